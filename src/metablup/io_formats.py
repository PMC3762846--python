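"""Readers and writers for on-disk artefacts.

Everything tabular is TSV (UTF-8, '.' decimal separator): count tables and
profile matrices with samples as rows and features as columns, relationship
matrices dense and square with matching row/column ids, phenotype tables
with a ``sample_id`` column.  Result bundles are schema-versioned JSON plus
a predictions TSV.  Configs are flat YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .profiles import CountTable, ProfileMatrix, RelationshipMatrix

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_profile",
    "write_profile",
    "read_grm",
    "write_grm",
    "read_phenotypes",
    "write_phenotypes",
    "read_config",
    "write_results",
    "read_results",
]

SCHEMA_VERSION = 1


def read_count_table(path: str | Path) -> CountTable:
    """Read a samples x features TSV of non-negative integer counts."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dupes[:5]}")
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float)) | (values.astype(float) % 1 != 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-integer value {values[i, j]!r} at "
            f"sample {df.index[i]!r}, feature {df.columns[j]!r} (line {i + 2})"
        )
    neg = values.astype(float) < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"{path}: negative count {values[i, j]} at "
            f"sample {df.index[i]!r}, feature {df.columns[j]!r} (line {i + 2})"
        )
    return CountTable.from_dataframe(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def read_profile(path: str | Path) -> ProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ProfileMatrix(
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(f) for f in df.columns],
        X=df.to_numpy(dtype=float),
    )


def write_profile(profile: ProfileMatrix, path: str | Path) -> None:
    pd.DataFrame(
        profile.X, index=profile.sample_ids, columns=profile.feature_ids
    ).to_csv(path, sep="\t", index_label="sample_id")


def read_grm(path: str | Path) -> RelationshipMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: GRM row and column ids differ")
    m = df.attrs.get("m_features", 0)
    return RelationshipMatrix(
        sample_ids=[str(s) for s in df.index],
        G=df.to_numpy(dtype=float),
        m_features=int(m),
    )


def write_grm(grm: RelationshipMatrix, path: str | Path) -> None:
    grm.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV: sample_id, phenotype[, covariate][, cohort].

    A blank phenotype marks the sample as a prediction target.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "phenotype" not in df.columns:
        raise ValueError(f"{path}: need sample_id and phenotype columns")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes[:5]}")
    df["phenotype"] = pd.to_numeric(df["phenotype"], errors="raise")
    if "covariate" in df.columns:
        df["covariate"] = pd.to_numeric(df["covariate"], errors="raise")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as handle:
        return yaml.safe_load(handle)


def write_results(bundle: Mapping, out_dir: str | Path) -> dict[str, Path]:
    """Write a result bundle: report.json plus predictions.tsv.

    The JSON carries the schema version, the full parameter/config log and
    any seeds used, so identical configs reproduce identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = dict(bundle)
    bundle.setdefault("schema_version", SCHEMA_VERSION)
    report_path = out_dir / "report.json"
    pred_path = out_dir / "predictions.tsv"
    predictions = bundle.get("predictions", {})
    with open(report_path, "w") as handle:
        json.dump(bundle, handle, indent=2, sort_keys=True, default=_json_default)
        handle.write("\n")
    pd.DataFrame(
        {"sample_id": list(predictions), "predicted": list(predictions.values())}
    ).to_csv(pred_path, sep="\t", index=False)
    return {"report": report_path, "predictions": pred_path}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj).__name__}")


def read_results(out_dir: str | Path) -> dict:
    with open(Path(out_dir) / "report.json") as handle:
        return json.load(handle)
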