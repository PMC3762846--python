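"""Validation designs and accuracy statistics for metagenomic prediction.

Accuracy is Pearson's r between predicted and observed phenotypes, assessed
either by k-fold cross-validation within one cohort (each fold predicted
from the remaining folds, predictions collated) or by training on one
population and validating on a second, independent one.  Binary traits are
predicted on the continuous scale and thresholded; the null predictor
(always guessing the majority class) and the rank-based AUC provide the
baselines.  Confidence intervals for r come from a percentile bootstrap
over (predicted, observed) pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import io_formats
from .mixedmodel import PredictionResult, fit_and_predict
from .profiles import (
    CountTable,
    ProfileMatrix,
    RelationshipMatrix,
    build_profile,
    filter_low_count,
    relationship_matrix,
)

__all__ = [
    "CVScheme",
    "AccuracyReport",
    "kfold_split",
    "cross_validate",
    "two_population_validate",
    "pearson_accuracy",
    "classify",
    "null_predictor_accuracy",
    "auc",
    "bootstrap_ci",
    "percent_reduction",
    "run_workflow",
]


@dataclass
class CVScheme:
    """Seeded random partition of samples into k near-equal folds (1..k)."""

    k: int
    assignment: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


@dataclass
class AccuracyReport:
    r: float
    per_fold_r: list[float] = field(default_factory=list)
    pct_correct: float | None = None
    auc: float | None = None
    ci95: tuple[float, float] | None = None
    n: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "per_fold_r": self.per_fold_r,
            "pct_correct": self.pct_correct,
            "auc": self.auc,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "n": self.n,
            **self.extra,
        }


def kfold_split(
    sample_ids: Sequence[str],
    k: int,
    seed: int,
    stratify_labels: Mapping[str, int] | None = None,
) -> CVScheme:
    """Randomly partition samples into k folds of size floor/ceil(n/k).

    With ``stratify_labels`` the split is performed within each label class,
    keeping class composition approximately even across folds.
    """
    n = len(sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    if stratify_labels is None:
        groups = [list(sample_ids)]
    else:
        classes = sorted({stratify_labels[s] for s in sample_ids})
        groups = [[s for s in sample_ids if stratify_labels[s] == c] for c in classes]
    offset = 0
    for group in groups:
        order = rng.permutation(len(group))
        for pos, idx in enumerate(order):
            assignment[group[idx]] = (pos + offset) % k + 1
        offset += len(group)
    return CVScheme(k=k, assignment=assignment, seed=seed)


def _as_relationship(data) -> RelationshipMatrix:
    if isinstance(data, RelationshipMatrix):
        return data
    if isinstance(data, ProfileMatrix):
        return relationship_matrix(data)
    if isinstance(data, CountTable):
        return relationship_matrix(build_profile(filter_low_count(data)))
    raise TypeError(f"cannot build a relationship matrix from {type(data).__name__}")


def cross_validate(
    data,
    phenotypes: Mapping[str, float],
    scheme: CVScheme,
    binary: bool = False,
) -> tuple[AccuracyReport, dict[str, float]]:
    """k-fold cross-validated prediction accuracy.

    For each fold the fold members are the targets and all remaining folds
    the reference; variance components are re-estimated per fold so target
    samples never influence their own prediction.  Predictions are collated
    (each sample predicted exactly once) into the overall r; per-fold r is
    reported alongside.

    ``data`` may be a CountTable, ProfileMatrix or RelationshipMatrix; G is
    built once over all samples.
    """
    G = _as_relationship(data)
    missing = set(scheme.assignment) - set(G.sample_ids)
    if missing:
        raise ValueError(f"samples missing from G: {sorted(missing)[:5]}")
    predictions: dict[str, float] = {}
    per_fold_r: list[float] = []
    for fold in range(1, scheme.k + 1):
        targets = scheme.fold_ids(fold)
        reference = [s for s in scheme.assignment if scheme.assignment[s] != fold]
        if len(reference) < 5:
            raise ValueError(
                f"fold {fold}: only {len(reference)} reference samples (need >= 5)"
            )
        y_ref = np.array([phenotypes[s] for s in reference], dtype=float)
        result = fit_and_predict(G, reference, y_ref, targets)
        fold_pred = result.predictions(targets)
        for s, p in zip(targets, fold_pred):
            predictions[s] = float(p)
        obs = np.array([phenotypes[s] for s in targets], dtype=float)
        if len(targets) >= 3 and np.ptp(obs) > 0 and np.ptp(fold_pred) > 0:
            per_fold_r.append(pearson_accuracy(fold_pred, obs))
    ids = list(predictions)
    pred = np.array([predictions[s] for s in ids])
    obs = np.array([phenotypes[s] for s in ids], dtype=float)
    report = AccuracyReport(
        r=pearson_accuracy(pred, obs), per_fold_r=per_fold_r, n=len(ids)
    )
    if binary:
        labels = obs.astype(int)
        _, report.pct_correct = classify(pred, obs=labels)
        report.auc = auc(pred, labels)
    return report, predictions


def two_population_validate(
    reference_counts: CountTable,
    reference_phenotypes: Mapping[str, float],
    validation_counts: CountTable,
    validation_phenotypes: Mapping[str, float],
    min_total: int = 10,
    binary: bool = False,
) -> tuple[AccuracyReport, dict[str, float]]:
    """Train on one population, predict a second, independent one.

    The two count tables are restricted to their shared feature space, G is
    built over the union of samples, variance components are estimated from
    the reference only, and r is computed on the validation samples.
    """
    overlap = set(reference_counts.sample_ids) & set(validation_counts.sample_ids)
    if overlap:
        raise ValueError(
            f"populations share samples: {sorted(overlap)[:5]} "
            "(validation must be independent)"
        )
    shared = [
        f
        for f in reference_counts.feature_ids
        if f in set(validation_counts.feature_ids)
    ]
    if not shared:
        raise ValueError("no shared features between the two populations")
    ref = reference_counts.subset_features(shared)
    val = validation_counts.subset_features(shared)
    combined = CountTable(
        sample_ids=list(ref.sample_ids) + list(val.sample_ids),
        feature_ids=shared,
        counts=np.vstack([ref.counts, val.counts]),
    )
    G = _as_relationship(combined)
    reference = list(ref.sample_ids)
    targets = list(val.sample_ids)
    y_ref = np.array([reference_phenotypes[s] for s in reference], dtype=float)
    result = fit_and_predict(G, reference, y_ref, targets)
    pred = result.predictions(targets)
    obs = np.array([validation_phenotypes[s] for s in targets], dtype=float)
    report = AccuracyReport(
        r=pearson_accuracy(pred, obs),
        n=len(targets),
        extra={"n_shared_features": len(shared), "n_features_used": G.m_features},
    )
    if binary:
        labels = obs.astype(int)
        _, report.pct_correct = classify(pred, obs=labels)
        report.auc = auc(pred, labels)
    return report, {s: float(p) for s, p in zip(targets, pred)}


def pearson_accuracy(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation between predicted and observed phenotypes."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("pred and obs must be equal-length vectors, n >= 3")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(pred, obs).statistic)


def classify(
    pred: np.ndarray,
    obs: np.ndarray | None = None,
    threshold: float = 0.5,
) -> tuple[np.ndarray, float | None]:
    """Threshold continuous predictions into most-likely 0/1 phenotypes.

    Predictions strictly above the threshold are class 1 ("normal"); ties at
    the threshold go to class 0 ("case").  When observed 0/1 labels are
    given, the fraction correctly classified is returned as well.
    """
    pred = np.asarray(pred, dtype=float)
    labels = (pred > threshold).astype(int)
    pct = None
    if obs is not None:
        obs = np.asarray(obs)
        if not set(np.unique(obs)) <= {0, 1}:
            raise ValueError("observed labels must be 0/1")
        pct = float(np.mean(labels == obs))
    return labels, pct


def null_predictor_accuracy(obs_labels: np.ndarray) -> float:
    """Accuracy of always predicting the most common class."""
    obs = np.asarray(obs_labels)
    if obs.size == 0:
        raise ValueError("empty label vector")
    if not set(np.unique(obs)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    n1 = int(np.sum(obs == 1))
    return max(n1, obs.size - n1) / obs.size


def auc(pred: np.ndarray, obs_labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve.

    Equals the probability that a randomly chosen class-1 sample has a
    higher prediction than a randomly chosen class-0 sample, with tied
    predictions counting one half.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs_labels)
    if not set(np.unique(obs)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    n1 = int(np.sum(obs == 1))
    n0 = obs.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(pred)
    r1 = float(np.sum(ranks[obs == 1]))
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)


def _bootstrap_r(pred, obs, idx):
    """Pearson r for each row of resample indices, vectorised."""
    p = pred[idx]
    o = obs[idx]
    pc = p - p.mean(axis=1, keepdims=True)
    oc = o - o.mean(axis=1, keepdims=True)
    sp = np.sqrt((pc**2).sum(axis=1))
    so = np.sqrt((oc**2).sum(axis=1))
    denom = sp * so
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc * oc).sum(axis=1) / denom
    r[denom == 0] = np.nan  # degenerate resample, to be redrawn
    return r


def bootstrap_ci(
    pred: np.ndarray,
    obs: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for the prediction accuracy r.

    (pred, obs) pairs are resampled with replacement ``n_boot`` times, r is
    recomputed per resample, and the 2.5th/97.5th percentiles are returned.
    Degenerate resamples in which either vector is constant are redrawn.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("need >= 3 (pred, obs) pairs")
    n = pred.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    r = _bootstrap_r(pred, obs, idx)
    for _ in range(100):
        bad = np.isnan(r)
        if not bad.any():
            break
        idx_new = rng.integers(0, n, size=(int(bad.sum()), n))
        r[bad] = _bootstrap_r(pred, obs, idx_new)
    else:
        raise RuntimeError("could not draw non-degenerate bootstrap resamples")
    lower, upper = np.percentile(r, [2.5, 97.5])
    return float(lower), float(upper)


def percent_reduction(control_mean: float, treatment_mean: float) -> float:
    """Percent reduction of the treatment mean relative to the control mean."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (control_mean - treatment_mean) / control_mean


def run_workflow(config: Mapping | str | Path) -> dict:
    """Run counting -> profile -> G -> REML -> BLUP -> evaluation end to end.

    ``config`` is a mapping (or path to a YAML file) with keys:

    - ``counts``: path to a samples x features count TSV
    - ``phenotypes``: path to a phenotype TSV (sample_id, phenotype,
      optional covariate / cohort columns)
    - ``design``: ``{"kind": "cv", "k": 3, "seed": 0}`` or
      ``{"kind": "two_population", "reference_cohort": ..., "validation_cohort": ...}``
    - ``min_total``: low-count filter threshold (default 10)
    - ``binary``: treat the phenotype as 0/1 (default False)
    - ``residualize_on_covariate``: pre-adjust phenotype by OLS on the
      covariate column (default False)
    - ``bootstrap``: ``{"n_boot": 10000, "seed": 0}`` (optional)
    - ``out_dir``: where predictions.tsv and report.json are written (optional)

    Returns the result bundle (also written to disk when ``out_dir`` is set).
    """
    if isinstance(config, (str, Path)):
        config = io_formats.read_config(config)
    for key in ("counts", "phenotypes", "design"):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    counts_path = Path(config["counts"])
    pheno_path = Path(config["phenotypes"])
    for p in (counts_path, pheno_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")

    counts = io_formats.read_count_table(counts_path)
    pheno = io_formats.read_phenotypes(pheno_path)
    observed = pheno.dropna(subset=["phenotype"])
    y = dict(zip(observed["sample_id"], observed["phenotype"].astype(float)))
    if config.get("residualize_on_covariate"):
        from .mixedmodel import residualize_phenotype

        ids = list(y)
        resid = residualize_phenotype(
            np.array([y[s] for s in ids]),
            observed.set_index("sample_id").loc[ids, "covariate"].to_numpy(float),
        )
        y = dict(zip(ids, resid.astype(float)))

    design = dict(config["design"])
    binary = bool(config.get("binary", False))
    min_total = int(config.get("min_total", 10))
    if design["kind"] == "cv":
        table = filter_low_count(counts, min_total=min_total)
        scheme = kfold_split(
            [s for s in counts.sample_ids if s in y],
            k=int(design.get("k", 3)),
            seed=int(design.get("seed", 0)),
        )
        report, predictions = cross_validate(table, y, scheme, binary=binary)
    elif design["kind"] == "two_population":
        if "cohort" not in pheno.columns:
            raise ValueError("two_population design needs a cohort column")
        cohorts = dict(zip(pheno["sample_id"], pheno["cohort"]))
        ref_ids = [s for s in counts.sample_ids if cohorts.get(s) == design["reference_cohort"]]
        val_ids = [s for s in counts.sample_ids if cohorts.get(s) == design["validation_cohort"]]
        report, predictions = two_population_validate(
            counts.subset_samples(ref_ids),
            y,
            counts.subset_samples(val_ids),
            y,
            min_total=min_total,
            binary=binary,
        )
    else:
        raise ValueError(f"unknown design kind {design['kind']!r}")

    if "bootstrap" in config:
        boot = dict(config["bootstrap"])
        ids = sorted(predictions)
        report.ci95 = bootstrap_ci(
            np.array([predictions[s] for s in ids]),
            np.array([y[s] for s in ids]),
            n_boot=int(boot.get("n_boot", 10_000)),
            seed=int(boot.get("seed", 0)),
        )

    bundle = {
        "schema_version": 1,
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in config.items()},
        "report": report.to_dict(),
        "predictions": predictions,
        "variance_components": None,
    }
    if "out_dir" in config:
        io_formats.write_results(bundle, config["out_dir"])
    return bundle
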