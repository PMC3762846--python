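"""Metagenomic profiles and the metagenomic relationship matrix.

A metagenomic profile is the vector of shotgun read counts per sample
aligning to each contig (or k-mer) of a reference set.  Profiles for n
samples over m features form a count table; after depth normalisation
(counts per million), a log transform and per-feature standardisation they
become the real-valued profile matrix X, from which the sample-relationship
matrix G = XX'/m is built.  G plays the role a genomic relationship matrix
plays in genomic prediction: it quantifies how similar two samples'
microbiomes are, and drives the BLUP prediction of host phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "CountTable",
    "ProfileMatrix",
    "RelationshipMatrix",
    "count_alignments",
    "filter_low_count",
    "build_profile",
    "relationship_matrix",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class CountTable:
    """Integer samples x features matrix of read (or k-mer) counts."""

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray  # (n, m) non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, m = self.counts.shape
        if n != len(self.sample_ids) or m != len(self.feature_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            counts=df.to_numpy(dtype=np.int64),
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "CountTable":
        idx = {f: j for j, f in enumerate(self.feature_ids)}
        cols = [idx[f] for f in feature_ids]
        return CountTable(
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            counts=self.counts[:, cols].copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return CountTable(
            sample_ids=list(sample_ids),
            feature_ids=list(self.feature_ids),
            counts=self.counts[rows, :].copy(),
        )


@dataclass
class ProfileMatrix:
    """Standardised profile matrix X (each column mean 0, population var 1)."""

    sample_ids: list[str]
    feature_ids: list[str]
    X: np.ndarray  # (n, m) reals
    transform_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("X shape does not match ids")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite entries in profile matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_features(self, feature_ids: Sequence[str]) -> "ProfileMatrix":
        idx = {f: j for j, f in enumerate(self.feature_ids)}
        cols = [idx[f] for f in feature_ids]
        return ProfileMatrix(
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            X=self.X[:, cols].copy(),
            transform_log=dict(self.transform_log, feature_subset=len(cols)),
        )


@dataclass
class RelationshipMatrix:
    """Symmetric n x n sample-similarity matrix G = XX'/m."""

    sample_ids: list[str]
    G: np.ndarray
    m_features: int

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.sample_ids)
        if self.G.shape != (n, n):
            raise ValueError("G must be square over the sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def block(self, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        r = [idx[s] for s in row_ids]
        c = [idx[s] for s in col_ids]
        return self.G[np.ix_(r, c)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.G, index=self.sample_ids, columns=self.sample_ids)


def count_alignments(
    sam_paths: Mapping[str, str | Path],
    contigs: Sequence[str],
    min_mapq: int = 0,
) -> CountTable:
    """Tally mapped primary alignments per contig for each sample's SAM file.

    Only mapped, primary, non-supplementary records count; unmapped reads are
    ignored.  A record aligned to a reference absent from ``contigs`` is an
    input error.
    """
    contig_index = {c: j for j, c in enumerate(contigs)}
    counts = np.zeros((len(sam_paths), len(contigs)), dtype=np.int64)
    for i, (sample, path) in enumerate(sam_paths.items()):
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam.fetch(until_eof=True):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                ref = rec.reference_name
                if ref not in contig_index:
                    raise ValueError(
                        f"sample {sample!r}: alignment to unknown contig {ref!r}"
                    )
                counts[i, contig_index[ref]] += 1
    return CountTable(
        sample_ids=list(sam_paths), feature_ids=list(contigs), counts=counts
    )


def filter_low_count(table: CountTable, min_total: int = 10) -> CountTable:
    """Drop features with fewer than ``min_total`` reads in total (strict <)."""
    totals = table.counts.sum(axis=0)
    keep = totals >= min_total
    if not keep.any():
        raise ValueError(
            f"empty profile: all {table.n_features} features have "
            f"total count < {min_total}"
        )
    return CountTable(
        sample_ids=list(table.sample_ids),
        feature_ids=[f for f, k in zip(table.feature_ids, keep) if k],
        counts=table.counts[:, keep].copy(),
    )


def build_profile(
    table: CountTable,
    depth_normalise: bool = True,
    pseudocount: float = 1.0,
    population_variance: bool = True,
) -> ProfileMatrix:
    """Normalise, log-transform and standardise a count table into X.

    Per sample, counts are optionally scaled to counts-per-million of that
    sample's total depth; each entry then becomes log(value + pseudocount);
    finally each feature column is centred to mean 0 and scaled to unit
    variance (population variance by default, so that trace(XX'/m) = n).
    Zero-variance columns carry no between-sample information and are
    dropped; their ids are recorded in ``transform_log['dropped_features']``.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to standardise")
    values = table.counts.astype(float)
    if depth_normalise:
        totals = values.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            zero = [s for s, t in zip(table.sample_ids, totals[:, 0]) if t == 0]
            raise ValueError(f"samples with zero total reads: {zero[:5]}")
        values = values / totals * 1e6
    values = np.log(values + pseudocount)
    mean = values.mean(axis=0)
    ddof = 0 if population_variance else 1
    sd = values.std(axis=0, ddof=ddof)
    # ptp catches exactly-constant columns whose floating-point std is a
    # harmless but nonzero rounding residual
    nonconst = (np.ptp(values, axis=0) > 0) & (sd > 0)
    dropped = [f for f, k in zip(table.feature_ids, nonconst) if not k]
    if not nonconst.any():
        raise ValueError("all features have zero variance after transform")
    X = (values[:, nonconst] - mean[nonconst]) / sd[nonconst]
    return ProfileMatrix(
        sample_ids=list(table.sample_ids),
        feature_ids=[f for f, k in zip(table.feature_ids, nonconst) if k],
        X=X,
        transform_log={
            "depth_normalise": depth_normalise,
            "pseudocount": pseudocount,
            "standardisation": "population" if population_variance else "sample",
            "dropped_features": dropped,
        },
    )


def relationship_matrix(profile: ProfileMatrix) -> RelationshipMatrix:
    """Compute G = XX'/m from a standardised profile matrix."""
    m = profile.n_features
    if m == 0:
        raise ValueError("profile has no features")
    G = profile.X @ profile.X.T / m
    G = (G + G.T) / 2.0  # remove float asymmetry
    return RelationshipMatrix(
        sample_ids=list(profile.sample_ids), G=G, m_features=m
    )
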