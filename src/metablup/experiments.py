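"""Reference-design experiments and the per-contig regression baseline.

These operations probe how prediction accuracy responds to properties of
the reference population and the feature space: reference size (random
sub-references, replicated), phenotype extremeness (most- vs least-extreme
reference sets), per-sample sequencing depth (hypergeometric read
subsampling), and contig-database size (random or disjoint feature
subsets).  A per-contig simple-regression baseline ranks contigs by
association significance in the reference and predicts validation samples
by averaging the top-N single-contig models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import pearson_accuracy
from .mixedmodel import fit_and_predict
from .profiles import (
    CountTable,
    ProfileMatrix,
    RelationshipMatrix,
    build_profile,
    filter_low_count,
    relationship_matrix,
)

__all__ = [
    "ExperimentResult",
    "reference_size_sweep",
    "extreme_reference",
    "depth_subsample",
    "contig_subset_sweep",
    "contigwise_association",
    "topn_contig_prediction",
]


@dataclass
class ExperimentResult:
    """Tidy per-replicate accuracies for one experimental factor."""

    factor: str
    records: list[tuple[float, int, float]] = field(default_factory=list)
    seed: int = 0

    def add(self, factor_value: float, replicate: int, accuracy: float) -> None:
        self.records.append((factor_value, replicate, accuracy))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records, columns=[self.factor, "replicate", "accuracy"]
        )

    def mean_by_factor(self) -> pd.Series:
        df = self.to_dataframe()
        return df.groupby(self.factor)["accuracy"].mean()

    def var_by_factor(self) -> pd.Series:
        df = self.to_dataframe()
        return df.groupby(self.factor)["accuracy"].var(ddof=1)


def _combined_profile(
    reference_counts: CountTable,
    validation_counts: CountTable,
    min_total: int = 10,
) -> ProfileMatrix:
    shared = [
        f
        for f in reference_counts.feature_ids
        if f in set(validation_counts.feature_ids)
    ]
    if not shared:
        raise ValueError("no shared features between the two populations")
    combined = CountTable(
        sample_ids=list(reference_counts.sample_ids)
        + list(validation_counts.sample_ids),
        feature_ids=shared,
        counts=np.vstack(
            [
                reference_counts.subset_features(shared).counts,
                validation_counts.subset_features(shared).counts,
            ]
        ),
    )
    return build_profile(filter_low_count(combined, min_total=min_total))


def _accuracy(
    G: RelationshipMatrix,
    reference_ids: Sequence[str],
    ref_pheno: Mapping[str, float],
    validation_ids: Sequence[str],
    val_pheno: Mapping[str, float],
) -> float:
    y_ref = np.array([ref_pheno[s] for s in reference_ids], dtype=float)
    result = fit_and_predict(G, list(reference_ids), y_ref, list(validation_ids))
    pred = result.predictions(list(validation_ids))
    obs = np.array([val_pheno[s] for s in validation_ids], dtype=float)
    return pearson_accuracy(pred, obs)


def reference_size_sweep(
    reference_counts: CountTable,
    reference_phenotypes: Mapping[str, float],
    validation_counts: CountTable,
    validation_phenotypes: Mapping[str, float],
    sizes: Sequence[int],
    reps: int = 20,
    seed: int = 0,
    min_total: int = 10,
) -> ExperimentResult:
    """Accuracy as a function of reference population size N.

    For each N, draws N reference samples without replacement, trains on
    them and predicts the full validation population; repeated ``reps``
    times.  The profile and G are built once over the union of samples, so
    replicates differ only in which reference rows enter the mixed model.
    """
    if min(sizes) < 5:
        raise ValueError("reference size must be >= 5 for REML")
    n_ref = reference_counts.n_samples
    if max(sizes) > n_ref:
        raise ValueError(f"size {max(sizes)} exceeds reference size {n_ref}")
    profile = _combined_profile(reference_counts, validation_counts, min_total)
    G = relationship_matrix(profile)
    rng = np.random.default_rng(seed)
    result = ExperimentResult(factor="reference_size", seed=seed)
    val_ids = list(validation_counts.sample_ids)
    ref_ids = np.array(reference_counts.sample_ids)
    for N in sizes:
        for rep in range(reps):
            chosen = list(rng.choice(ref_ids, size=N, replace=False))
            r = _accuracy(
                G, chosen, reference_phenotypes, val_ids, validation_phenotypes
            )
            result.add(float(N), rep, r)
    return result


def extreme_reference(
    phenotypes: Mapping[str, float],
    mode: str,
    size: int,
) -> list[str]:
    """Select the most- or least-extreme reference samples by phenotype.

    ``most``: size/2 highest plus size/2 lowest phenotypes.  ``least``: the
    ``size`` samples in the middle of the phenotype ranking.  Ties across a
    selection boundary are broken by stable sample-id order.
    """
    n = len(phenotypes)
    if size > n:
        raise ValueError(f"size {size} exceeds {n} samples")
    ranked = sorted(phenotypes, key=lambda s: (phenotypes[s], s))
    if mode == "most":
        if size % 2 != 0:
            raise ValueError("size must be even for mode='most'")
        half = size // 2
        return ranked[:half] + ranked[-half:]
    if mode == "least":
        start = (n - size) // 2
        return ranked[start : start + size]
    raise ValueError(f"mode must be 'most' or 'least', got {mode!r}")


def depth_subsample(counts: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample each sample's reads to a fixed depth without replacement.

    Each sample's count vector is treated as an urn of reads; ``depth``
    reads are drawn multivariate-hypergeometrically.  Samples whose total is
    at or below the requested depth keep all their reads (with a warning
    when strictly below).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    new = np.empty_like(counts.counts)
    for i, row in enumerate(counts.counts):
        total = int(row.sum())
        if total <= depth:
            if total < depth:
                warnings.warn(
                    f"sample {counts.sample_ids[i]!r} has only {total} reads "
                    f"(< depth {depth}); keeping all",
                    RuntimeWarning,
                    stacklevel=2,
                )
            new[i] = row
        else:
            new[i] = rng.multivariate_hypergeometric(
                row.astype(np.int64), depth, method="marginals"
            )
    return CountTable(
        sample_ids=list(counts.sample_ids),
        feature_ids=list(counts.feature_ids),
        counts=new,
    )


def contig_subset_sweep(
    reference_counts: CountTable,
    reference_phenotypes: Mapping[str, float],
    validation_counts: CountTable,
    validation_phenotypes: Mapping[str, float],
    Ns: Sequence[int] = (),
    reps: int = 20,
    seed: int = 0,
    disjoint_groups: int | None = None,
    min_total: int = 10,
) -> ExperimentResult:
    """Accuracy using random (or disjoint) contig subsets of varying size.

    The standardised profile is computed once over all retained features;
    because standardisation is per-feature, the G of a feature subset is
    exactly X[:, subset] X[:, subset]' / |subset|.  In disjoint mode the
    features are shuffled and partitioned into ``disjoint_groups``
    equal-sized non-overlapping groups, each evaluated once.
    """
    profile = _combined_profile(reference_counts, validation_counts, min_total)
    m = profile.n_features
    rng = np.random.default_rng(seed)
    ref_ids = list(reference_counts.sample_ids)
    val_ids = list(validation_counts.sample_ids)

    def eval_cols(cols: np.ndarray) -> float:
        Xs = profile.X[:, cols]
        G = RelationshipMatrix(
            sample_ids=list(profile.sample_ids),
            G=Xs @ Xs.T / len(cols),
            m_features=len(cols),
        )
        return _accuracy(
            G, ref_ids, reference_phenotypes, val_ids, validation_phenotypes
        )

    if disjoint_groups is not None:
        group_size = m // disjoint_groups
        if group_size < 1:
            raise ValueError(
                f"cannot split {m} features into {disjoint_groups} groups"
            )
        result = ExperimentResult(factor="contig_group", seed=seed)
        perm = rng.permutation(m)
        for g in range(disjoint_groups):
            cols = perm[g * group_size : (g + 1) * group_size]
            result.add(float(group_size), g, eval_cols(cols))
        return result

    if not Ns:
        raise ValueError("provide subset sizes Ns or disjoint_groups")
    if max(Ns) > m:
        raise ValueError(f"subset size {max(Ns)} exceeds {m} features")
    result = ExperimentResult(factor="n_contigs", seed=seed)
    for N in Ns:
        for rep in range(reps):
            cols = rng.choice(m, size=N, replace=False)
            result.add(float(N), rep, eval_cols(cols))
    return result


def contigwise_association(
    reference_counts: CountTable,
    reference_phenotypes: Mapping[str, float],
    validation_counts: CountTable,
    min_reads: int = 100,
    use_standardised: bool = True,
) -> pd.DataFrame:
    """Per-contig simple regression of phenotype on profile value.

    Contigs with fewer than ``min_reads`` total reads in *either* population
    are removed.  For each surviving contig a simple linear model
    phenotype ~ profile value is fitted over the reference samples; contigs
    are ranked by the two-sided t-test p-value of the slope (ties broken by
    |t| descending, then feature id).

    Returns a DataFrame (feature_id, slope, intercept, t, p, rank) sorted by
    rank; the slope/intercept operate on the standardised profile scale by
    default (``use_standardised=False`` regresses on raw counts).
    """
    shared = [
        f
        for f in reference_counts.feature_ids
        if f in set(validation_counts.feature_ids)
    ]
    ref = reference_counts.subset_features(shared)
    val = validation_counts.subset_features(shared)
    keep = (ref.counts.sum(axis=0) >= min_reads) & (
        val.counts.sum(axis=0) >= min_reads
    )
    if not keep.any():
        raise ValueError(f"no contigs with >= {min_reads} reads in both populations")
    features = [f for f, k in zip(shared, keep) if k]
    if use_standardised:
        # depth-normalise against the full shared feature space, then keep
        # only the surviving columns (standardisation is per-feature)
        profile = build_profile(ref)
        features = [f for f in features if f in set(profile.feature_ids)]
        profile = profile.subset_features(features)
        predictor = profile.X
    else:
        ref = ref.subset_features(features)
        predictor = ref.counts.astype(float)
        sd = predictor.std(axis=0)
        features = [f for f, s in zip(features, sd) if s > 0]
        predictor = predictor[:, sd > 0]

    y = np.array([reference_phenotypes[s] for s in ref.sample_ids], dtype=float)
    n = len(y)
    xc = predictor - predictor.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    sxy = xc.T @ yc
    slope = sxy / sxx
    intercept = y.mean() - slope * predictor.mean(axis=0)
    syy = float((yc**2).sum())
    ss_res = syy - slope * sxy
    ss_res = np.maximum(ss_res, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = slope / se
    t[~np.isfinite(t)] = np.inf  # perfect fit
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    df = pd.DataFrame(
        {
            "feature_id": features,
            "slope": slope,
            "intercept": intercept,
            "t": t,
            "p": p,
        }
    )
    df["abs_t"] = np.abs(df["t"])
    df = df.sort_values(
        ["p", "abs_t", "feature_id"], ascending=[True, False, True]
    ).drop(columns="abs_t")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def topn_contig_prediction(
    models: pd.DataFrame,
    validation_counts: CountTable,
    validation_phenotypes: Mapping[str, float],
    Ns: Sequence[int],
    use_standardised: bool = True,
) -> ExperimentResult:
    """Predict validation phenotypes by averaging the top-N contig models.

    Each of the N best-ranked single-contig models predicts every validation
    sample from that contig's profile value; the N predictions are averaged
    and correlated with the observed phenotypes.
    """
    if models.empty:
        raise ValueError("no ranked contig models")
    val = validation_counts
    if use_standardised:
        # standardise within the full validation table so depth scaling and
        # per-feature moments do not depend on which models are requested
        profile = build_profile(val)
        values = {f: profile.X[:, j] for j, f in enumerate(profile.feature_ids)}
    else:
        values = {
            f: val.counts[:, j].astype(float) for j, f in enumerate(val.feature_ids)
        }
    models = models[models["feature_id"].isin(values)].reset_index(drop=True)
    obs = np.array(
        [validation_phenotypes[s] for s in val.sample_ids], dtype=float
    )
    result = ExperimentResult(factor="top_n_contigs", seed=0)
    for N in Ns:
        n_used = N
        if N > len(models):
            warnings.warn(
                f"top-N {N} exceeds {len(models)} available models; capping",
                RuntimeWarning,
                stacklevel=2,
            )
            n_used = len(models)
        top = models.iloc[:n_used]
        preds = np.mean(
            [
                row.intercept + row.slope * values[row.feature_id]
                for row in top.itertuples()
            ],
            axis=0,
        )
        result.add(float(N), 0, pearson_accuracy(preds, obs))
    return result
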