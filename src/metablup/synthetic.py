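"""Synthetic metagenomic datasets with known phenotypic architecture.

The generator emulates the statistical structure that metagenomic BLUP
assumes: a community of contigs whose relative abundances vary between
samples, sequenced to uneven depth, with many contigs each carrying a
small effect on the host phenotype.  Contig relative abundances are
log-normal; each sample perturbs the shared log-abundance vector, creating
the between-sample profile variation that the relationship matrix picks
up; read counts are multinomial given a sample's depth.  Phenotypes are
mu + g + e with g = X beta rescaled so that the realized microbiability
m2 = var(g)/var(g + e) hits the requested value exactly.  Binary traits
are produced by thresholding the liability g + e at a prevalence quantile,
and a two-cohort design can lower a "treatment" cohort's phenotype mean by
a set fraction (default 20%), mirroring a methane-mitigating feed trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .profiles import CountTable, build_profile, filter_low_count

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_counts",
    "simulate_phenotype",
    "simulate_dataset",
    "make_two_cohort_fixture",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic community and phenotype architecture.

    Depth is per-sample total reads, log-normal around ``mean_depth`` with
    coefficient of variation ``depth_dispersion``.  ``abundance_sigma`` is
    the s.d. of contig log-abundances (community unevenness).  Between-
    sample variation has two parts: ``n_factors`` latent community gradients
    (diet, enterotype-like axes) that move correlated blocks of contigs
    together with overall s.d. ``factor_sigma``, plus contig-wise
    independent noise of s.d. ``sample_sigma``.  ``m2`` is the
    microbiability, the fraction of phenotypic variance contributed by the
    contig effects.
    """

    n_samples: int = 100
    m_contigs: int = 1000
    mean_depth: int = 50_000
    depth_dispersion: float = 0.3
    abundance_sigma: float = 1.5
    n_factors: int = 5
    factor_sigma: float = 0.8
    sample_sigma: float = 0.5
    n_causal: Optional[int] = None  # None: every contig carries an effect
    m2: float = 0.5
    mu: float = 25.75  # phenotype mean, methane-like g CH4 / kg DMI scale
    phenotype_sd: float = 1.0  # within-cohort phenotypic standard deviation
    binary_prevalence: Optional[float] = None
    cohort_effect: Optional[float] = None  # fractional mean drop for treatment
    sparse_effects: bool = False  # few large effects instead of many small
    seed: int = 0

    @property
    def effective_n_causal(self) -> int:
        return self.m_contigs if self.n_causal is None else self.n_causal

    def validate(self) -> None:
        if not 0 <= self.m2 <= 1:
            raise ValueError("m2 must be in [0, 1]")
        if self.effective_n_causal > self.m_contigs:
            raise ValueError("n_causal cannot exceed m_contigs")
        if self.m2 > 0 and self.effective_n_causal == 0:
            raise ValueError("m2 > 0 requires at least one causal contig")


@dataclass
class SyntheticDataset:
    """A simulated count table plus the ground truth behind its phenotypes."""

    counts: CountTable
    beta: dict[str, float]
    g: np.ndarray  # true microbiome effect per sample
    phenotype: np.ndarray  # continuous trait, mu + g + e
    binary: Optional[np.ndarray] = None  # 0 = case, 1 = normal
    cohorts: Optional[dict[str, str]] = None
    m2_target: float = 0.0
    config: Optional[SimulationConfig] = None

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.sample_ids

    def phenotype_map(self, binary: bool = False) -> dict[str, float]:
        values = self.binary if binary else self.phenotype
        return {s: float(v) for s, v in zip(self.sample_ids, values)}

    def realized_m2(self) -> float:
        return float(np.var(self.g) / np.var(self.phenotype))


def simulate_counts(
    config: SimulationConfig, sample_prefix: str = "s"
) -> CountTable:
    """Draw a samples x contigs count table from the community model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.m_contigs
    log_abund = rng.normal(0.0, config.abundance_sigma, size=m)
    perturb = rng.normal(0.0, config.sample_sigma, size=(n, m))
    if config.n_factors > 0 and config.factor_sigma > 0:
        loadings = rng.normal(0.0, 1.0, size=(config.n_factors, m))
        scores = rng.normal(0.0, 1.0, size=(n, config.n_factors))
        perturb += (
            config.factor_sigma / np.sqrt(config.n_factors)
        ) * scores @ loadings
    logits = log_abund[None, :] + perturb
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    if config.depth_dispersion > 0:
        sigma = np.sqrt(np.log1p(config.depth_dispersion**2))
        depths = np.maximum(
            1,
            np.round(
                config.mean_depth
                * rng.lognormal(-(sigma**2) / 2, sigma, size=n)
            ).astype(np.int64),
        )
    else:
        depths = np.full(n, config.mean_depth, dtype=np.int64)
    counts = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], probs[i])
    width = len(str(n))
    return CountTable(
        sample_ids=[f"{sample_prefix}{i:0{width}d}" for i in range(n)],
        feature_ids=[f"contig{j:05d}" for j in range(m)],
        counts=counts,
    )


def simulate_phenotype(
    counts: CountTable, config: SimulationConfig
) -> SyntheticDataset:
    """Attach a phenotype with microbiability ``m2`` to a count table.

    Builds the standardised profile X through the same pipeline the
    predictor uses, draws effects beta for ``n_causal`` randomly chosen
    retained contigs (normal for the dense, infinitesimal-style
    architecture; a few large effects when ``sparse_effects``), sets
    g = X beta, and rescales g and the noise so the *realized* variance
    ratio var(g)/var(g + e) equals m2 exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = counts.n_samples
    profile = build_profile(filter_low_count(counts))
    m_kept = profile.n_features
    n_causal = min(config.effective_n_causal, m_kept)

    beta = np.zeros(m_kept)
    if n_causal > 0 and config.m2 > 0:
        causal = rng.choice(m_kept, size=n_causal, replace=False)
        if config.sparse_effects:
            beta[causal] = rng.choice([-1.0, 1.0], size=n_causal) * rng.lognormal(
                0.0, 0.5, size=n_causal
            )
        else:
            beta[causal] = rng.normal(0.0, 1.0, size=n_causal)
    g = profile.X @ beta
    e = rng.normal(0.0, 1.0, size=n)

    if config.m2 == 0 or np.std(g) == 0:
        g = np.zeros(n)
        e = e / np.std(e)  # unit phenotypic variance
        if config.m2 > 0:
            raise ValueError("causal effects produced no profile variation")
    else:
        g = g / np.std(g) * np.sqrt(config.m2)
        if config.m2 < 1:
            e = e - e.mean()
            # remove the sample projection of e onto g so the realized
            # variance ratio is exact, then scale
            e = e - (e @ g) / (g @ g) * g
            e = e / np.std(e) * np.sqrt(1 - config.m2)
        else:
            e = np.zeros(n)
    g = g * config.phenotype_sd
    e = e * config.phenotype_sd
    phenotype = config.mu + g + e

    binary = None
    if config.binary_prevalence is not None:
        liability = g + e
        threshold = np.quantile(liability, 1 - config.binary_prevalence)
        # top `prevalence` of the liability distribution are cases (0)
        binary = (liability <= threshold).astype(int)

    cohorts = None
    if config.cohort_effect is not None:
        half = n // 2
        cohorts = {
            s: ("control" if i < half else "treatment")
            for i, s in enumerate(counts.sample_ids)
        }
        control_mean = phenotype[:half].mean()
        phenotype = phenotype.copy()
        phenotype[half:] -= config.cohort_effect * control_mean

    return SyntheticDataset(
        counts=counts,
        beta={f: float(b) for f, b in zip(profile.feature_ids, beta)},
        g=g,
        phenotype=phenotype,
        binary=binary,
        cohorts=cohorts,
        m2_target=config.m2,
        config=config,
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Counts and phenotype in one call (same seed governs both)."""
    return simulate_phenotype(simulate_counts(config), config)


def make_two_cohort_fixture(
    seed: int = 0,
    n_reference: int = 40,
    n_validation: int = 24,
    m_contigs: int = 600,
    m2: float = 0.5,
    cohort_effect: float = 0.2,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Two sample-disjoint cohorts sharing one contig space.

    Cohort A (the reference) is split into control and treatment halves,
    the treatment half's phenotype mean lowered by ``cohort_effect``
    (default 20%), mirroring a methane-mitigating feed trial; cohort B
    (the validation population) is homogeneous.  Both cohorts are generated
    from one community and one set of contig effects, so cross-cohort
    prediction is meaningful.  Sized to run end-to-end in seconds.
    """
    n_total = n_reference + n_validation
    config = SimulationConfig(
        n_samples=n_total,
        m_contigs=m_contigs,
        n_causal=m_contigs,
        m2=m2,
        phenotype_sd=2.5,  # within-cohort sd on the methane-like scale
        seed=seed,
    )
    counts = simulate_counts(config)
    joint = simulate_phenotype(counts, config)

    ref_ids = counts.sample_ids[:n_reference]
    val_ids = counts.sample_ids[n_reference:]
    half = n_reference // 2
    cohorts_a = {
        s: ("control" if i < half else "treatment") for i, s in enumerate(ref_ids)
    }
    phen = joint.phenotype.copy()
    control_mean = phen[:half].mean()
    phen[half:n_reference] -= cohort_effect * control_mean

    def subset(ids, sl, cohorts=None):
        return SyntheticDataset(
            counts=counts.subset_samples(ids),
            beta=joint.beta,
            g=joint.g[sl],
            phenotype=phen[sl],
            binary=None,
            cohorts=cohorts,
            m2_target=m2,
            config=config,
        )

    cohort_a = subset(ref_ids, slice(0, n_reference), cohorts_a)
    cohort_b = subset(val_ids, slice(n_reference, n_total))
    return cohort_a, cohort_b
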