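"""REML variance-component estimation and BLUP phenotype prediction.

The model is the single-random-effect linear mixed model

    y = 1_n mu + Z g + e,   g ~ N(0, G sigma2_g),   e ~ N(0, I sigma2_e),

where G is the metagenomic relationship matrix over the reference samples
and Z is the identity (one phenotype record per sample; repeated
measurements must be averaged beforehand).  Variance components are
estimated by restricted maximum likelihood, profiling out sigma2_g and
maximising over the ratio lambda = sigma2_e / sigma2_g on a log scale via
an eigendecomposition of the reference G block, so each likelihood
evaluation is O(n).  Prediction of new samples is standard BLUP:

    g_hat = G[., ref] (G_rr + lambda I)^-1 (y_r - 1 mu_hat),

with mu_hat from generalised least squares, and the predicted phenotype of
sample i is g_hat_i + mu_hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .profiles import RelationshipMatrix

__all__ = [
    "MixedModelSpec",
    "VarianceComponents",
    "PredictionResult",
    "residualize_phenotype",
    "reml_loglik",
    "reml_fit",
    "blup_predict",
    "fit_and_predict",
]

LAMBDA_MIN = 1e-6
LAMBDA_MAX = 1e6


@dataclass
class MixedModelSpec:
    """Phenotyped reference samples plus unphenotyped targets, with their G."""

    y: np.ndarray  # phenotypes of reference samples, aligned to reference_ids
    reference_ids: list[str]
    target_ids: list[str]
    G: RelationshipMatrix

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.reference_ids),):
            raise ValueError("y must align with reference_ids")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite phenotype values")
        overlap = set(self.reference_ids) & set(self.target_ids)
        if overlap:
            raise ValueError(
                f"samples in both reference and target: {sorted(overlap)[:5]}"
            )
        known = set(self.G.sample_ids)
        missing = (set(self.reference_ids) | set(self.target_ids)) - known
        if missing:
            raise ValueError(f"samples absent from G: {sorted(missing)[:5]}")


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    mu_hat: float
    lambda_: float  # sigma2_e / sigma2_g
    reml_loglik: float
    degenerate: bool = False
    n_reference: int = 0

    @property
    def m2(self) -> float:
        """Microbiability: fraction of phenotypic variance from the microbiome."""
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


@dataclass
class PredictionResult:
    sample_ids: list[str]
    g_hat: np.ndarray
    y_hat: np.ndarray  # g_hat + mu_hat
    vc: VarianceComponents
    is_target: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def predictions(self, ids: list[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return self.y_hat[[idx[s] for s in ids]]


def residualize_phenotype(y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """OLS residuals of y on (intercept, covariate).

    Used to pre-adjust phenotypes for a known driver, e.g. methane production
    corrected for dry matter intake.  Residuals sum to zero and are
    orthogonal to the covariate.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or y.size < 3:
        raise ValueError("y and covariate must be equal-length vectors, n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _spectral_parts(G_rr: np.ndarray, y_r: np.ndarray):
    """Eigendecompose G_rr and rotate y and the intercept into its basis."""
    D, U = np.linalg.eigh((G_rr + G_rr.T) / 2.0)
    return D, U.T @ y_r, U.T @ np.ones(len(y_r))


def _profile_loglik(D, ty, t1, lam: float):
    """Profiled restricted log-likelihood at variance ratio lambda.

    Returns (loglik, mu_hat, sigma2_g) with sigma2_g profiled out in closed
    form: sigma2_g = r' V0^-1 r / (n - 1), V0 = G + lambda I.
    """
    n = len(ty)
    w = D + lam
    if np.any(w <= 0):
        return -np.inf, np.nan, np.nan
    a11 = np.sum(t1**2 / w)
    a1y = np.sum(t1 * ty / w)
    ayy = np.sum(ty**2 / w)
    mu = a1y / a11
    q = ayy - a1y**2 / a11  # (y - 1 mu)' V0^-1 (y - 1 mu)
    if q <= 0:
        return -np.inf, mu, 0.0
    s2g = q / (n - 1)
    ll = -0.5 * (
        (n - 1) * (np.log(2 * np.pi * s2g) + 1) + np.sum(np.log(w)) + np.log(a11)
    )
    return ll, mu, s2g


def reml_loglik(G_rr: np.ndarray, y_r: np.ndarray, lambda_: float) -> float:
    """Restricted log-likelihood at a given lambda, sigma2_g profiled out."""
    D, ty, t1 = _spectral_parts(np.asarray(G_rr, float), np.asarray(y_r, float))
    return _profile_loglik(D, ty, t1, lambda_)[0]


def reml_fit(
    G_rr: np.ndarray,
    y_r: np.ndarray,
    lambda_bounds: tuple[float, float] = (LAMBDA_MIN, LAMBDA_MAX),
    n_grid: int = 256,
) -> VarianceComponents:
    """Estimate (sigma2_g, sigma2_e, mu) by REML for the reference block.

    The restricted likelihood is scanned on a log-lambda grid and the best
    bracket refined by bounded scalar minimisation, which is robust to the
    occasional multi-modal likelihood at small n.  Boundary solutions are
    reported with a warning: lambda at the upper bound means sigma2_g ~ 0
    (no detectable microbiome signal).
    """
    G_rr = np.asarray(G_rr, dtype=float)
    y_r = np.asarray(y_r, dtype=float)
    n = len(y_r)
    if n < 5:
        raise ValueError(f"need at least 5 reference samples, got {n}")
    if G_rr.shape != (n, n):
        raise ValueError("G_rr shape does not match y_r")
    if np.max(np.abs(G_rr - G_rr.T)) > 1e-8:
        raise ValueError("G_rr is not symmetric")
    if not np.all(np.isfinite(y_r)):
        raise ValueError("non-finite phenotypes")
    if np.ptp(y_r) == 0:
        return VarianceComponents(
            sigma2_g=0.0,
            sigma2_e=0.0,
            mu_hat=float(y_r[0]),
            lambda_=np.nan,
            reml_loglik=np.nan,
            degenerate=True,
            n_reference=n,
        )

    D, ty, t1 = _spectral_parts(G_rr, y_r)
    lo, hi = np.log(lambda_bounds[0]), np.log(lambda_bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([_profile_loglik(D, ty, t1, np.exp(t))[0] for t in grid])
    if not np.any(np.isfinite(lls)):
        raise RuntimeError("REML likelihood not finite anywhere on the grid")
    best = int(np.argmax(lls))
    left = grid[max(best - 1, 0)]
    right = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_profile_loglik(D, ty, t1, np.exp(t))[0],
        bounds=(left, right),
        method="bounded",
        options={"xatol": 1e-10},
    )
    candidates = [(lls[best], grid[best]), (-res.fun, res.x)]
    ll_opt, t_opt = max(candidates)
    lam = float(np.exp(t_opt))
    ll, mu, s2g = _profile_loglik(D, ty, t1, lam)
    if best in (0, n_grid - 1):
        warnings.warn(
            "REML solution at the lambda boundary "
            f"(lambda={lam:.3g}); sigma2_g may be effectively "
            + ("zero" if best == n_grid - 1 else "dominant"),
            RuntimeWarning,
            stacklevel=2,
        )
    return VarianceComponents(
        sigma2_g=float(s2g),
        sigma2_e=float(lam * s2g),
        mu_hat=float(mu),
        lambda_=lam,
        reml_loglik=float(ll),
        n_reference=n,
    )


def blup_predict(spec: MixedModelSpec, vc: VarianceComponents) -> PredictionResult:
    """BLUP of the microbiome effect g for reference and target samples.

    Targets never contribute to estimation: only reference phenotypes enter
    the mixed-model equations, and target predictions are formed through
    their G covariances with the reference.
    """
    all_ids = list(spec.reference_ids) + list(spec.target_ids)
    G_all_r = spec.G.block(all_ids, spec.reference_ids)
    G_rr = spec.G.block(spec.reference_ids, spec.reference_ids)
    n_ref = len(spec.reference_ids)

    if vc.degenerate or vc.sigma2_g == 0:
        mu = vc.mu_hat if np.isfinite(vc.mu_hat) else float(np.mean(spec.y))
        g_hat = np.zeros(len(all_ids))
        return PredictionResult(
            sample_ids=all_ids,
            g_hat=g_hat,
            y_hat=g_hat + mu,
            vc=vc,
            is_target=np.arange(len(all_ids)) >= n_ref,
        )

    lam = max(vc.lambda_, 0.0)
    V0 = G_rr + lam * np.eye(n_ref)
    try:
        cho = linalg.cho_factor(V0)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"G_rr + lambda I is singular at lambda={lam:.3g}; "
            "consider flooring lambda"
        ) from exc
    ones = np.ones(n_ref)
    Vi1 = linalg.cho_solve(cho, ones)
    mu = float(Vi1 @ spec.y / (Vi1 @ ones))
    g_hat = G_all_r @ linalg.cho_solve(cho, spec.y - mu)
    vc_out = VarianceComponents(
        sigma2_g=vc.sigma2_g,
        sigma2_e=vc.sigma2_e,
        mu_hat=mu,
        lambda_=vc.lambda_,
        reml_loglik=vc.reml_loglik,
        degenerate=vc.degenerate,
        n_reference=n_ref,
    )
    return PredictionResult(
        sample_ids=all_ids,
        g_hat=g_hat,
        y_hat=g_hat + mu,
        vc=vc_out,
        is_target=np.arange(len(all_ids)) >= n_ref,
    )


def fit_and_predict(
    G: RelationshipMatrix,
    reference_ids: list[str],
    y_reference: np.ndarray,
    target_ids: list[str],
) -> PredictionResult:
    """Convenience wrapper: REML on the reference block, then BLUP for all."""
    spec = MixedModelSpec(
        y=y_reference, reference_ids=reference_ids, target_ids=target_ids, G=G
    )
    vc = reml_fit(G.block(reference_ids, reference_ids), spec.y)
    return blup_predict(spec, vc)
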