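"""Synthetic physical-examination cohorts with correlated binary labels.

The hospital data behind this method are not public, so downstream code is
exercised on simulated cohorts that reproduce the reported statistical
structure: 62 grouped numeric features, three binary disease labels with
configurable marginal prevalence, weak pairwise phi correlation (maximum
pair 0.24, hypertension-fatty liver), and the resulting skewed
label-powerset distribution (isolated diabetes around 1% of records).

Labels come from a latent Gaussian copula: a trivariate standard normal
with pairwise correlations chosen (by :func:`solve_latent_correlation`) so
that thresholding each coordinate at its prevalence quantile yields binary
variables with the requested phi. This is the minimal mechanism matching
both the marginals and the pairwise correlations, which is all the label
structure the source data are characterised by.

Features are linear mean shifts on a standard-normal baseline: feature
vector = baseline N(0,1) + sum_d label_d * effect_d + N(0, noise_sd^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import (
    N_FEATURES,
    N_LABELS,
    N_LP_CLASSES,
    CohortTable,
    lp_encode,
    pmcc_matrix,
)
from .exceptions import InfeasibleCorrelationError, ValidationError

#: default marginal prevalences (H, D, FL): fatty liver balanced,
#: hypertension moderately prevalent, diabetes rare
DEFAULT_PREVALENCES = (0.35, 0.05, 0.50)

#: default pairwise phi targets; (H, FL) = 0.24 is the maximum pair
DEFAULT_TARGET_PHI = np.array(
    [
        [1.00, 0.15, 0.24],
        [0.15, 1.00, 0.10],
        [0.24, 0.10, 1.00],
    ]
)


def default_effect_sizes(magnitude: float = 0.8) -> np.ndarray:
    """Per-disease mean shifts (3 x 62), in baseline-SD units.

    Each disease shifts 12 features by `magnitude`, placed in the feature
    groups a clinician would expect to carry its signal: hypertension in
    the basic vitals and the first blood-routine items, diabetes in later
    blood-routine and urine items, fatty liver in the liver panel.
    """
    eff = np.zeros((N_LABELS, N_FEATURES))
    eff[0, 0:4] = magnitude     # basic vitals
    eff[0, 4:12] = magnitude    # blood routine (first items)
    eff[1, 12:20] = magnitude   # blood routine (glycaemic block)
    eff[1, 30:34] = magnitude   # urine routine
    eff[2, 42:54] = magnitude   # liver function panel
    return eff


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort draw."""

    n: int = 20_000
    prevalences: tuple[float, float, float] = DEFAULT_PREVALENCES
    target_phi: np.ndarray = field(default_factory=lambda: DEFAULT_TARGET_PHI.copy())
    effect_sizes: np.ndarray = field(default_factory=default_effect_sizes)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.target_phi = np.asarray(self.target_phi, dtype=float)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if self.n <= 0:
            raise ValidationError("cohort size n must be positive")
        if not all(0 < p < 1 for p in self.prevalences):
            raise ValidationError("prevalences must lie in (0, 1)")
        if self.target_phi.shape != (N_LABELS, N_LABELS):
            raise ValidationError("target_phi must be 3x3")
        if not np.allclose(self.target_phi, self.target_phi.T):
            raise ValidationError("target_phi must be symmetric")
        if not np.allclose(np.diag(self.target_phi), 1.0):
            raise ValidationError("target_phi must have a unit diagonal")
        off = self.target_phi[~np.eye(N_LABELS, dtype=bool)]
        if np.any(np.abs(off) >= 1):
            raise ValidationError("off-diagonal target_phi must lie in (-1, 1)")
        if self.effect_sizes.shape != (N_LABELS, N_FEATURES):
            raise ValidationError("effect_sizes must be 3x62")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        kwargs = dict(d)
        if "prevalences" in kwargs:
            kwargs["prevalences"] = tuple(kwargs["prevalences"])
        if "effect_magnitude" in kwargs:
            kwargs["effect_sizes"] = default_effect_sizes(kwargs.pop("effect_magnitude"))
        return cls(**kwargs)


@dataclass
class GeneratorReport:
    """Empirical summary of a cohort: margins, phi matrix, LP frequencies."""

    prevalences: np.ndarray
    phi: np.ndarray
    lp_frequencies: np.ndarray

    def to_json(self) -> dict:
        return {
            "prevalences": self.prevalences.tolist(),
            "phi": self.phi.tolist(),
            "lp_frequencies": self.lp_frequencies.tolist(),
        }


def phi_bounds(prev_a: float, prev_b: float) -> tuple[float, float]:
    """Attainable phi interval for two binary variables with given margins.

    The joint cell P(a=1, b=1) is constrained to
    [max(0, pa+pb-1), min(pa, pb)] by Frechet; phi is linear in that cell.
    """
    pa, pb = prev_a, prev_b
    denom = np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    lo = (max(0.0, pa + pb - 1.0) - pa * pb) / denom
    hi = (min(pa, pb) - pa * pb) / denom
    return float(lo), float(hi)


def _phi_of_rho(rho: float, za: float, zb: float, pa: float, pb: float) -> float:
    """Phi of the pair obtained by thresholding a bivariate normal at za, zb."""
    # P(Z1 > za, Z2 > zb) via the bivariate CDF
    cdf = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]], allow_singular=True
    ).cdf([za, zb])
    p11 = 1.0 - stats.norm.cdf(za) - stats.norm.cdf(zb) + cdf
    return (p11 - pa * pb) / np.sqrt(pa * (1 - pa) * pb * (1 - pb))


def solve_latent_correlation(
    target_phi: float, prev_a: float, prev_b: float, tol: float = 1e-4
) -> float:
    """Latent Gaussian correlation rho hitting a target phi after thresholding.

    Thresholds are the prevalence quantiles (label = 1 when the latent
    coordinate exceeds the upper prev-quantile). phi is continuous and
    strictly increasing in rho, so a bracketed root-find converges; the
    returned rho reproduces target_phi to within `tol`.

    Raises :class:`InfeasibleCorrelationError` when the target lies outside
    the phi interval the margins allow.
    """
    if not (0 < prev_a < 1 and 0 < prev_b < 1):
        raise ValidationError("prevalences must lie in (0, 1)")
    if target_phi == 0:
        return 0.0
    lo, hi = phi_bounds(prev_a, prev_b)
    if not lo < target_phi < hi:
        raise InfeasibleCorrelationError(
            f"target phi {target_phi:.4f} outside feasible interval "
            f"({lo:.4f}, {hi:.4f}) for prevalences {prev_a}, {prev_b}",
            feasible=(lo, hi),
        )
    za = stats.norm.ppf(1 - prev_a)
    zb = stats.norm.ppf(1 - prev_b)

    def f(rho: float) -> float:
        return _phi_of_rho(rho, za, zb, prev_a, prev_b) - target_phi

    from scipy.optimize import brentq

    rho = brentq(f, -0.9999, 0.9999, xtol=1e-10, rtol=1e-12)
    assert abs(f(rho)) < tol
    return float(rho)


def _nearest_correlation(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project to the nearest positive-definite matrix by eigenvalue clipping."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, eps, None)
    out = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    return (out + out.T) / 2


def latent_correlation_matrix(spec: CohortSpec) -> np.ndarray:
    """Assemble the 3x3 latent matrix from pairwise solved correlations.

    If the pairwise assembly is not positive definite it is repaired by
    projection; a repair further than Frobenius distance 0.05 raises.
    """
    rho = np.eye(N_LABELS)
    for i in range(N_LABELS):
        for j in range(i + 1, N_LABELS):
            rho[i, j] = rho[j, i] = solve_latent_correlation(
                spec.target_phi[i, j], spec.prevalences[i], spec.prevalences[j]
            )
    if np.linalg.eigvalsh(rho).min() <= 0:
        fixed = _nearest_correlation(rho)
        dist = np.linalg.norm(fixed - rho, "fro")
        if dist > 0.05:
            raise ValidationError(
                f"latent correlation matrix not repairable (Frobenius {dist:.3f})"
            )
        rho = fixed
    return rho


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a cohort: copula labels, then mean-shifted Gaussian features.

    Deterministic given ``spec.seed``: the random stream is consumed in a
    fixed order (latent labels, feature baseline, feature noise).
    """
    rng = np.random.default_rng(spec.seed)
    rho = latent_correlation_matrix(spec)
    chol = np.linalg.cholesky(rho)
    z = rng.standard_normal((spec.n, N_LABELS)) @ chol.T
    thresholds = stats.norm.ppf([1 - p for p in spec.prevalences])
    labels = (z > thresholds).astype(np.int64)

    baseline = rng.standard_normal((spec.n, N_FEATURES))
    noise = spec.noise_sd * rng.standard_normal((spec.n, N_FEATURES))
    features = baseline + labels @ spec.effect_sizes + noise
    return CohortTable(features=features, labels=labels)


def summarize_cohort(cohort: CohortTable) -> GeneratorReport:
    """Empirical margins, phi matrix, and LP class frequencies of a cohort.

    A constant label column makes its correlations undefined; the affected
    phi entries are reported as NaN rather than failing the summary.
    """
    codes = lp_encode(cohort.labels)
    freqs = np.bincount(codes, minlength=N_LP_CLASSES) / cohort.n
    if np.all(cohort.labels.std(axis=0) > 0):
        phi = pmcc_matrix(cohort.labels)
    else:
        phi = np.full((N_LABELS, N_LABELS), np.nan)
        np.fill_diagonal(phi, 1.0)
    return GeneratorReport(
        prevalences=cohort.labels.mean(axis=0),
        phi=phi,
        lp_frequencies=freqs,
    )
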