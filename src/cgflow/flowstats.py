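"""Quantification of coarse-graining flows.

A flow — real-space depths or momentum-space retained-mode fractions — is
tracked with four kinds of summaries:

* the spectral gap of the correlation matrix (largest difference between
  consecutive sorted eigenvalues; optionally normalized by the largest
  eigenvalue so cell types of different overall correlation strength are
  comparable);
* standardized fourth moments ``m4 / m2**2`` of individual variables
  (Gaussian reference 3);
* Anderson–Darling normality statistics with the small-sample adjustment
  ``A*^2 = A^2 (1 + 0.75/n + 2.25/n^2)`` for the case where mean and
  variance are estimated from the sample (5% critical value 0.752);
* per-variable marginal densities on a shared grid, summarized by their
  pointwise median and interquartile curves against a standard-normal
  reference.

The Marchenko–Pastur law provides the random-matrix baseline for the bulk
of the eigenvalue spectrum: for uncorrelated variables with aspect ratio
``gamma = N / n_obs`` the eigenvalue density is supported on
``sigma^2 (1 ± sqrt(gamma))^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional, Sequence, Union

import numpy as np
import scipy.stats

from .containers import CGState, ExpressionMatrix, variable_matrix

__all__ = [
    "spectral_gap",
    "standardized_fourth_moment",
    "anderson_darling",
    "AD_CRITICAL_5PCT",
    "MPModel",
    "mp_pdf",
    "mp_cdf",
    "mp_compare",
    "DensitySummary",
    "marginal_density_summary",
    "FlowSummary",
    "summarize_scale",
    "summarize_realspace_flow",
    "summarize_momentum_flow",
]

#: 5% critical value for the adjusted statistic A*^2, both parameters estimated
AD_CRITICAL_5PCT = 0.752

DEFAULT_GRID = np.linspace(-5.0, 5.0, 101)


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

def spectral_gap(
    eigenvalues: Sequence[float], normalized: bool = False, skip_first: bool = False
) -> float:
    """Maximum consecutive difference of descending-sorted eigenvalues.

    ``skip_first`` ignores the λ1−λ2 gap (useful when a dominant global mode
    would mask block structure). ``normalized`` divides by λ1.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    if np.any(np.diff(lam) > 1e-10):
        raise ValueError("eigenvalues must be sorted in descending order")
    diffs = lam[:-1] - lam[1:]
    if skip_first:
        if diffs.size < 2:
            raise ValueError("skip_first requires at least 3 eigenvalues")
        diffs = diffs[1:]
    gap = float(np.max(diffs))
    if normalized:
        gap /= float(lam[0])
    return gap


def standardized_fourth_moment(x: Sequence[float]) -> float:
    """Kurtosis ``m4 / m2**2`` with central sample moments; Gaussian value 3."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if x.std() == 0:
        raise ValueError("zero-variance input")
    return float(scipy.stats.kurtosis(x, fisher=False, bias=True))


def anderson_darling(x: Sequence[float], adjust: bool = True) -> float:
    """Anderson–Darling A² against normality with estimated mean/variance.

    With ``adjust``, returns ``A*^2 = A^2 (1 + 0.75/n + 2.25/n^2)``; compare
    against :data:`AD_CRITICAL_5PCT` for a 5%-level decision. Larger values
    mean stronger departure from Gaussianity.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation (all values tied)")
    w = np.sort((x - x.mean()) / sd)
    cdf = scipy.stats.norm.cdf(w)
    cdf = np.clip(cdf, 1e-300, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1]))) / n
    if adjust:
        a2 *= 1 + 0.75 / n + 2.25 / n**2
    return float(a2)


# ---------------------------------------------------------------------------
# Marchenko–Pastur baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MPModel:
    """Marchenko–Pastur eigenvalue law with aspect ratio gamma ≤ 1."""

    gamma: float
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")

    @property
    def lam_minus(self) -> float:
        return self.sigma2 * (1 - np.sqrt(self.gamma)) ** 2

    @property
    def lam_plus(self) -> float:
        return self.sigma2 * (1 + np.sqrt(self.gamma)) ** 2


def mp_pdf(lam: Union[float, np.ndarray], model: MPModel) -> Union[float, np.ndarray]:
    """MP density ``sqrt((λ+−λ)(λ−λ−)) / (2π γ σ² λ)`` on support, else 0."""
    lam = np.asarray(lam, dtype=float)
    lo, hi = model.lam_minus, model.lam_plus
    inside = (lam > lo) & (lam < hi) & (lam > 0)
    out = np.zeros_like(lam)
    lam_in = lam[inside]
    out[inside] = np.sqrt((hi - lam_in) * (lam_in - lo)) / (
        2 * np.pi * model.gamma * model.sigma2 * lam_in
    )
    return out if out.ndim else float(out)


def mp_cdf(lam: Union[float, np.ndarray], model: MPModel, _n_grid: int = 4001) -> Union[float, np.ndarray]:
    """Numerically integrated MP CDF (trapezoid on a dense support grid)."""
    lam = np.asarray(lam, dtype=float)
    grid = np.linspace(model.lam_minus, model.lam_plus, _n_grid)
    pdf = mp_pdf(grid, model)
    cum = np.concatenate(([0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))))
    if cum[-1] > 0:
        cum = cum / cum[-1]  # absorb quadrature error at the edges
    out = np.interp(lam, grid, cum, left=0.0, right=1.0)
    return out if out.ndim else float(out)


def mp_compare(
    eigenvalues: Sequence[float], n_obs: int, exclude_top_frac: float = 0.0
) -> tuple[MPModel, float]:
    """Fit an MP model to the eigenvalue bulk and report the KS distance.

    The top ``ceil(exclude_top_frac * N)`` eigenvalues are dropped; the model
    uses ``gamma = N_remaining / n_obs`` and moment-matched
    ``sigma2 = mean(remaining eigenvalues)``. Returns the model and the
    Kolmogorov–Smirnov distance between the empirical CDF of the remaining
    eigenvalues and the MP CDF.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(lam) > 1e-10):
        raise ValueError("eigenvalues must be sorted descending")
    if not 0 <= exclude_top_frac < 1:
        raise ValueError("exclude_top_frac must lie in [0, 1)")
    n_drop = ceil(exclude_top_frac * lam.size)
    rest = lam[n_drop:]
    if rest.size < 10:
        raise ValueError("fewer than 10 eigenvalues left for the MP fit")
    if rest.size > n_obs:
        raise ValueError("MP fit with gamma > 1 is not supported; need n_obs > N")
    model = MPModel(gamma=rest.size / n_obs, sigma2=float(np.mean(rest)))
    asc = np.sort(rest)
    f = np.asarray(mp_cdf(asc, model))
    i = np.arange(1, asc.size + 1)
    ks = float(np.max(np.maximum(np.abs(f - i / asc.size), np.abs(f - (i - 1) / asc.size))))
    return model, ks


# ---------------------------------------------------------------------------
# marginal densities
# ---------------------------------------------------------------------------

@dataclass
class DensitySummary:
    """Pointwise median / quartile histogram densities across variables."""

    bin_edges: np.ndarray
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    gaussian: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def marginal_density_summary(
    data: "ExpressionMatrix | CGState | np.ndarray",
    grid: Optional[np.ndarray] = None,
) -> DensitySummary:
    """Per-variable histogram densities on a shared grid with ensemble summary."""
    x = variable_matrix(data)
    edges = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if edges.size < 2:
        raise ValueError("grid must have at least 2 bin edges")
    dens = np.stack([np.histogram(row, bins=edges, density=True)[0] for row in x])
    centers = (edges[:-1] + edges[1:]) / 2
    return DensitySummary(
        bin_edges=edges,
        median=np.median(dens, axis=0),
        q25=np.quantile(dens, 0.25, axis=0),
        q75=np.quantile(dens, 0.75, axis=0),
        gaussian=scipy.stats.norm.pdf(centers),
    )


# ---------------------------------------------------------------------------
# per-scale flow summary
# ---------------------------------------------------------------------------

@dataclass
class FlowSummary:
    """All tracked statistics of one scale of a flow."""

    scale_label: Union[int, float, str]
    n_variables: int
    spectral_gap: Optional[float]
    spectral_gap_normalized: Optional[float]
    eigenvalues: Optional[np.ndarray]
    kurtosis_per_variable: np.ndarray
    ad_stat_per_variable: np.ndarray
    marginal_density: DensitySummary
    extra: dict = field(default_factory=dict)

    @property
    def median_kurtosis(self) -> float:
        return float(np.median(self.kurtosis_per_variable))

    @property
    def median_ad(self) -> float:
        return float(np.median(self.ad_stat_per_variable))

    def ad_rejection_rate(self, critical: float = AD_CRITICAL_5PCT) -> float:
        return float(np.mean(self.ad_stat_per_variable > critical))

    def to_dict(self) -> dict:
        return {
            "scale_label": self.scale_label,
            "n_variables": self.n_variables,
            "spectral_gap": self.spectral_gap,
            "spectral_gap_normalized": self.spectral_gap_normalized,
            "eigenvalues": None if self.eigenvalues is None else list(map(float, self.eigenvalues)),
            "median_kurtosis": self.median_kurtosis,
            "median_ad": self.median_ad,
            "ad_rejection_rate_5pct": self.ad_rejection_rate(),
            "kurtosis_per_variable": list(map(float, self.kurtosis_per_variable)),
            "ad_stat_per_variable": list(map(float, self.ad_stat_per_variable)),
            "density_bin_edges": list(map(float, self.marginal_density.bin_edges)),
            "density_median": list(map(float, self.marginal_density.median)),
            "density_q25": list(map(float, self.marginal_density.q25)),
            "density_q75": list(map(float, self.marginal_density.q75)),
            **self.extra,
        }


def summarize_scale(
    data: "ExpressionMatrix | CGState | np.ndarray",
    scale_label: Union[int, float, str],
    *,
    restandardize: bool = False,
    grid: Optional[np.ndarray] = None,
    skip_first_gap: bool = False,
) -> FlowSummary:
    """Compute the full statistics bundle for one scale.

    ``restandardize`` rescales each variable to mean 0 / unit variance before
    the per-variable moments and densities (used for momentum-space scales,
    where projection changes variances).
    """
    from .momentum import eigendecompose  # local import avoids cycle
    from .realspace import correlation_matrix

    x = variable_matrix(data)
    if restandardize:
        sd = x.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero-variance variable; cannot restandardize")
        x = (x - x.mean(axis=1, keepdims=True)) / sd
    gap = gap_norm = None
    eigenvalues = None
    if x.shape[0] >= 2:
        spec = eigendecompose(correlation_matrix(x))
        eigenvalues = spec.eigenvalues
        gap = spectral_gap(eigenvalues, normalized=False, skip_first=skip_first_gap)
        gap_norm = spectral_gap(eigenvalues, normalized=True, skip_first=skip_first_gap)
    kurt = np.array([standardized_fourth_moment(row) for row in x])
    ad = np.array([anderson_darling(row) for row in x])
    return FlowSummary(
        scale_label=scale_label,
        n_variables=x.shape[0],
        spectral_gap=gap,
        spectral_gap_normalized=gap_norm,
        eigenvalues=eigenvalues,
        kurtosis_per_variable=kurt,
        ad_stat_per_variable=ad,
        marginal_density=marginal_density_summary(x, grid),
    )


def summarize_realspace_flow(states: Sequence[CGState], **kwargs) -> list[FlowSummary]:
    """One summary per depth of a real-space flow."""
    return [summarize_scale(s, scale_label=s.depth, **kwargs) for s in states]


def summarize_momentum_flow(
    flow: Sequence[tuple[float, ExpressionMatrix]], **kwargs
) -> list[FlowSummary]:
    """One summary per retained fraction; variables are re-standardized."""
    return [
        summarize_scale(e, scale_label=f, restandardize=True, **kwargs) for f, e in flow
    ]
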