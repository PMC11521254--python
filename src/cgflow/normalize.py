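"""Analytic Pearson-residual normalization of count matrices.

Counts are modelled as negative binomial, ``X_cg ~ NB(mu_cg, theta)`` with a
shared dispersion ``theta``. The mean is estimated analytically from the
margins under the Poisson approximation,

    mu_hat_cg = (sum_j X_cj) (sum_i X_ig) / (sum_ij X_ij),

and the residual z-score is

    Z_cg = (X_cg - mu_hat_cg) / sqrt(mu_hat_cg + mu_hat_cg**2 / theta).

With ``theta -> inf`` this reduces to the Poisson Pearson residual. The
default ``theta = 50`` is an ad hoc choice appropriate for droplet-scale
sample sizes; it is exposed on :class:`NormalizationParams`.

Residuals are returned genes × cells (variables as rows). ``standardize``
then rescales every gene row to mean 0 and unit *sample* variance (n−1
denominator, used consistently with the correlation estimator downstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix

__all__ = [
    "NormalizationParams",
    "estimate_mean",
    "pearson_residuals",
    "standardize",
    "write_expression",
    "read_expression",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Negative-binomial residual parameters.

    theta
        NB dispersion; variance is ``mu + mu**2/theta``. Must be positive.
    clip
        Optional symmetric truncation of residuals to ``[-clip, +clip]``.
        Default None (no clipping).
    """

    theta: float = 50.0
    clip: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError("theta must be positive")
        if self.clip is not None and not self.clip > 0:
            raise ValueError("clip must be positive when set")


def estimate_mean(m: CountMatrix) -> np.ndarray:
    """Margin-product mean estimate, cells × genes.

    ``mu_hat_cg = cell_total_c * gene_total_g / grand_total``.
    """
    counts = m.counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot estimate means from an all-zero count matrix")
    cell_totals = counts.sum(axis=1, keepdims=True).astype(float)
    gene_totals = counts.sum(axis=0, keepdims=True).astype(float)
    return cell_totals * gene_totals / float(total)


def pearson_residuals(m: CountMatrix, p: NormalizationParams = NormalizationParams()) -> ExpressionMatrix:
    """Analytic Pearson residuals, transposed to genes × cells."""
    mu = estimate_mean(m)
    zero = mu <= 0
    if zero.any():
        c, g = np.argwhere(zero)[0]
        raise ValueError(
            f"zero estimated mean for cell {m.cell_ids[c]!r} / gene {m.gene_ids[g]!r}; "
            "run QC to remove all-zero cells and genes first"
        )
    z = (m.counts - mu) / np.sqrt(mu + mu**2 / p.theta)
    if p.clip is not None:
        z = np.clip(z, -p.clip, p.clip)
    return ExpressionMatrix(z.T, list(m.gene_ids), list(m.cell_ids), standardized=False)


def standardize(e: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene row to mean 0, sample variance 1 (ddof=1)."""
    values = e.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"gene {e.gene_ids[flat[0]]!r} has zero variance; cannot standardize")
    return ExpressionMatrix(
        (values - mean) / sd, list(e.gene_ids), list(e.cell_ids), standardized=True
    )


def write_expression(e: ExpressionMatrix, path: str | Path) -> Path:
    """Write a genes × cells expression matrix to TSV (genes as rows)."""
    path = Path(path)
    pd.DataFrame(e.values, index=e.gene_ids, columns=e.cell_ids).to_csv(path, sep="\t")
    return path


def read_expression(path: str | Path, standardized: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)), standardized
    )
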