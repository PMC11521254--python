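"""Momentum-space coarse-graining: projection onto top correlation eigenmodes.

The correlation matrix C of the standardized variables (for unit-variance
variables correlation and covariance coincide) is eigendecomposed,

    sum_j C_ij v_j(lam_K) = lam_K v_i(lam_K),

eigenvalues sorted descending. Coarse-graining zeroes the loadings of
low-variance modes: with K* modes retained the projector is

    P_ij = sum_{K<=K*} u_i(lam_K) u_j(lam_K)

and the data flow is Y -> P Y across the variable index. An optional
``exclude_top_frac`` removes the very largest modes from consideration
before the flow (their loadings are zeroed as well), mirroring the
convention of discarding a dominant global mode before fitting noise
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
import scipy.linalg

from .containers import CorrelationMatrix, EigenSpectrum, ExpressionMatrix

__all__ = [
    "eigendecompose",
    "ModeProjector",
    "project_top_modes",
    "momentum_flow",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = tuple(np.round(np.arange(1.0, 0.05, -0.1), 10))


def eigendecompose(c: CorrelationMatrix | np.ndarray) -> EigenSpectrum:
    """Full spectrum in descending order with a deterministic sign convention.

    Each eigenvector is flipped so its largest-magnitude entry is positive,
    making flows reproducible across linear-algebra backends.
    """
    values = c.values if isinstance(c, CorrelationMatrix) else np.asarray(c, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("input matrix is not symmetric")
    lam, vec = scipy.linalg.eigh((values + values.T) / 2.0)
    lam, vec = lam[::-1].copy(), vec[:, ::-1].copy()
    flip = np.sign(vec[np.argmax(np.abs(vec), axis=0), np.arange(vec.shape[1])])
    flip[flip == 0] = 1.0
    vec *= flip
    return EigenSpectrum(lam, vec)


@dataclass
class ModeProjector:
    """Rank-``K_star`` projector built from retained eigenvector columns."""

    K_star: int
    basis: np.ndarray  # N × K_star

    def matrix(self) -> np.ndarray:
        return self.basis @ self.basis.T

    def apply(self, values: np.ndarray) -> np.ndarray:
        return self.basis @ (self.basis.T @ values)


def project_top_modes(
    e: ExpressionMatrix, spec: EigenSpectrum, K_star: int
) -> ExpressionMatrix:
    """Project the data onto the span of the top ``K_star`` eigenmodes.

    No rescaling is applied: retained-mode variance is preserved and
    discarded-mode variance removed, so the output is not standardized.
    """
    n = e.n_genes
    if spec.eigenvectors.shape[0] != n:
        raise ValueError("spectrum and expression matrix have different variable counts")
    if not 1 <= K_star <= n:
        raise ValueError(f"K_star must lie in [1, {n}]")
    proj = ModeProjector(K_star, spec.eigenvectors[:, :K_star])
    return ExpressionMatrix(
        proj.apply(e.values), list(e.gene_ids), list(e.cell_ids), standardized=False
    )


def momentum_flow(
    e: ExpressionMatrix,
    retained_fractions: Sequence[float] = DEFAULT_FRACTIONS,
    exclude_top_frac: float = 0.0,
) -> list[tuple[float, ExpressionMatrix]]:
    """Flow of projections retaining progressively fewer top modes.

    For each fraction ``f`` the top ``ceil(f * N_remaining)`` modes are
    retained, where ``N_remaining`` excludes the top
    ``ceil(exclude_top_frac * N)`` modes, which are zeroed throughout.
    """
    if not 0 <= exclude_top_frac < 1:
        raise ValueError("exclude_top_frac must lie in [0, 1)")
    from .realspace import correlation_matrix  # local import avoids cycle

    if not e.standardized:
        raise ValueError("momentum flow requires a standardized expression matrix")
    spec = eigendecompose(correlation_matrix(e))
    n = e.n_genes
    n_excl = ceil(exclude_top_frac * n)
    n_rem = n - n_excl
    out: list[tuple[float, ExpressionMatrix]] = []
    for f in retained_fractions:
        if not 0 < f <= 1:
            raise ValueError(f"retained fraction {f} outside (0, 1]")
        k = ceil(f * n_rem)
        if k < 1:
            raise ValueError(f"fraction {f} retains zero modes")
        basis = spec.eigenvectors[:, n_excl : n_excl + k]
        proj = ModeProjector(k, basis)
        out.append(
            (
                float(f),
                ExpressionMatrix(
                    proj.apply(e.values), list(e.gene_ids), list(e.cell_ids), standardized=False
                ),
            )
        )
    return out
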