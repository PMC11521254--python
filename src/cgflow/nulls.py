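"""Marginally resampled null models.

Shuffling each gene independently across cells preserves every marginal
distribution exactly while destroying all inter-gene correlation. Running
the coarse-graining flows on such data establishes the baseline behaviour
expected in the absence of genetic correlations: real-space metagenes are
sums of independent variables and converge to Gaussians by the central
limit theorem, and the eigenvalue spectrum follows the Marchenko–Pastur
random-matrix law.

Each gene draws its permutation from an independent substream keyed by
``(seed, replicate, gene index)``, so results do not depend on evaluation
order and replicates are independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .containers import ExpressionMatrix
from .flowstats import (
    AD_CRITICAL_5PCT,
    FlowSummary,
    summarize_momentum_flow,
    summarize_realspace_flow,
)
from .momentum import DEFAULT_FRACTIONS, momentum_flow
from .realspace import realspace_flow

__all__ = ["NullSpec", "marginal_resample", "null_baseline", "NullBaseline"]


@dataclass(frozen=True)
class NullSpec:
    """Seed and replicate count for a marginal-resampling null ensemble."""

    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")


def marginal_resample(
    e: ExpressionMatrix, spec: "NullSpec | int", replicate: int = 0
) -> ExpressionMatrix:
    """Independently permute each gene row across cells (exact marginals)."""
    seed = spec.seed if isinstance(spec, NullSpec) else int(spec)
    if e.n_genes < 2:
        raise ValueError("need at least 2 variables for a meaningful null")
    out = np.empty_like(e.values)
    n = e.n_cells
    for g in range(e.n_genes):
        rng = np.random.default_rng([seed, replicate, g])
        out[g] = e.values[g, rng.permutation(n)]
    return ExpressionMatrix(out, list(e.gene_ids), list(e.cell_ids), e.standardized)


@dataclass
class NullBaseline:
    """Null-flow summaries: per-replicate and aggregated across replicates."""

    spec: NullSpec
    flow: str
    replicate_summaries: list[list[FlowSummary]]

    @property
    def scale_labels(self) -> list:
        return [s.scale_label for s in self.replicate_summaries[0]]

    def pooled(self, attr: str) -> list[np.ndarray]:
        """Per-scale pooled per-variable statistics across replicates."""
        out = []
        for i in range(len(self.replicate_summaries[0])):
            out.append(
                np.concatenate([rep[i].__getattribute__(attr) for rep in self.replicate_summaries])
            )
        return out

    def median_kurtosis(self) -> list[float]:
        return [float(np.median(v)) for v in self.pooled("kurtosis_per_variable")]

    def ad_rejection_rate(self, critical: float = AD_CRITICAL_5PCT) -> list[float]:
        return [float(np.mean(v > critical)) for v in self.pooled("ad_stat_per_variable")]

    def median_gap_normalized(self) -> list[Optional[float]]:
        out = []
        for i in range(len(self.replicate_summaries[0])):
            gaps = [rep[i].spectral_gap_normalized for rep in self.replicate_summaries]
            out.append(None if gaps[0] is None else float(np.median([g for g in gaps])))
        return out


def null_baseline(
    e: ExpressionMatrix,
    spec: NullSpec,
    flow: Literal["realspace", "momentum"] = "realspace",
    *,
    max_depth: Optional[int] = None,
    retained_fractions: Sequence[float] = DEFAULT_FRACTIONS,
    exclude_top_frac: float = 0.0,
    mode: str = "signed",
) -> NullBaseline:
    """Run the chosen flow on each resampled replicate and summarize.

    The scale structure mirrors the corresponding flow on the real data, so
    real and null summaries can be compared scale by scale.
    """
    reps: list[list[FlowSummary]] = []
    for r in range(spec.n_replicates):
        resampled = marginal_resample(e, spec, replicate=r)
        if flow == "realspace":
            states = realspace_flow(resampled, max_depth=max_depth, mode=mode)
            reps.append(summarize_realspace_flow(states))
        elif flow == "momentum":
            mflow = momentum_flow(resampled, retained_fractions, exclude_top_frac)
            reps.append(summarize_momentum_flow(mflow))
        else:
            raise ValueError(f"unknown flow {flow!r}")
    return NullBaseline(spec=spec, flow=flow, replicate_summaries=reps)
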