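"""Model/Results interface to the coarse-graining flows.

The two flows are exposed as model objects in the statsmodels idiom: a
model is constructed from data, ``fit()`` runs the flow and returns a
results object carrying the per-scale statistics, a ``summary()`` table,
and plotting helpers. The functional machinery lives in
:mod:`cgflow.realspace`, :mod:`cgflow.momentum`, :mod:`cgflow.flowstats`
and :mod:`cgflow.nulls`; these classes orchestrate it.

Example
-------
>>> from cgflow import simulate, normalize, RealSpaceFlow
>>> counts, labels = simulate.generate_block_counts(simulate.SyntheticSpec(seed=1))
>>> expr = normalize.standardize(normalize.pearson_residuals(counts))
>>> res = RealSpaceFlow(expr, max_depth=4).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix
from .flowstats import (
    FlowSummary,
    summarize_momentum_flow,
    summarize_realspace_flow,
)
from .momentum import DEFAULT_FRACTIONS, momentum_flow
from .normalize import NormalizationParams, pearson_residuals, standardize
from .nulls import NullBaseline, NullSpec, null_baseline
from .realspace import realspace_flow

__all__ = ["RealSpaceFlow", "MomentumFlow", "FlowResults"]


def _prepare(data, theta: float) -> ExpressionMatrix:
    if isinstance(data, CountMatrix):
        return standardize(pearson_residuals(data, NormalizationParams(theta=theta)))
    if isinstance(data, ExpressionMatrix):
        return data if data.standardized else standardize(data)
    raise TypeError("data must be a CountMatrix or ExpressionMatrix")


class FlowResults:
    """Per-scale statistics of a fitted coarse-graining flow.

    Attributes
    ----------
    summaries
        One :class:`~cgflow.flowstats.FlowSummary` per scale.
    null
        Optional :class:`~cgflow.nulls.NullBaseline` attached by
        ``fit(null_replicates=...)``.
    """

    def __init__(self, model, summaries: list[FlowSummary], null: Optional[NullBaseline] = None):
        self.model = model
        self.summaries = summaries
        self.null = null

    @property
    def scale_labels(self) -> list:
        return [s.scale_label for s in self.summaries]

    def summary(self) -> pd.DataFrame:
        """Tabulate gap, kurtosis and AD statistics per scale."""
        rows = []
        for s in self.summaries:
            row = {
                "scale": s.scale_label,
                "n_variables": s.n_variables,
                "spectral_gap": s.spectral_gap,
                "spectral_gap_norm": s.spectral_gap_normalized,
                "median_kurtosis": s.median_kurtosis,
                "median_AD": s.median_ad,
                "AD_reject_5pct": s.ad_rejection_rate(),
            }
            rows.append(row)
        df = pd.DataFrame(rows).set_index("scale")
        if self.null is not None:
            df["null_median_kurtosis"] = self.null.median_kurtosis()
            df["null_AD_reject_5pct"] = self.null.ad_rejection_rate()
        return df

    def to_dicts(self) -> list[dict]:
        return [s.to_dict() for s in self.summaries]

    # -- plotting -----------------------------------------------------------
    def plot_spectra(self, ax=None):
        """Eigenvalue spectra per scale (log y)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in self.summaries:
            if s.eigenvalues is not None:
                ax.plot(np.arange(1, s.eigenvalues.size + 1), s.eigenvalues,
                        marker=".", lw=0.8, label=f"scale {s.scale_label}")
        ax.set(xlabel="rank", ylabel="eigenvalue", yscale="log")
        ax.legend(fontsize="small")
        return ax

    def plot_densities(self, ax=None):
        """Median marginal density per scale against the Gaussian reference."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for s in self.summaries:
            d = s.marginal_density
            ax.plot(d.centers, d.median, lw=1.0, label=f"scale {s.scale_label}")
        d0 = self.summaries[0].marginal_density
        ax.plot(d0.centers, d0.gaussian, "k-", lw=1.5, label="Gaussian")
        ax.set(xlabel="standardized expression", ylabel="density", yscale="log")
        ax.set_ylim(bottom=1e-4)
        ax.legend(fontsize="small")
        return ax


class RealSpaceFlowResults(FlowResults):
    """Adds access to the coarse-grained states and memberships."""

    def __init__(self, model, states, summaries, null=None):
        super().__init__(model, summaries, null)
        self.states = states

    def membership(self, depth: int) -> dict[int, frozenset[int]]:
        for s in self.states:
            if s.depth == depth:
                return s.membership
        raise KeyError(f"no state at depth {depth}")


class _FlowModel:
    """Shared constructor logic: accepts counts, residuals or a DataFrame."""

    def __init__(self, data, *, theta: float = 50.0):
        self.exog = _prepare(data, theta)
        self.theta = theta

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, counts: bool = True, **kwargs):
        """Build from a cells × genes DataFrame (index cells, columns genes)."""
        if counts:
            data = CountMatrix(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))
        else:
            data = ExpressionMatrix(
                df.to_numpy().T, list(df.columns.astype(str)), list(df.index.astype(str))
            )
        return cls(data, **kwargs)


class RealSpaceFlow(_FlowModel):
    """Real-space coarse-graining model.

    Parameters
    ----------
    data
        CountMatrix (normalized internally with dispersion ``theta``),
        ExpressionMatrix, or via :meth:`from_dataframe`.
    max_depth
        Deepest coarse-graining iteration; None runs until one variable.
    mode
        ``"signed"`` (default) pairs by largest correlation; ``"absolute"``
        by largest magnitude.
    """

    def __init__(self, data, max_depth: Optional[int] = None, mode: str = "signed",
                 *, theta: float = 50.0, keep_leftover: bool = False):
        super().__init__(data, theta=theta)
        self.max_depth = max_depth
        self.mode = mode
        self.keep_leftover = keep_leftover

    def fit(self, *, null_replicates: int = 0, null_seed: int = 0) -> RealSpaceFlowResults:
        states = realspace_flow(
            self.exog, max_depth=self.max_depth, mode=self.mode,
            keep_leftover=self.keep_leftover,
        )
        summaries = summarize_realspace_flow(states)
        null = None
        if null_replicates > 0:
            null = null_baseline(
                self.exog, NullSpec(null_seed, null_replicates), "realspace",
                max_depth=self.max_depth, mode=self.mode,
            )
        return RealSpaceFlowResults(self, states, summaries, null)


class MomentumFlow(_FlowModel):
    """Momentum-space coarse-graining model (top-eigenmode projection)."""

    def __init__(self, data, retained_fractions: Sequence[float] = DEFAULT_FRACTIONS,
                 exclude_top_frac: float = 0.0, *, theta: float = 50.0):
        super().__init__(data, theta=theta)
        self.retained_fractions = list(retained_fractions)
        self.exclude_top_frac = exclude_top_frac

    def fit(self, *, null_replicates: int = 0, null_seed: int = 0) -> FlowResults:
        flow = momentum_flow(self.exog, self.retained_fractions, self.exclude_top_frac)
        summaries = summarize_momentum_flow(flow)
        null = None
        if null_replicates > 0:
            null = null_baseline(
                self.exog, NullSpec(null_seed, null_replicates), "momentum",
                retained_fractions=self.retained_fractions,
                exclude_top_frac=self.exclude_top_frac,
            )
        res = FlowResults(self, summaries, null)
        res.projections = flow
        return res
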