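"""Real-space coarse-graining: greedy correlation pairing into metagenes.

By analogy with Kadanoff block spins, correlation strength plays the role of
spatial proximity: at each depth the sample correlation matrix of the current
(meta)genes is computed once, the maximally correlated pair is found, then
the next most correlated pair among the untouched variables, and so on down
the ranked list. Each pair is replaced by its entrywise sum rescaled to mean
0 and unit sample variance (equal footing across resolutions). Iterating
from N variables yields ⌊N/2^k⌋ metagenes at depth k; with an odd count the
unpaired leftover is dropped by default so the schedule holds exactly.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np

from .containers import CGState, CorrelationMatrix, ExpressionMatrix, variable_ids, variable_matrix

__all__ = [
    "correlation_matrix",
    "greedy_pair",
    "coarse_grain_step",
    "realspace_flow",
    "initial_state",
]

PairMode = Literal["signed", "absolute"]

_CHUNK = 1_000_000


def correlation_matrix(data: "ExpressionMatrix | CGState | np.ndarray") -> CorrelationMatrix:
    """Pearson sample correlation across cells (variables as rows)."""
    x = variable_matrix(data)
    ids = variable_ids(data)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 variables for a correlation matrix")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 observations per variable")
    sd = x.std(axis=1, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"variable {ids[flat[0]]!r} has zero variance")
    c = np.corrcoef(x)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(c, ids)


def greedy_pair(
    c: CorrelationMatrix | np.ndarray, mode: PairMode = "signed"
) -> tuple[list[tuple[int, int]], Optional[int]]:
    """Disjoint pairs by repeated argmax over the fixed correlation matrix.

    Equivalent to walking the globally ranked list of off-diagonal entries
    (the matrix is not recomputed between selections within a depth). Ties
    break to the lexicographically smallest ``(i, j)``, ``i < j``. With an
    odd variable count exactly one leftover index is returned.
    """
    values = c.values if isinstance(c, CorrelationMatrix) else np.asarray(c, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 variables to pair")
    iu, ju = np.triu_indices(n, k=1)
    vals = values[iu, ju]
    if mode == "absolute":
        vals = np.abs(vals)
    elif mode != "signed":
        raise ValueError(f"unknown pairing mode {mode!r}")
    # primary: value descending; then i, then j ascending
    order = np.lexsort((ju, iu, -vals))
    used = np.zeros(n, dtype=bool)
    pairs: list[tuple[int, int]] = []
    target = n // 2
    for start in range(0, order.size, _CHUNK):
        chunk = order[start : start + _CHUNK]
        ci, cj = iu[chunk], ju[chunk]
        keep = ~(used[ci] | used[cj])  # prefilter; selection stays sequential
        for a, b in zip(ci[keep].tolist(), cj[keep].tolist()):
            if used[a] or used[b]:
                continue
            used[a] = used[b] = True
            pairs.append((a, b))
            if len(pairs) == target:
                break
        if len(pairs) == target:
            break
    leftover = int(np.flatnonzero(~used)[0]) if n % 2 else None
    return pairs, leftover


def initial_state(e: ExpressionMatrix) -> CGState:
    """Depth-0 state: every gene is its own metagene."""
    if not e.standardized:
        raise ValueError("real-space flow requires a standardized expression matrix")
    return CGState(
        e.values.copy(),
        {i: frozenset({i}) for i in range(e.n_genes)},
        depth=0,
        variable_ids=list(e.gene_ids),
    )


def coarse_grain_step(
    s: CGState, mode: PairMode = "signed", *, keep_leftover: bool = False
) -> CGState:
    """One pairing-and-averaging iteration.

    Each paired metagene is the entrywise sum of its two parent rows,
    recentered to mean 0 (guards float drift; the sum of zero-mean rows is
    already zero-mean analytically) and rescaled to unit sample variance.
    The odd leftover is dropped unless ``keep_leftover``.
    """
    if s.n_variables < 2:
        raise ValueError("cannot coarse-grain fewer than 2 variables")
    corr = correlation_matrix(s)
    pairs, leftover = greedy_pair(corr, mode)
    rows = []
    membership: dict[int, frozenset[int]] = {}
    for k, (a, b) in enumerate(pairs):
        summed = s.expression[a] + s.expression[b]
        summed = summed - summed.mean()
        sd = summed.std(ddof=1)
        if sd == 0:
            raise ValueError(
                f"pair ({a}, {b}) sums to a zero-variance metagene "
                "(perfectly anticorrelated parents)"
            )
        rows.append(summed / sd)
        membership[k] = s.membership[a] | s.membership[b]
    if keep_leftover and leftover is not None:
        rows.append(s.expression[leftover].copy())
        membership[len(pairs)] = s.membership[leftover]
    return CGState(np.vstack(rows), membership, depth=s.depth + 1)


def realspace_flow(
    e: ExpressionMatrix,
    max_depth: Optional[int] = None,
    mode: PairMode = "signed",
    *,
    keep_leftover: bool = False,
) -> list[CGState]:
    """Full flow: states at depths 0..max_depth (or until one variable is left)."""
    states = [initial_state(e)]
    while states[-1].n_variables >= 2:
        if max_depth is not None and states[-1].depth >= max_depth:
            break
        states.append(coarse_grain_step(states[-1], mode, keep_leftover=keep_leftover))
    return states
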