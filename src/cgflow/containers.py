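"""Core in-memory containers shared across the package.

The canonical internal orientation is *variables as rows*: a raw
:class:`CountMatrix` is cells × genes (as sequenced), while every
normalized :class:`ExpressionMatrix` and coarse-grained :class:`CGState`
is genes (or metagenes) × cells, so that each row is one random variable
observed across the cell ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "CGState",
    "CorrelationMatrix",
    "EigenSpectrum",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class CountMatrix:
    """Raw non-negative integer counts, cells × genes.

    Parameters
    ----------
    counts
        Integer array of shape ``(n_cells, n_genes)``.
    cell_ids, gene_ids
        Unique row / column identifiers.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts contain non-integer entries")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise ValueError("counts contain negative entries")
        self.counts = counts
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.gene_ids)} genes"
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountMatrix({self.n_cells} cells × {self.n_genes} genes)"


@dataclass
class ExpressionMatrix:
    """Real-valued normalized expression, genes × cells.

    ``standardized`` is True once every gene row has been scaled to mean 0
    and unit sample variance (n−1 denominator).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.values = values
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        if values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"expression shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.cell_ids)} cells"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = "standardized" if self.standardized else "raw residuals"
        return f"ExpressionMatrix({self.n_genes} genes × {self.n_cells} cells, {tag})"


@dataclass
class CGState:
    """One depth of a real-space coarse-graining flow.

    ``membership`` maps each metagene row index to the set of *original*
    (depth-0) gene indices averaged into it. Membership sets are disjoint;
    genes dropped as odd leftovers simply stop appearing.
    """

    expression: np.ndarray  # metagenes × cells
    membership: dict[int, frozenset[int]]
    depth: int
    variable_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.ndim != 2:
            raise ValueError("expression must be 2-D")
        if set(self.membership) != set(range(self.expression.shape[0])):
            raise ValueError("membership keys must index every metagene row")
        seen: set[int] = set()
        for members in self.membership.values():
            if seen & set(members):
                raise ValueError("membership sets overlap")
            seen |= set(members)
        if not self.variable_ids:
            self.variable_ids = [f"mg{self.depth}_{i}" for i in range(self.n_variables)]

    @property
    def n_variables(self) -> int:
        return self.expression.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expression.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CGState(depth={self.depth}, {self.n_variables} metagenes × {self.n_cells} cells)"


@dataclass
class CorrelationMatrix:
    """Pearson sample correlation matrix with unit diagonal."""

    values: np.ndarray
    variable_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        self.values = values
        if len(self.variable_ids) != values.shape[0]:
            raise ValueError("variable_ids length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class EigenSpectrum:
    """Eigenvalues (descending) and matching orthonormal eigenvectors.

    Column ``k`` of ``eigenvectors`` pairs with ``eigenvalues[k]``. Sign
    convention: the largest-magnitude entry of each eigenvector is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n(self) -> int:
        return self.eigenvalues.size


def variable_matrix(data: "ExpressionMatrix | CGState | np.ndarray") -> np.ndarray:
    """Return the underlying variables × observations array."""
    if isinstance(data, ExpressionMatrix):
        return data.values
    if isinstance(data, CGState):
        return data.expression
    return np.asarray(data, dtype=float)


def variable_ids(data: "ExpressionMatrix | CGState | np.ndarray") -> list[str]:
    if isinstance(data, ExpressionMatrix):
        return data.gene_ids
    if isinstance(data, CGState):
        return data.variable_ids
    return [f"v{i}" for i in range(np.asarray(data).shape[0])]
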