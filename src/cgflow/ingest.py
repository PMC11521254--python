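"""Reading, writing and quality control of count matrices.

Supported on-disk formats:

* MatrixMarket coordinate triplets (10x dialect): ``matrix.mtx`` with
  ``genes.tsv``/``features.tsv`` and ``barcodes.tsv`` sidecars in the same
  directory, plain or gzipped. The 10x convention stores genes × cells;
  ``transpose=True`` (default for mtx) converts to cells × genes.
* Dense CSV/TSV with one header row of gene ids and one index column of
  cell ids, cells × genes.

QC follows the detection-based convention: a gene counts as "found" in a
cell when its count is strictly positive, genes are kept when detected in
at least ``min_gene_cell_frac`` of cells (inclusive), cells are kept when
their total count is at least ``min_cell_total`` (inclusive). Cells are
filtered first, then genes, in a single pass by default.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "filter_qc",
    "intersect_gene_sets",
]

_GENE_SIDECARS = ("genes.tsv", "genes.tsv.gz", "features.tsv", "features.tsv.gz")
_BARCODE_SIDECARS = ("barcodes.tsv", "barcodes.tsv.gz")


def _find_sidecar(directory: Path, candidates: Sequence[str]) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"no sidecar file among {candidates!r} next to matrix in {directory}"
    )


def _read_tsv_column(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(path: str | Path, format: str | None = None, *, transpose: bool | None = None) -> CountMatrix:
    """Read a count matrix from ``path``.

    Parameters
    ----------
    path
        For ``mtx``, the ``.mtx``/``.mtx.gz`` file (sidecars are looked up in
        its directory). For ``csv``/``tsv``, the dense table.
    format
        One of ``{"mtx", "csv", "tsv"}``; inferred from the suffix if omitted.
    transpose
        Whether the on-disk matrix is genes × cells and must be transposed to
        the cells × genes convention. Defaults to True for mtx (10x dialect)
        and False for dense tables.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        suffixes = "".join(path.suffixes)
        if ".mtx" in suffixes:
            format = "mtx"
        elif ".csv" in suffixes:
            format = "csv"
        elif ".tsv" in suffixes or ".txt" in suffixes:
            format = "tsv"
        else:
            raise ValueError(f"cannot infer format from {path.name!r}")
    format = format.lower()

    if format == "mtx":
        mat = scipy.io.mmread(str(path))
        dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        gene_ids = _read_tsv_column(_find_sidecar(path.parent, _GENE_SIDECARS))
        cell_ids = _read_tsv_column(_find_sidecar(path.parent, _BARCODE_SIDECARS))
        if transpose is None:
            transpose = True
        if transpose:
            dense = dense.T  # 10x stores genes × cells
        if dense.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match sidecars "
                f"({len(cell_ids)} barcodes, {len(gene_ids)} genes)"
            )
        return CountMatrix(dense, cell_ids, gene_ids)

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy()
        if transpose:
            df = df.T
            values = df.to_numpy()
        return CountMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))

    raise ValueError(f"unknown format {format!r}")


def write_counts(m: CountMatrix, path: str | Path, format: str = "mtx") -> Path:
    """Write ``m`` in the given format; mtx emits 10x-style sidecars."""
    path = Path(path)
    format = format.lower()
    if format == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.counts.T))
        (path.parent / "genes.tsv").write_text(
            "".join(f"{g}\t{g}\n" for g in m.gene_ids)
        )
        (path.parent / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
        return path
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(m.counts, index=m.cell_ids, columns=m.gene_ids)
        df.to_csv(path, sep=sep)
        return path
    raise ValueError(f"unknown format {format!r}")


def filter_qc(
    m: CountMatrix,
    min_gene_cell_frac: float = 0.05,
    min_cell_total: int = 5,
    *,
    cell_metric: str = "total_counts",
    iterate: bool = False,
) -> CountMatrix:
    """Apply detection/depth QC filters.

    Cells with total count (or detected-gene count when
    ``cell_metric="detected_genes"``) below ``min_cell_total`` are dropped
    first; then genes detected in fewer than ``min_gene_cell_frac`` of the
    *remaining* cells are dropped. Both thresholds are inclusive (entities
    strictly below are removed). With ``iterate=True`` the pass repeats until
    a fixed point.
    """
    if not 0 <= min_gene_cell_frac <= 1:
        raise ValueError("min_gene_cell_frac must lie in [0, 1]")
    if min_cell_total < 0:
        raise ValueError("min_cell_total must be non-negative")
    if cell_metric not in ("total_counts", "detected_genes"):
        raise ValueError(f"unknown cell_metric {cell_metric!r}")

    counts = m.counts
    cell_keep = np.ones(counts.shape[0], dtype=bool)
    gene_keep = np.ones(counts.shape[1], dtype=bool)
    while True:
        sub = counts[np.ix_(cell_keep, gene_keep)]
        if cell_metric == "total_counts":
            cell_stat = sub.sum(axis=1)
        else:
            cell_stat = (sub > 0).sum(axis=1)
        new_cell = cell_stat >= min_cell_total
        sub = sub[new_cell]
        n_cells = sub.shape[0]
        if n_cells == 0:
            raise ValueError("QC removed every cell")
        detect_frac = (sub > 0).sum(axis=0) / n_cells
        new_gene = detect_frac >= min_gene_cell_frac
        changed = (~new_cell).any() or (~new_gene).any()
        cell_keep[np.flatnonzero(cell_keep)[~new_cell]] = False
        gene_keep[np.flatnonzero(gene_keep)[~new_gene]] = False
        if not (iterate and changed):
            break
    if not gene_keep.any():
        raise ValueError("QC removed every gene")
    return CountMatrix(
        counts[np.ix_(cell_keep, gene_keep)],
        [c for c, k in zip(m.cell_ids, cell_keep) if k],
        [g for g, k in zip(m.gene_ids, gene_keep) if k],
    )


def intersect_gene_sets(ms: Sequence[CountMatrix]) -> list[CountMatrix]:
    """Restrict every matrix to the genes shared by all, in lexicographic order.

    This is how a common gene panel is built across time points: each sample
    is QC-filtered separately and the final gene set is the intersection.
    """
    if not ms:
        raise ValueError("need at least one matrix")
    common = set(ms[0].gene_ids)
    for m in ms[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("gene-set intersection is empty")
    order = sorted(common)
    out = []
    for m in ms:
        pos = {g: i for i, g in enumerate(m.gene_ids)}
        idx = [pos[g] for g in order]
        out.append(CountMatrix(m.counts[:, idx], list(m.cell_ids), order))
    return out
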