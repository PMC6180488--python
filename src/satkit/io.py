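"""Readers and writers for 10x-style count matrices and the toolkit's tabular outputs.

The on-disk formats supported are:

* Matrix Market triplet directories as produced by CellRanger, in both the
  "v2" dialect (``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``) and the
  "v3" dialect (gzipped files, ``features.tsv.gz`` with three columns).
* The 10x HDF5 gene-barcode matrix layout (CSC arrays under a ``matrix``
  group, or the legacy per-genome group).
* Cluster label tables (``barcode<TAB>cluster`` TSV with a header row).
* The cluster-overlap CSV whose cells hold two fractions joined by an
  underscore (row-denominator fraction, column-denominator fraction).

Matrices are held genes-as-rows internally, matching the 10x convention.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, IntegrityError

__all__ = [
    "CountMatrix",
    "ClusterAssignment",
    "read_mtx_dir",
    "write_mtx_dir",
    "read_10x_h5",
    "write_10x_h5",
    "read_labels",
    "write_labels",
    "write_overlap_csv",
]


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with cell annotations.

    Parameters
    ----------
    counts
        Sparse non-negative integer matrix, genes as rows and cells as columns.
    gene_names
        One symbol per row.
    barcodes
        One unique barcode per column.
    library_labels
        Per-cell library (batch) of origin. Defaults to a single library.
    truth_labels
        Optional per-cell ground-truth cluster labels (synthetic data only).
    """

    counts: sp.spmatrix
    gene_names: list[str]
    barcodes: list[str]
    library_labels: Optional[list[str]] = None
    truth_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.gene_names = [str(g) for g in self.gene_names]
        self.barcodes = [str(b) for b in self.barcodes]
        n_genes, n_cells = self.counts.shape
        if len(self.gene_names) != n_genes:
            raise IntegrityError(
                f"{len(self.gene_names)} gene names for {n_genes} matrix rows"
            )
        if len(self.barcodes) != n_cells:
            raise IntegrityError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix columns"
            )
        if len(set(self.barcodes)) != n_cells:
            raise IntegrityError("duplicate barcodes in count matrix")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("negative entries in count matrix")
        if self.library_labels is None:
            self.library_labels = ["lib0"] * n_cells
        else:
            self.library_labels = [str(x) for x in self.library_labels]
            if len(self.library_labels) != n_cells:
                raise IntegrityError("library_labels length != number of cells")
        if self.truth_labels is not None:
            self.truth_labels = [str(x) for x in self.truth_labels]
            if len(self.truth_labels) != n_cells:
                raise IntegrityError("truth_labels length != number of cells")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def barcode_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.barcodes)}

    def subset_cells(self, barcodes: Sequence[str]) -> "CountMatrix":
        """Return a new matrix restricted to ``barcodes`` (kept in the given order)."""
        idx_of = self.barcode_index()
        try:
            idx = [idx_of[b] for b in barcodes]
        except KeyError as exc:
            raise IntegrityError(f"unknown barcode {exc.args[0]!r}") from None
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_names=list(self.gene_names),
            barcodes=[self.barcodes[i] for i in idx],
            library_labels=[self.library_labels[i] for i in idx],
            truth_labels=(
                [self.truth_labels[i] for i in idx] if self.truth_labels else None
            ),
        )


@dataclass
class ClusterAssignment:
    """Barcode -> cluster label mapping for one clustering analysis."""

    cells: list[str]
    labels: list[str]
    analysis_id: str = "analysis"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = [str(c) for c in self.cells]
        self.labels = [str(l) for l in self.labels]
        if len(self.cells) != len(self.labels):
            raise IntegrityError("one label per cell required")
        if len(set(self.cells)) != len(self.cells):
            raise IntegrityError("duplicate barcodes in cluster assignment")
        if not self.cells:
            raise IntegrityError("assignment must contain at least one cell")

    def __len__(self) -> int:
        return len(self.cells)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cells, name=self.analysis_id)

    def cluster_sizes(self) -> pd.Series:
        return self.as_series().value_counts()

    def cells_of(self, clusters: Sequence[str]) -> list[str]:
        wanted = {str(c) for c in clusters}
        return [c for c, l in zip(self.cells, self.labels) if l in wanted]


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_file(directory: Path, stems: Sequence[str]) -> Optional[Path]:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    return None


def read_mtx_dir(path: str | os.PathLike) -> CountMatrix:
    """Read a CellRanger-style Matrix Market directory into a :class:`CountMatrix`.

    Accepts both the v2 dialect (``genes.tsv``, two columns: id, symbol) and
    the v3 dialect (``features.tsv`` with id, symbol, feature type; usually
    gzipped). Gene names are taken from the symbol column. The library label
    defaults to the directory name.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FormatError(f"not a directory: {directory}")
    mtx = _find_file(directory, ["matrix.mtx"])
    if mtx is None:
        raise FormatError(f"missing matrix.mtx[.gz] in {directory}")
    genes = _find_file(directory, ["features.tsv", "genes.tsv"])
    if genes is None:
        raise FormatError(f"missing genes.tsv/features.tsv[.gz] in {directory}")
    bc = _find_file(directory, ["barcodes.tsv"])
    if bc is None:
        raise FormatError(f"missing barcodes.tsv[.gz] in {directory}")

    with _open_maybe_gz(mtx) as fh:
        counts = sp.csc_matrix(scipy.io.mmread(fh))
    with _open_maybe_gz(genes) as fh:
        gene_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    # v2: (id, symbol); v3: (id, symbol, type). Symbol column indexes 1 when present.
    gene_names = [row[1] if len(row) > 1 else row[0] for row in gene_rows]
    with _open_maybe_gz(bc) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if counts.shape[0] != len(gene_names):
        raise IntegrityError(
            f"matrix has {counts.shape[0]} rows but {len(gene_names)} gene entries"
        )
    if counts.shape[1] != len(barcodes):
        raise IntegrityError(
            f"matrix has {counts.shape[1]} columns but {len(barcodes)} barcodes"
        )
    library = directory.name
    return CountMatrix(
        counts=counts,
        gene_names=gene_names,
        barcodes=barcodes,
        library_labels=[library] * len(barcodes),
    )


def write_mtx_dir(
    matrix: CountMatrix, path: str | os.PathLike, dialect: str = "v2"
) -> None:
    """Write ``matrix`` as a Matrix Market directory.

    ``dialect="v2"`` writes plain ``genes.tsv``; ``dialect="v3"`` writes
    gzipped files with a three-column ``features.tsv.gz``.
    """
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.counts)
    if dialect == "v2":
        with open(directory / "matrix.mtx", "wb") as fh:
            scipy.io.mmwrite(fh, coo, field="integer")
        with open(directory / "genes.tsv", "wt") as fh:
            for g in matrix.gene_names:
                fh.write(f"{g}\t{g}\n")
        with open(directory / "barcodes.tsv", "wt") as fh:
            fh.write("\n".join(matrix.barcodes) + "\n")
    elif dialect == "v3":
        with gzip.open(directory / "matrix.mtx.gz", "wb") as fh:
            scipy.io.mmwrite(fh, coo, field="integer")
        with gzip.open(directory / "features.tsv.gz", "wt") as fh:
            for g in matrix.gene_names:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with gzip.open(directory / "barcodes.tsv.gz", "wt") as fh:
            fh.write("\n".join(matrix.barcodes) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_10x_h5(path: str | os.PathLike) -> CountMatrix:
    """Read a 10x HDF5 gene-barcode matrix (CSC layout).

    Supports the CellRanger v3 layout (a ``matrix`` group holding ``data``,
    ``indices``, ``indptr``, ``shape``, ``barcodes`` and ``features/name``)
    and the legacy per-genome layout (``gene_names`` instead of features).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        groups = list(f.keys())
        group = None
        if "matrix" in f:
            group = f["matrix"]
        else:
            for key in groups:
                node = f[key]
                if isinstance(node, h5py.Group) and "indptr" in node:
                    group = node
                    break
        if group is None or not all(
            k in group for k in ("data", "indices", "indptr", "shape")
        ):
            raise FormatError(
                f"no 10x matrix group in {path.name}; top-level groups: {groups}"
            )
        shape = tuple(int(x) for x in group["shape"][:])
        counts = sp.csc_matrix(
            (group["data"][:], group["indices"][:], group["indptr"][:]), shape=shape
        )
        barcodes = [b.decode() if isinstance(b, bytes) else str(b) for b in group["barcodes"][:]]
        if "features" in group:
            raw = group["features"]["name"][:]
        elif "gene_names" in group:
            raw = group["gene_names"][:]
        elif "genes" in group:
            raw = group["genes"][:]
        else:
            raise FormatError(
                f"no gene name array in {path.name}; datasets: {list(group.keys())}"
            )
        gene_names = [g.decode() if isinstance(g, bytes) else str(g) for g in raw]
    return CountMatrix(
        counts=counts,
        gene_names=gene_names,
        barcodes=barcodes,
        library_labels=[path.stem] * len(barcodes),
    )


def write_10x_h5(matrix: CountMatrix, path: str | os.PathLike) -> None:
    """Write ``matrix`` in the 10x v3 HDF5 gene-barcode layout."""
    csc = sp.csc_matrix(matrix.counts)
    with h5py.File(path, "w") as f:
        g = f.create_group("matrix")
        g.create_dataset("data", data=csc.data.astype(np.int64))
        g.create_dataset("indices", data=csc.indices.astype(np.int64))
        g.create_dataset("indptr", data=csc.indptr.astype(np.int64))
        g.create_dataset("shape", data=np.asarray(csc.shape, dtype=np.int64))
        g.create_dataset(
            "barcodes", data=np.array([b.encode() for b in matrix.barcodes])
        )
        feats = g.create_group("features")
        feats.create_dataset(
            "name", data=np.array([s.encode() for s in matrix.gene_names])
        )
        feats.create_dataset(
            "id", data=np.array([s.encode() for s in matrix.gene_names])
        )


def write_labels(assignment: ClusterAssignment, path: str | os.PathLike) -> None:
    """Write a ``barcode<TAB>cluster`` TSV with a header row."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("barcode\tcluster\n")
        for cell, label in zip(assignment.cells, assignment.labels):
            fh.write(f"{cell}\t{label}\n")


def read_labels(
    path: str | os.PathLike, analysis_id: Optional[str] = None
) -> ClusterAssignment:
    """Read a label TSV written by :func:`write_labels`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.empty or df.shape[1] < 2:
        raise IntegrityError(f"no label rows in {path}")
    cells = df.iloc[:, 0].tolist()
    if len(set(cells)) != len(cells):
        raise IntegrityError(f"duplicate barcodes in {path}")
    return ClusterAssignment(
        cells=cells,
        labels=df.iloc[:, 1].tolist(),
        analysis_id=analysis_id or path.stem,
    )


def write_overlap_csv(overlap, path: str | os.PathLike) -> None:
    """Write an :class:`~satkit.metrics.OverlapMatrix` as a fraction-pair CSV.

    Each cell holds ``<row fraction>_<column fraction>`` to four decimal
    places: the shared-cell count divided by the row cluster's common-cell
    total, then by the column cluster's.
    """
    counts = overlap.counts
    row_sizes = overlap.row_sizes.astype(float)
    col_sizes = overlap.col_sizes.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_row = np.where(row_sizes[:, None] > 0, counts / row_sizes[:, None], 0.0)
        frac_col = np.where(col_sizes[None, :] > 0, counts / col_sizes[None, :], 0.0)
    cells = np.empty(counts.shape, dtype=object)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            cells[i, j] = f"{frac_row[i, j]:.4f}_{frac_col[i, j]:.4f}"
    pd.DataFrame(cells, index=overlap.rows, columns=overlap.cols).to_csv(path)
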