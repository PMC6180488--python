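"""Quality control, per-cell normalization, scaling, PCA and significant-PC selection.

Cells are removed when their mitochondrial or ribosomal UMI fraction exceeds
10% (strictly greater), or when fewer than 1000 genes are detected. Kept
cells are depth-normalized to 10,000 counts and (by default) log1p
transformed before genes are centered and scaled for PCA. The number of
informative principal components is chosen by comparing eigenvalues of the
scaled data against the Marchenko-Pastur upper edge for a pure-noise matrix
of the same shape.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import EmptyResultError, IntegrityError
from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QCParams",
    "QCReport",
    "EmbeddingSpace",
    "qc_filter",
    "normalize_counts",
    "run_pca",
    "n_significant_pcs",
]


@dataclass
class QCParams:
    """Thresholds for cell-level quality control.

    Defaults follow common mouse single-cell practice: remove cells with
    more than 10% mitochondrial or more than 10% ribosomal content, or with
    fewer than 1000 detected genes. ``combined`` applies the 10% cutoff to
    the summed mito+ribo fraction instead of separately.
    """

    max_mito_frac: float = 0.10
    max_ribo_frac: float = 0.10
    min_genes: int = 1000
    mito_prefixes: tuple[str, ...] = ("mt-",)
    ribo_prefixes: tuple[str, ...] = ("Rps", "Rpl")
    combined: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.max_mito_frac <= 1 and 0 <= self.max_ribo_frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")


@dataclass
class QCReport:
    """Per-cell QC measurements and keep/remove flags."""

    table: pd.DataFrame  # barcode, n_genes, mito_frac, ribo_frac, kept

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_removed(self) -> int:
        return int((~self.table["kept"]).sum())

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class EmbeddingSpace:
    """A PCA embedding: scores, loadings, eigenvalues and the significant-PC count.

    ``pc_scores`` is cells x components; ``pc_loadings`` is genes x components
    over ``gene_names`` (zero-variance genes are dropped before scaling, so
    this may be a subset of the input genes). ``gene_means``/``gene_scales``
    hold the centering/scaling applied, enabling projection of new cells into
    the same space.
    """

    pc_scores: np.ndarray
    pc_loadings: np.ndarray
    eigenvalues: np.ndarray
    gene_names: list[str]
    barcodes: list[str]
    gene_means: np.ndarray
    gene_scales: np.ndarray
    n_significant: int = 1
    reference_id: str = "pca"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-8):
            raise IntegrityError("eigenvalues must be non-increasing")
        if self.n_significant < 1:
            raise IntegrityError("n_significant must be >= 1")

    @property
    def n_components(self) -> int:
        return self.pc_scores.shape[1]

    def significant_scores(self) -> np.ndarray:
        return self.pc_scores[:, : self.n_significant]

    def barcode_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.barcodes)}

    def scores_for(self, barcodes) -> np.ndarray:
        idx_of = self.barcode_index()
        idx = [idx_of[b] for b in barcodes]
        return self.pc_scores[idx]


def _family_mask(gene_names: list[str], prefixes: tuple[str, ...]) -> np.ndarray:
    return np.array(
        [any(g.startswith(p) for p in prefixes) for g in gene_names], dtype=bool
    )


def qc_filter(
    matrix: CountMatrix, params: Optional[QCParams] = None
) -> tuple[CountMatrix, QCReport]:
    """Remove low-quality cells; the gene set is left unchanged.

    A cell is removed when its mitochondrial fraction or ribosomal fraction
    exceeds the respective threshold (strictly greater), or when it detects
    fewer than ``min_genes`` genes. Filtering is idempotent.
    """
    params = params or QCParams()
    counts = sp.csc_matrix(matrix.counts)
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito = _family_mask(matrix.gene_names, params.mito_prefixes)
    ribo = _family_mask(matrix.gene_names, params.ribo_prefixes)
    mito_counts = np.asarray(counts[mito].sum(axis=0)).ravel() if mito.any() else np.zeros_like(totals)
    ribo_counts = np.asarray(counts[ribo].sum(axis=0)).ravel() if ribo.any() else np.zeros_like(totals)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)
        ribo_frac = np.where(totals > 0, ribo_counts / totals, 0.0)
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()

    if params.combined:
        frac_ok = (mito_frac + ribo_frac) <= params.max_mito_frac
    else:
        frac_ok = (mito_frac <= params.max_mito_frac) & (ribo_frac <= params.max_ribo_frac)
    kept = frac_ok & (n_genes >= params.min_genes)

    report = QCReport(
        pd.DataFrame(
            {
                "barcode": matrix.barcodes,
                "n_genes": n_genes,
                "mito_frac": mito_frac,
                "ribo_frac": ribo_frac,
                "kept": kept,
            }
        )
    )
    if not kept.any():
        raise EmptyResultError("QC filtering removed every cell")
    filtered = matrix.subset_cells([b for b, k in zip(matrix.barcodes, kept) if k])
    logger.info("QC kept %d/%d cells", report.n_kept, len(kept))
    return filtered, report


def normalize_counts(
    matrix: CountMatrix, target_sum: float = 10_000.0, log1p: bool = True
) -> sp.csc_matrix:
    """Scale each cell's counts to ``target_sum`` total, then (optionally) log1p.

    Returns a sparse genes x cells float matrix. Pre-log, every column sums
    to ``target_sum`` exactly.
    """
    counts = sp.csc_matrix(matrix.counts, dtype=np.float64, copy=True)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise IntegrityError(
            f"cell(s) with zero total counts: {[matrix.barcodes[i] for i in zero[:5]]}"
        )
    counts = counts @ sp.diags(target_sum / totals)
    if log1p:
        counts.data = np.log1p(counts.data)
    return sp.csc_matrix(counts)


def _scale_dense(expr: sp.spmatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Center and unit-scale genes (rows); drop zero-variance genes.

    Returns (cells x genes scaled dense matrix, kept-gene mask, means, scales).
    """
    dense = np.asarray(expr.todense() if sp.issparse(expr) else expr, dtype=np.float64)
    means = dense.mean(axis=1)
    stds = dense.std(axis=1, ddof=0)
    keep = stds > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance genes before scaling", n_dropped)
    scaled = (dense[keep] - means[keep, None]) / stds[keep, None]
    return scaled.T, keep, means[keep], stds[keep]


def run_pca(
    expr: sp.spmatrix | np.ndarray,
    gene_names: list[str],
    barcodes: list[str],
    n_components: int = 50,
    reference_id: str = "pca",
) -> EmbeddingSpace:
    """PCA of the centered-and-scaled expression matrix (genes x cells input).

    Components are ordered by decreasing explained variance. When fewer
    cells (or genes) than requested components are available the component
    count is clamped with a warning.
    """
    X, keep, means, scales = _scale_dense(expr)  # cells x genes
    n_cells, n_genes = X.shape
    max_rank = min(n_cells - 1 if n_cells > 1 else 1, n_genes)
    if n_components > max_rank:
        warnings.warn(
            f"n_components clamped from {n_components} to {max_rank} "
            f"for a {n_cells} x {n_genes} matrix"
        )
        n_components = max_rank
    # X is already centered per gene, so plain SVD is the PCA decomposition.
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    eigenvalues = S**2 / max(n_cells - 1, 1)
    return EmbeddingSpace(
        pc_scores=U * S,
        pc_loadings=Vt.T,
        eigenvalues=eigenvalues,
        gene_names=[g for g, k in zip(gene_names, keep) if k],
        barcodes=list(barcodes),
        gene_means=means,
        gene_scales=scales,
        reference_id=reference_id,
    )


def marchenko_pastur_edge(n_cells: int, n_genes: int) -> float:
    """Upper eigenvalue edge (1 + sqrt(n_genes/n_cells))^2 for unit-variance noise."""
    return (1.0 + np.sqrt(n_genes / n_cells)) ** 2


def n_significant_pcs(
    space: EmbeddingSpace,
    n_cells: Optional[int] = None,
    n_genes: Optional[int] = None,
    method: str = "marchenko_pastur",
    n_permutations: int = 20,
    seed: int = 0,
) -> int:
    """Count eigenvalues above the pure-noise expectation; always >= 1.

    ``method="marchenko_pastur"`` compares each eigenvalue to the
    Marchenko-Pastur upper edge for an i.i.d. unit-variance matrix of the
    same shape. ``method="permutation"`` instead simulates that null
    directly and uses the maximum null eigenvalue as the threshold.
    """
    n_cells = n_cells or len(space.barcodes)
    n_genes = n_genes or len(space.gene_names)
    if method == "marchenko_pastur":
        edge = marchenko_pastur_edge(n_cells, n_genes)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        maxima = []
        for _ in range(n_permutations):
            Z = rng.standard_normal((min(n_cells, 2000), n_genes))
            Z -= Z.mean(axis=0)
            s = np.linalg.svd(Z, compute_uv=False)[0]
            maxima.append(s**2 / max(Z.shape[0] - 1, 1))
        edge = float(np.median(maxima))
    else:
        raise ValueError(f"unknown method {method!r}")
    n_sig = int(np.sum(space.eigenvalues > edge))
    return max(n_sig, 1)
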