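"""Complexity index over cluster centroids and the R²-truncation saturation scan.

The complexity index summarizes how spread out a set of clusters is in a
fixed principal-component space: cluster centroids are joined by
average-linkage agglomeration on their Euclidean distances, leaves sit at
height 0, each edge's length is the parent merge height minus the child's
height, and the index is the sum of all edge lengths (arbitrary units; 0
for a single cluster, linear in any rescaling of the coordinates).

Saturation is judged from (cell count or complexity, mean preservation)
points: an ordinary-least-squares line is refit while the largest x values
are removed one at a time, and the dataset is called saturated when the
full-data fit explains little variance (R² below the threshold, default
0.6) and R² does not improve as larger-x points are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .errors import SatkitError
from .io import ClusterAssignment
from .qc import EmbeddingSpace

__all__ = [
    "ComplexityTree",
    "SaturationCurve",
    "cluster_centroids",
    "complexity_index",
    "complexity_downsample",
    "saturation_scan",
    "saturation_report",
]


@dataclass
class ComplexityTree:
    """Average-linkage dendrogram over cluster centroids with its branch-length sum."""

    leaves: list[str]
    centroids: np.ndarray  # clusters x dims
    linkage: Optional[np.ndarray]  # scipy linkage matrix; None for < 2 leaves
    index: float

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2] if self.linkage is not None else np.empty(0)


@dataclass
class SaturationCurve:
    """(x, preservation) points with the R²-truncation scan and its verdict."""

    points: pd.DataFrame  # columns: x, y, replicate
    r2_scan: pd.DataFrame  # columns: max_x, n_points, r2 (ascending max_x)
    verdict: str  # "saturated" | "not_saturated"
    threshold: float
    x_kind: str = "cells"


def plot_saturation(curve: SaturationCurve, path) -> None:
    """Write a two-panel figure: preservation points and the R² scan.

    The x axis is log2-scaled, which spreads the halving series evenly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    for rep, grp in curve.points.groupby("replicate"):
        ax1.plot(grp["x"], grp["y"], "o-", alpha=0.6, label=f"rep {rep}")
    ax1.set_xscale("log", base=2)
    ax1.set_xlabel(f"log2 {curve.x_kind}")
    ax1.set_ylabel("mean preservation")
    ax1.legend(fontsize=7)
    ax2.plot(curve.r2_scan["max_x"], curve.r2_scan["r2"], "s-")
    ax2.axhline(curve.threshold, ls="--", c="grey")
    ax2.set_xscale("log", base=2)
    ax2.set_xlabel(f"max {curve.x_kind} used")
    ax2.set_ylabel("R² of linear fit")
    ax2.set_title(f"verdict: {curve.verdict}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cluster_centroids(
    space: EmbeddingSpace,
    assignment: ClusterAssignment,
    use_significant: bool = True,
) -> tuple[list[str], np.ndarray]:
    """Mean significant-PC scores per cluster, in the reference space.

    Every cell of ``assignment`` must be embedded in ``space`` (subsets of
    the reference analysis always are, since their barcodes come from it).
    """
    idx_of = space.barcode_index()
    missing = [c for c in assignment.cells if c not in idx_of]
    if missing:
        raise SatkitError(
            f"{len(missing)} cells of {assignment.analysis_id!r} absent from "
            f"space {space.reference_id!r} (e.g. {missing[:3]})"
        )
    scores = space.significant_scores() if use_significant else space.pc_scores
    series = assignment.as_series()
    labels = sorted(set(assignment.labels))
    centroids = np.empty((len(labels), scores.shape[1]))
    for i, lab in enumerate(labels):
        cells = series.index[series.values == lab]
        rows = [idx_of[c] for c in cells]
        if not rows:
            raise SatkitError(f"cluster {lab!r} has no cells in the space")
        centroids[i] = scores[rows].mean(axis=0)
    return labels, centroids


def complexity_index(
    labels: Sequence[str],
    centroids: np.ndarray,
    linkage_method: str = "average",
) -> ComplexityTree:
    """Total branch length of the centroid dendrogram.

    Leaves sit at height 0; an edge's length is its parent's merge height
    minus the child node's height; the index sums every edge. A single
    cluster (or identical centroids) yields 0.
    """
    centroids = np.asarray(centroids, dtype=float)
    labels = [str(l) for l in labels]
    if centroids.ndim != 2 or centroids.shape[0] != len(labels):
        raise SatkitError("centroid matrix must be clusters x dims")
    k = centroids.shape[0]
    if k < 1:
        raise SatkitError("need at least one centroid")
    if k == 1:
        return ComplexityTree(leaves=labels, centroids=centroids, linkage=None, index=0.0)
    Z = sch.linkage(centroids, method=linkage_method, metric="euclidean")
    # height of each node: 0 for leaves, merge height for internal nodes
    heights = np.concatenate([np.zeros(k), Z[:, 2]])
    total = 0.0
    for m in range(Z.shape[0]):
        parent_h = Z[m, 2]
        for child in (int(Z[m, 0]), int(Z[m, 1])):
            total += parent_h - heights[child]
    return ComplexityTree(leaves=labels, centroids=centroids, linkage=Z, index=float(total))


def complexity_downsample(
    space: EmbeddingSpace,
    assignment: ClusterAssignment,
    branch: Sequence[str],
    linkage_method: str = "average",
) -> tuple[list[str], float]:
    """Cells and complexity index of a chosen branch (subset of clusters).

    The index is recomputed on just those clusters' centroids in the same
    reference space, so high- and low-complexity branches are comparable.
    """
    branch = [str(b) for b in branch]
    if not branch:
        raise SatkitError("empty branch")
    present = set(assignment.labels)
    missing = [b for b in branch if b not in present]
    if missing:
        raise SatkitError(f"branch clusters not in assignment: {missing}")
    cells = assignment.cells_of(branch)
    labels, cents = cluster_centroids(space, assignment)
    keep = [i for i, l in enumerate(labels) if l in set(branch)]
    tree = complexity_index([labels[i] for i in keep], cents[keep], linkage_method)
    return cells, tree.index


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R² of the least-squares line y = a + b·x; 0 when y has no variance."""
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # guard against catastrophic cancellation on (near-)constant y
    if ss_tot <= (1e-10 * (np.abs(y).max() + 1.0)) ** 2 * len(y):
        return 0.0
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(min(max(r2, 0.0), 1.0))


def saturation_scan(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    threshold: float = 0.6,
    min_points: int = 3,
    monotone_window: int = 3,
    monotone_tol: float = 0.05,
    x_kind: str = "cells",
) -> SaturationCurve:
    """Refit the preservation-vs-x line while truncating the largest x values.

    The scan removes the largest distinct x values one at a time (from none
    removed down to ``min_points`` distinct values remaining) and records
    the OLS R² of each fit. The verdict is ``saturated`` when the full-data
    R² falls below ``threshold`` and adding the plateau does not make the
    linear fit better: R² is non-increasing (within ``monotone_tol``) over
    the last ``monotone_window`` truncations, or every R² in that window is
    already below the threshold (a flat curve, where tiny R² values
    fluctuate without meaning).
    """
    if isinstance(points, pd.DataFrame):
        df = points[["x", "y"]].copy()
        df["replicate"] = points.get("replicate", 0)
    else:
        df = pd.DataFrame(points, columns=["x", "y"])
        df["replicate"] = 0
    if len(df) < min_points:
        raise SatkitError(f"need at least {min_points} points, got {len(df)}")
    if (df["x"] <= 0).any():
        raise SatkitError("x values must be positive")
    distinct = np.sort(df["x"].unique())
    if len(distinct) < min_points:
        raise SatkitError(
            f"need at least {min_points} distinct x values, got {len(distinct)}"
        )
    rows = []
    for n_keep in range(min_points, len(distinct) + 1):
        max_x = distinct[n_keep - 1]
        sub = df[df["x"] <= max_x]
        rows.append(
            {
                "max_x": float(max_x),
                "n_points": int(len(sub)),
                "r2": _ols_r2(sub["x"].to_numpy(float), sub["y"].to_numpy(float)),
            }
        )
    scan = pd.DataFrame(rows)
    r2 = scan["r2"].to_numpy()
    full_r2 = r2[-1]
    tail = r2[-min(monotone_window, len(r2)):]
    non_increasing = bool(np.all(np.diff(tail) <= monotone_tol))
    plateau = bool(np.all(tail < threshold))
    verdict = (
        "saturated" if (full_r2 < threshold and (non_increasing or plateau)) else "not_saturated"
    )
    return SaturationCurve(points=df, r2_scan=scan, verdict=verdict, threshold=threshold, x_kind=x_kind)


def saturation_report(
    comparisons: Sequence[dict],
    threshold: float = 0.6,
    min_points: int = 3,
) -> dict:
    """Assemble preservation-vs-size and -vs-complexity curves plus the cluster-count curve.

    ``comparisons`` holds one record per clustered subset with keys
    ``n_cells``, ``mean_preservation``, ``complexity``, ``n_clusters`` and
    optionally ``replicate``. Returns the two :class:`SaturationCurve`
    objects and the (complexity, n_clusters) table.
    """
    df = pd.DataFrame(list(comparisons))
    required = {"n_cells", "mean_preservation", "complexity", "n_clusters"}
    if not required <= set(df.columns):
        raise SatkitError(f"comparison records need columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    by_cells = df.rename(columns={"n_cells": "x", "mean_preservation": "y"})[
        ["x", "y", "replicate"]
    ]
    by_complexity = df.rename(columns={"complexity": "x", "mean_preservation": "y"})[
        ["x", "y", "replicate"]
    ]
    curve_cells = saturation_scan(by_cells, threshold, min_points, x_kind="cells")
    # complexity can be 0 for single-cluster subsets; drop those points
    by_complexity = by_complexity[by_complexity["x"] > 0]
    curve_complexity = saturation_scan(by_complexity, threshold, min_points, x_kind="complexity")
    cluster_counts = df[["complexity", "n_clusters", "replicate"]].sort_values("complexity")
    # headline verdict follows the cell-count curve: when clustering is already
    # stable the subset complexities collapse onto one value and the
    # complexity-axis regression is ill-conditioned
    return {
        "by_cells": curve_cells,
        "by_complexity": curve_complexity,
        "cluster_counts": cluster_counts,
        "verdict": curve_cells.verdict,
    }
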