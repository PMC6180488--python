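"""Cluster-overlap accounting between two analyses of nested cell sets.

The comparison is restricted to the barcodes common to both analyses
(downsampling removes cells at random, so absence from the subset is not a
clustering failure). From the resulting contingency table three per-cluster
scores are derived:

* **preservation** — for each reference cluster, the maximum fraction of its
  common cells found together in any single subset cluster (top-down);
* **conservation** — for each subset cluster, the maximum fraction of its
  cells originating from any single reference cluster (bottom-up, the
  reciprocal analysis);
* **split** — the number of clusters on the other side sharing at least one
  cell, separating an even two-way split from scattering across many
  clusters.

The Rand index (raw and Hubert-Arabie adjusted) is computed on the same
common cells for comparison against the pairwise-agreement view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import comb

from .errors import SatkitError
from .io import ClusterAssignment

__all__ = [
    "OverlapMatrix",
    "PreservationResult",
    "overlap_matrix",
    "preservation",
    "conservation",
    "split_count",
    "rand_index",
    "compare_analyses",
    "ComparisonSummary",
]


@dataclass
class OverlapMatrix:
    """Contingency table of shared-cell counts between two clusterings."""

    rows: list[str]  # reference ("original") cluster labels
    cols: list[str]  # subset cluster labels
    counts: np.ndarray  # rows x cols shared-cell counts over common cells

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.rows), len(self.cols)):
            raise SatkitError("overlap counts shape does not match label lists")
        if self.counts.min(initial=0) < 0:
            raise SatkitError("negative overlap counts")

    @property
    def row_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_common(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "OverlapMatrix":
        return OverlapMatrix(rows=list(self.cols), cols=list(self.rows), counts=self.counts.T)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.rows, columns=self.cols)


@dataclass
class PreservationResult:
    """Per-cluster max-fraction scores with the cluster achieving each max."""

    scores: dict[str, float]
    best_match: dict[str, Optional[str]]
    direction: str  # "preservation" | "conservation"

    def mean(self) -> float:
        vals = [v for v in self.scores.values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def weighted_mean(self, sizes: dict[str, int]) -> float:
        pairs = [
            (v, sizes[c]) for c, v in self.scores.items() if not np.isnan(v) and sizes.get(c, 0) > 0
        ]
        if not pairs:
            return float("nan")
        vals, w = zip(*pairs)
        return float(np.average(vals, weights=w))

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, name=self.direction)


def overlap_matrix(a: ClusterAssignment, b: ClusterAssignment) -> OverlapMatrix:
    """Shared-cell contingency table over the barcodes common to both analyses.

    Clusters of ``a`` with no common cells appear as all-zero rows so the
    reference cluster list is complete.
    """
    sa, sb = a.as_series(), b.as_series()
    common = sa.index.intersection(sb.index)
    if common.empty:
        raise SatkitError(
            f"no common barcodes between {a.analysis_id!r} and {b.analysis_id!r}"
        )
    table = pd.crosstab(sa.loc[common], sb.loc[common])
    all_rows = pd.Index(pd.unique(sa.values))
    table = table.reindex(index=all_rows, fill_value=0)
    return OverlapMatrix(
        rows=[str(r) for r in table.index],
        cols=[str(c) for c in table.columns],
        counts=table.to_numpy(),
    )


def _max_fraction(overlap: OverlapMatrix, axis: int, direction: str) -> PreservationResult:
    counts = overlap.counts
    labels = overlap.rows if axis == 0 else overlap.cols
    other = overlap.cols if axis == 0 else overlap.rows
    sizes = overlap.row_sizes if axis == 0 else overlap.col_sizes
    scores: dict[str, float] = {}
    best: dict[str, Optional[str]] = {}
    for i, lab in enumerate(labels):
        line = counts[i] if axis == 0 else counts[:, i]
        if sizes[i] == 0:
            import warnings

            warnings.warn(f"cluster {lab!r} has no common cells; score undefined")
            scores[lab] = float("nan")
            best[lab] = None
            continue
        j = int(np.argmax(line))
        scores[lab] = float(line[j] / sizes[i])
        best[lab] = other[j]
    return PreservationResult(scores=scores, best_match=best, direction=direction)


def preservation(overlap: OverlapMatrix) -> PreservationResult:
    """Top-down score: max over subset clusters of count / reference-cluster size."""
    return _max_fraction(overlap, axis=0, direction="preservation")


def conservation(overlap: OverlapMatrix) -> PreservationResult:
    """Bottom-up score: max over reference clusters of count / subset-cluster size."""
    return _max_fraction(overlap, axis=1, direction="conservation")


def split_count(overlap: OverlapMatrix, cluster: str, direction: str = "rows") -> int:
    """Number of clusters on the opposite axis holding >= 1 cell of ``cluster``."""
    cluster = str(cluster)
    if direction == "rows":
        if cluster not in overlap.rows:
            raise SatkitError(f"unknown row cluster {cluster!r}")
        line = overlap.counts[overlap.rows.index(cluster)]
    elif direction == "cols":
        if cluster not in overlap.cols:
            raise SatkitError(f"unknown column cluster {cluster!r}")
        line = overlap.counts[:, overlap.cols.index(cluster)]
    else:
        raise ValueError("direction must be 'rows' or 'cols'")
    return int((line >= 1).sum())


def rand_index(
    a: ClusterAssignment, b: ClusterAssignment, adjusted: bool = False
) -> float:
    """Rand index over common cells; Hubert-Arabie correction when ``adjusted``.

    Raw Rand counts the pairs of cells on which both clusterings agree
    (together in both or separated in both) out of all pairs; the adjusted
    form subtracts the chance expectation of that agreement.
    """
    overlap = overlap_matrix(a, b)
    n = overlap.n_common
    if n < 2:
        raise SatkitError("need at least 2 common cells for a Rand index")
    nij = overlap.counts
    sum_nij = comb(nij, 2).sum()
    sum_ai = comb(overlap.row_sizes, 2).sum()
    sum_bj = comb(overlap.col_sizes, 2).sum()
    total = comb(n, 2)
    if not adjusted:
        # agreements = pairs together in both + pairs apart in both
        return float((total + 2 * sum_nij - sum_ai - sum_bj) / total)
    expected = sum_ai * sum_bj / total
    max_index = (sum_ai + sum_bj) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_nij - expected) / (max_index - expected))


@dataclass
class ComparisonSummary:
    """Bundle of overlap table, per-cluster scores and summary statistics."""

    overlap: OverlapMatrix
    preservation: PreservationResult
    conservation: PreservationResult
    splits_rows: dict[str, int]
    splits_cols: dict[str, int]
    rand: float
    adjusted_rand: float
    n_common: int
    mean_preservation: float
    mean_conservation: float
    weighted_mean_preservation: float
    weighted_mean_conservation: float

    def per_cluster_table(self) -> pd.DataFrame:
        ov = self.overlap
        return pd.DataFrame(
            {
                "cluster": ov.rows,
                "size_common": ov.row_sizes,
                "preservation": [self.preservation.scores[r] for r in ov.rows],
                "best_match": [self.preservation.best_match[r] for r in ov.rows],
                "split": [self.splits_rows[r] for r in ov.rows],
            }
        )

    def to_dict(self) -> dict:
        return {
            "n_common": self.n_common,
            "mean_preservation": self.mean_preservation,
            "mean_conservation": self.mean_conservation,
            "rand": self.rand,
            "adjusted_rand": self.adjusted_rand,
        }


def compare_analyses(a: ClusterAssignment, b: ClusterAssignment) -> ComparisonSummary:
    """Full pairwise comparison: overlap, scores, splits, Rand indices, means.

    Mean scores are unweighted across clusters (rare clusters count the same
    as abundant ones); cell-weighted means are reported alongside.
    """
    ov = overlap_matrix(a, b)
    pres = preservation(ov)
    cons = conservation(ov)
    splits_rows = {r: split_count(ov, r, "rows") for r in ov.rows}
    splits_cols = {c: split_count(ov, c, "cols") for c in ov.cols}
    row_size = dict(zip(ov.rows, ov.row_sizes.tolist()))
    col_size = dict(zip(ov.cols, ov.col_sizes.tolist()))
    return ComparisonSummary(
        overlap=ov,
        preservation=pres,
        conservation=cons,
        splits_rows=splits_rows,
        splits_cols=splits_cols,
        rand=rand_index(a, b, adjusted=False),
        adjusted_rand=rand_index(a, b, adjusted=True),
        n_common=ov.n_common,
        mean_preservation=pres.mean(),
        mean_conservation=cons.mean(),
        weighted_mean_preservation=pres.weighted_mean(row_size),
        weighted_mean_conservation=cons.weighted_mean(col_size),
    )
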