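"""Per-cluster marker-gene detection and unique-marker accounting.

Markers are called one-vs-rest with a two-sided Wilcoxon rank-sum test per
gene, Benjamini-Hochberg correction across genes within each cluster, and
thresholds on the (log-scale) fold change and adjusted p-value. A gene that
marks exactly one cluster is a *unique* marker; clusters without any unique
marker are distinguishable only by combinations of marker levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import SatkitError
from .io import ClusterAssignment

__all__ = ["MarkerTable", "find_markers", "unique_marker_counts", "marker_retention"]

_LN2 = np.log(2.0)


@dataclass
class MarkerTable:
    """Long-format marker test results plus the thresholds that define a marker."""

    table: pd.DataFrame  # cluster, gene, lfc, pval, padj, frac_in, frac_rest, is_marker
    min_lfc: float
    max_padj: float

    def markers_of(self, cluster: str) -> pd.DataFrame:
        t = self.table
        return t[(t["cluster"] == str(cluster)) & t["is_marker"]]

    def marker_counts(self) -> pd.Series:
        m = self.table[self.table["is_marker"]]
        clusters = self.table["cluster"].unique()
        return m.groupby("cluster").size().reindex(clusters, fill_value=0)

    def marker_sets(self) -> dict[str, set[str]]:
        return {
            c: set(self.markers_of(c)["gene"]) for c in self.table["cluster"].unique()
        }


def find_markers(
    expr: sp.spmatrix | np.ndarray,
    gene_names: list[str],
    assignment: ClusterAssignment,
    min_lfc: float = 0.25,
    max_padj: float = 0.05,
) -> MarkerTable:
    """One-vs-rest Wilcoxon marker test on a normalized (log-scale) matrix.

    ``expr`` is genes x cells over ``assignment.cells`` in order. The fold
    change is the difference of in-cluster and rest mean log expression,
    expressed in log2 units; markers must be up-regulated (positive fold
    change), significant after BH correction, and above ``min_lfc``.
    Clusters of size 1 are skipped with a warning.
    """
    dense = np.asarray(expr.todense() if sp.issparse(expr) else expr, dtype=np.float64)
    if dense.shape[1] != len(assignment):
        raise SatkitError("expression columns must match assignment cells")
    labels = np.asarray(assignment.labels)
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise SatkitError("need at least 2 clusters to test markers")
    frames = []
    for c in clusters:
        in_mask = labels == c
        n_in = int(in_mask.sum())
        if n_in < 2:
            warnings.warn(f"cluster {c!r} has {n_in} cell(s); skipped")
            continue
        x_in = dense[:, in_mask]
        x_rest = dense[:, ~in_mask]
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pvals = mannwhitneyu(x_in, x_rest, axis=1, alternative="two-sided")
        pvals = np.nan_to_num(pvals, nan=1.0)
        padj = multipletests(pvals, method="fdr_bh")[1]
        lfc = (x_in.mean(axis=1) - x_rest.mean(axis=1)) / _LN2
        frames.append(
            pd.DataFrame(
                {
                    "cluster": str(c),
                    "gene": gene_names,
                    "lfc": lfc,
                    "pval": pvals,
                    "padj": padj,
                    "frac_in": (x_in > 0).mean(axis=1),
                    "frac_rest": (x_rest > 0).mean(axis=1),
                }
            )
        )
    if not frames:
        raise SatkitError("no cluster large enough to test")
    table = pd.concat(frames, ignore_index=True)
    table["is_marker"] = (
        (table["lfc"] > min_lfc) & (table["padj"] <= max_padj) & (table["lfc"] > 0)
    )
    return MarkerTable(table=table, min_lfc=min_lfc, max_padj=max_padj)


def unique_marker_counts(table: MarkerTable) -> pd.Series:
    """Markers claimed by exactly one cluster, per cluster.

    A gene marking two or more clusters contributes to none of them; a
    cluster with count 0 has no unique identifiers.
    """
    sets = table.marker_sets()
    all_markers = pd.Series(
        [g for s in sets.values() for g in s], dtype=object
    ).value_counts()
    unique_genes = set(all_markers[all_markers == 1].index)
    return pd.Series(
        {c: len(s & unique_genes) for c, s in sets.items()}, name="unique_markers"
    )


def marker_retention(
    full_table: MarkerTable,
    subset_table: MarkerTable,
    cluster_map: dict[str, str],
) -> pd.Series:
    """Fraction of each full-analysis cluster's markers recovered in the subset.

    ``cluster_map`` maps full-analysis clusters to their best-matching
    subset clusters (from :func:`satkit.metrics.compare_analyses`). Full
    clusters without a mapped partner are reported as NaN.
    """
    full_sets = full_table.marker_sets()
    subset_sets = subset_table.marker_sets()
    out = {}
    for c, markers in full_sets.items():
        partner = cluster_map.get(c)
        if partner is None or partner not in subset_sets:
            out[c] = float("nan")
            continue
        out[c] = (
            len(markers & subset_sets[partner]) / len(markers) if markers else float("nan")
        )
    return pd.Series(out, name="marker_retention")
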