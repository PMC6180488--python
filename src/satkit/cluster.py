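"""Louvain-Jaccard graph clustering in significant-PC space.

The pipeline follows the classic droplet-era recipe: Euclidean k-nearest
neighbors (k = 10) in the space of significant principal components, edges
weighted by the Jaccard similarity of the endpoints' neighbor sets, and
Louvain modularity optimization on the resulting graph. Iterative
reclustering re-runs the whole pipeline (including a fresh PCA) on the
cells of a chosen cluster group to expose subtypes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import igraph
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .errors import SatkitError
from .io import ClusterAssignment, CountMatrix
from .qc import EmbeddingSpace, n_significant_pcs, normalize_counts, run_pca

__all__ = [
    "ClusteringParams",
    "NeighborGraph",
    "knn_jaccard_graph",
    "louvain_cluster",
    "cluster_pipeline",
    "iterative_recluster",
    "pc_correlation",
]


@dataclass
class ClusteringParams:
    """Knobs for the Louvain-Jaccard pipeline.

    ``n_neighbors=10`` and ``n_pcs_total=50`` are the droplet-era defaults;
    when ``use_significant_pcs`` is on, neighbor search runs on the
    significant components only. ``resolution=1.0`` is classic modularity.
    """

    n_pcs_total: int = 50
    n_neighbors: int = 10
    use_significant_pcs: bool = True
    louvain_seed: int = 0
    resolution: float = 1.0
    knn_edges_only: bool = False
    normalize_target: float = 10_000.0
    log1p: bool = True

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class NeighborGraph:
    """Undirected cell graph with Jaccard-similarity edge weights in [0, 1]."""

    nodes: list[str]
    edges: np.ndarray  # (m, 2) int node indices, i < j
    weights: np.ndarray  # (m,) floats in (0, 1]

    def __post_init__(self) -> None:
        if len(self.weights) and (self.weights.min() <= 0 or self.weights.max() > 1):
            raise SatkitError("Jaccard weights must lie in (0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_igraph(self) -> igraph.Graph:
        g = igraph.Graph(n=self.n_nodes, edges=self.edges.tolist())
        g.es["weight"] = self.weights.tolist()
        return g


def _knn_sets(coords: np.ndarray, k: int) -> sp.csr_matrix:
    """Boolean cells x cells matrix: row i marks i's k nearest neighbors (self excluded).

    Distance ties are broken by cell index so neighbor sets are reproducible.
    """
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(coords)
    dist, idx = nn.kneighbors(coords)
    rows, cols = [], []
    for i in range(n):
        # stable re-sort on (distance, index) for deterministic tie handling
        order = np.lexsort((idx[i], dist[i]))
        neigh = [j for j in idx[i][order] if j != i][:k]
        rows.extend([i] * len(neigh))
        cols.extend(neigh)
    data = np.ones(len(rows), dtype=np.int8)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def knn_jaccard_graph(
    space: EmbeddingSpace, params: ClusteringParams | None = None
) -> NeighborGraph:
    """Build the shared-nearest-neighbor graph with Jaccard edge weights.

    The weight of an edge (a, b) is |N(a) ∩ N(b)| / |N(a) ∪ N(b)| over the
    two k-neighbor sets (each cell excluded from its own set). By default an
    edge joins every pair of cells whose neighbor sets overlap at all; with
    ``knn_edges_only`` the edge set is restricted to (directed) k-nearest
    neighbor pairs. Zero-weight edges are dropped either way.
    """
    params = params or ClusteringParams()
    coords = (
        space.significant_scores()
        if params.use_significant_pcs
        else space.pc_scores
    )
    n = coords.shape[0]
    k = params.n_neighbors
    if n < k + 1:
        raise SatkitError(f"need at least {k + 1} cells for {k} neighbors, got {n}")
    A = _knn_sets(coords, k)
    sizes = np.asarray(A.sum(axis=1)).ravel()
    if params.knn_edges_only:
        cand = (A + A.T).tocoo()
        mask = cand.row < cand.col
        pairs = np.column_stack([cand.row[mask], cand.col[mask]])
        inter_lookup = sp.csr_matrix(A @ A.T)
        inter_vals = np.asarray(inter_lookup[pairs[:, 0], pairs[:, 1]]).ravel()
    else:
        inter = sp.triu(sp.csr_matrix(A @ A.T), k=1).tocoo()
        pairs = np.column_stack([inter.row, inter.col])
        inter_vals = inter.data
    union = sizes[pairs[:, 0]] + sizes[pairs[:, 1]] - inter_vals
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(union > 0, inter_vals / union, 0.0)
    keep = w > 0
    return NeighborGraph(nodes=list(space.barcodes), edges=pairs[keep], weights=w[keep])


def louvain_cluster(
    graph: NeighborGraph, params: ClusteringParams | None = None, analysis_id: str = "louvain"
) -> ClusterAssignment:
    """Louvain community detection on the weighted neighbor graph.

    Deterministic for a fixed ``louvain_seed``. Disconnected components are
    handled natively by the multilevel algorithm; isolated cells become
    singleton clusters.
    """
    params = params or ClusteringParams()
    if graph.n_nodes == 0:
        raise SatkitError("empty graph")
    g = graph.to_igraph()
    igraph.set_random_number_generator(random.Random(params.louvain_seed))
    part = g.community_multilevel(weights="weight", resolution=params.resolution)
    igraph.set_random_number_generator(random)
    labels = [str(m) for m in part.membership]
    return ClusterAssignment(
        cells=list(graph.nodes),
        labels=labels,
        analysis_id=analysis_id,
        params={"louvain_seed": params.louvain_seed, "resolution": params.resolution},
    )


def cluster_pipeline(
    matrix: CountMatrix,
    params: ClusteringParams | None = None,
    analysis_id: str = "full",
) -> tuple[ClusterAssignment, EmbeddingSpace]:
    """Normalize, scale, PCA, pick significant PCs, build the graph, Louvain.

    Expects a QC-filtered matrix. All parameters are recorded on the
    returned assignment so a run can be reproduced from its outputs.
    """
    params = params or ClusteringParams()
    expr = normalize_counts(matrix, target_sum=params.normalize_target, log1p=params.log1p)
    space = run_pca(
        expr,
        gene_names=matrix.gene_names,
        barcodes=matrix.barcodes,
        n_components=params.n_pcs_total,
        reference_id=analysis_id,
    )
    space.n_significant = n_significant_pcs(space)
    graph = knn_jaccard_graph(space, params)
    assignment = louvain_cluster(graph, params, analysis_id=analysis_id)
    assignment.params.update(
        {
            "n_pcs_total": params.n_pcs_total,
            "n_significant": space.n_significant,
            "n_neighbors": params.n_neighbors,
            "normalize_target": params.normalize_target,
            "log1p": params.log1p,
        }
    )
    return assignment, space


def iterative_recluster(
    matrix: CountMatrix,
    assignment: ClusterAssignment,
    group: set[str] | list[str],
    params: ClusteringParams | None = None,
) -> ClusterAssignment:
    """Re-run the full pipeline (fresh PCA) on the cells of ``group`` only.

    Returned labels are namespaced ``<group-name>/<sub-label>`` so they stay
    distinguishable from top-level clusters.
    """
    params = params or ClusteringParams()
    group = {str(g) for g in group}
    present = set(assignment.labels)
    missing = group - present
    if not group:
        raise SatkitError("empty cluster group")
    if missing:
        raise SatkitError(f"cluster group not in assignment: {sorted(missing)}")
    cells = assignment.cells_of(group)
    if len(cells) < params.n_neighbors + 1:
        raise SatkitError(
            f"group has {len(cells)} cells; need at least {params.n_neighbors + 1}"
        )
    sub = matrix.subset_cells(cells)
    prefix = "+".join(sorted(group))
    sub_assignment, _ = cluster_pipeline(sub, params, analysis_id=f"{assignment.analysis_id}/{prefix}")
    sub_assignment.labels = [f"{prefix}/{l}" for l in sub_assignment.labels]
    return sub_assignment


def pc_correlation(space_a: EmbeddingSpace, space_b: EmbeddingSpace) -> np.ndarray:
    """Absolute Pearson correlation between the gene loadings of two spaces.

    Loadings are intersected on shared genes first; entry (i, j) is
    |corr(loading_i of a, loading_j of b)|.
    """
    shared = sorted(set(space_a.gene_names) & set(space_b.gene_names))
    if not shared:
        raise SatkitError("no shared genes between embedding spaces")
    ia = {g: i for i, g in enumerate(space_a.gene_names)}
    ib = {g: i for i, g in enumerate(space_b.gene_names)}
    A = space_a.pc_loadings[[ia[g] for g in shared]]
    B = space_b.pc_loadings[[ib[g] for g in shared]]
    A = (A - A.mean(axis=0)) / A.std(axis=0, ddof=0)
    B = (B - B.mean(axis=0)) / B.std(axis=0, ddof=0)
    corr = np.abs(A.T @ B) / len(shared)
    return np.clip(corr, 0.0, 1.0)
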