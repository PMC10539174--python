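"""Normalisation, feature selection, embedding, kNN graph and pseudotime.

Pseudotime is the geodesic (shortest-path) distance from a root cell over the
symmetrised Euclidean kNN graph in PCA space, normalised to [0, 1]. This is a
deliberately simple, dependency-free and deterministic substrate for the fate
window and trajectory stages; it is monotone along the simulated branches.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.neighbors import NearestNeighbors

from .io import Dataset

__all__ = [
    "EmbeddingGraph",
    "normalize_log",
    "select_hvg",
    "compute_pca",
    "build_knn_graph",
    "compute_pseudotime",
    "preprocess_dataset",
]

TARGET_SUM = 10_000.0


@dataclasses.dataclass
class EmbeddingGraph:
    """PCA embedding plus exact kNN structure.

    ``neighbors``/``distances`` are (n, k) arrays (self excluded, ties broken
    by cell index). ``multi_component`` flags a symmetrised graph that is not
    connected.
    """

    embedding: np.ndarray
    neighbors: np.ndarray
    distances: np.ndarray
    cell_ids: pd.Index
    root_cell_id: object = None
    multi_component: bool = False

    @property
    def n_cells(self) -> int:
        return self.embedding.shape[0]

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    def symmetrized(self) -> sp.csr_matrix:
        """Undirected weighted adjacency (union of kNN edges, Euclidean
        weights)."""
        n, k = self.neighbors.shape
        rows = np.repeat(np.arange(n), k)
        cols = self.neighbors.ravel()
        vals = self.distances.ravel()
        a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        return a.maximum(a.T)


def normalize_log(dataset: Dataset) -> tuple[sp.csr_matrix, np.ndarray]:
    """Scale each cell to 10,000 total counts, then log(1 + x).

    Returns ``(normalized, zero_total_flag)``; all-zero cells keep all-zero
    rows and are flagged rather than dropped.
    """
    counts = dataset.counts.astype(np.float64).tocsr()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    zero = totals == 0
    scale = np.ones_like(totals)
    scale[~zero] = TARGET_SUM / totals[~zero]
    x = sp.diags(scale) @ counts
    x.data = np.log1p(x.data)
    return x.tocsr(), zero


def select_hvg(normalized: sp.spmatrix, gene_ids, n_hvg: int) -> np.ndarray:
    """Boolean flags for the ``n_hvg`` genes of highest variance of the
    log-normalised values; ties broken by lexically smaller gene_id."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    n_genes = normalized.shape[1]
    if n_hvg > n_genes:
        raise ValueError(f"n_hvg = {n_hvg} exceeds the {n_genes} genes present")
    x = sp.csc_matrix(normalized)
    n = x.shape[0]
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = (sq - mean**2) * (n / max(n - 1, 1))
    order = np.lexsort((gene_ids.astype(str), -var))
    flags = np.zeros(n_genes, dtype=bool)
    flags[order[:n_hvg]] = True
    return flags


def compute_pca(normalized: sp.spmatrix, hvg_flags, n_pcs: int) -> np.ndarray:
    """Project the per-gene-centred HVG submatrix onto its top right singular
    vectors. Component signs are fixed so the largest-magnitude loading of
    each component is positive."""
    hvg_flags = np.asarray(hvg_flags, dtype=bool)
    x = np.asarray(sp.csr_matrix(normalized)[:, hvg_flags].todense(), dtype=float)
    n, g = x.shape
    if n_pcs > min(n, g):
        raise ValueError(f"n_pcs = {n_pcs} exceeds min(cells, hvgs) = {min(n, g)}")
    x -= x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    return u * s


def _exact_knn(points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = points.shape[0]
    extra = min(n, k + 6)  # headroom so ties can be re-sorted deterministically
    nn = NearestNeighbors(n_neighbors=extra, algorithm="brute").fit(points)
    dist, idx = nn.kneighbors(points)
    neighbors = np.empty((n, k), dtype=np.int64)
    distances = np.empty((n, k), dtype=float)
    for i in range(n):
        keep = idx[i] != i
        di, ii = dist[i][keep], idx[i][keep]
        order = np.lexsort((ii, di))[:k]
        neighbors[i] = ii[order]
        distances[i] = di[order]
    return neighbors, distances


def build_knn_graph(embedding: np.ndarray, k: int, cell_ids,
                    root_cell_id=None, within=None) -> EmbeddingGraph:
    """Exact Euclidean k-nearest neighbours (self excluded); distance ties
    broken by cell index order.

    ``within`` (optional per-cell group labels, e.g. the condition) restricts
    each cell's neighbour search to its own group, so groups that are not
    integrated into a common manifold get independent graphs (the resulting
    graph is then multi-component by construction).
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the {n} cells")
    cell_ids = pd.Index(cell_ids)
    if within is None:
        neighbors, distances = _exact_knn(embedding, k)
    else:
        within = np.asarray(within)
        neighbors = np.empty((n, k), dtype=np.int64)
        distances = np.empty((n, k), dtype=float)
        for g in pd.unique(within):
            members = np.flatnonzero(within == g)
            if k >= members.size:
                raise ValueError(
                    f"k = {k} must be smaller than the {members.size} cells "
                    f"of group {g!r}")
            nb, di = _exact_knn(embedding[members], k)
            neighbors[members] = members[nb]
            distances[members] = di
    graph = EmbeddingGraph(embedding, neighbors, distances, cell_ids,
                           root_cell_id=root_cell_id)
    ncomp, _ = connected_components(graph.symmetrized(), directed=False)
    graph.multi_component = ncomp > 1
    return graph


def compute_pseudotime(graph: EmbeddingGraph,
                       component_roots=None) -> tuple[np.ndarray, np.ndarray]:
    """Geodesic pseudotime in [0, 1] from the root over the symmetrised graph.

    On a connected graph distances from ``graph.root_cell_id`` are divided by
    their maximum. If the graph has several components, each needs its own
    root (``component_roots``: iterable of cell ids, one per extra component;
    the main root covers its own component) and distances are normalised to
    [0, 1] within each component. Cells in components without a root get NaN
    pseudotime and a flag.

    Returns ``(pseudotime, unreachable_flag)``.
    """
    if graph.root_cell_id is None:
        raise ValueError("graph has no root_cell_id set")
    if graph.root_cell_id not in graph.cell_ids:
        raise ValueError(f"root cell {graph.root_cell_id!r} not in graph")
    adj = graph.symmetrized()
    n = graph.n_cells
    ncomp, labels = connected_components(adj, directed=False)
    roots = [graph.root_cell_id] + list(component_roots or [])
    root_idx = []
    for r in roots:
        if r not in graph.cell_ids:
            raise ValueError(f"root cell {r!r} not in graph")
        root_idx.append(int(graph.cell_ids.get_loc(r)))
    pt = np.full(n, np.nan)
    for comp in range(ncomp):
        members = np.flatnonzero(labels == comp)
        comp_roots = [r for r in root_idx if labels[r] == comp]
        if not comp_roots:
            continue
        d = dijkstra(adj, directed=False, indices=comp_roots[0])
        dm = d[members]
        top = np.nanmax(dm[np.isfinite(dm)]) if np.isfinite(dm).any() else 0.0
        pt[members] = dm / top if top > 0 else 0.0
    unreachable = ~np.isfinite(pt)
    pt[unreachable] = np.nan
    return pt, unreachable


def preprocess_dataset(dataset: Dataset, n_hvg: int, n_pcs: int, k: int,
                       root_cell_id=None, stratify_by_condition: bool = True):
    """Normalise -> HVG -> PCA -> kNN -> pseudotime, in one call.

    Because the package performs no batch integration, the kNN graph is by
    default built within each condition (``stratify_by_condition``): the two
    cohorts occupy offset sheets of the embedding and a joint graph would
    order one cohort's cells by their distance to the inter-cohort bridge
    rather than by differentiation progress. Pseudotime is then normalised
    per component.

    The root defaults to the cell of minimal ``true_pseudotime`` when the
    dataset carries simulator ground truth; on real data it must be supplied
    (one root per graph component). Returns
    ``(normalized, hvg_flags, graph, pseudotime, unreachable)``.
    """
    normalized, _ = normalize_log(dataset)
    hvg = select_hvg(normalized, dataset.gene_ids, n_hvg)
    emb = compute_pca(normalized, hvg, n_pcs)
    within = None
    if stratify_by_condition and dataset.cells["condition"].nunique() > 1:
        within = dataset.cells["condition"].to_numpy()
    graph = build_knn_graph(emb, k, dataset.cell_ids,
                            root_cell_id=root_cell_id, within=within)
    if isinstance(root_cell_id, (list, tuple)):
        roots = list(root_cell_id)
        graph.root_cell_id = roots[0]
        pt, unreachable = compute_pseudotime(graph, roots[1:])
        return normalized, hvg, graph, pt, unreachable
    component_roots = []
    if root_cell_id is None or graph.multi_component:
        if "true_pseudotime" not in dataset.cells.columns:
            raise ValueError(
                "root_cell_id required (no true_pseudotime to infer roots from)")
        tpt = dataset.cells["true_pseudotime"].to_numpy(dtype=float)
        _, labels = connected_components(graph.symmetrized(), directed=False)
        for comp in range(labels.max() + 1):
            members = np.flatnonzero(labels == comp)
            best = members[np.argmin(tpt[members])]
            component_roots.append(dataset.cell_ids[best])
        if root_cell_id is None:
            graph.root_cell_id = component_roots[0]
        component_roots = [r for r in component_roots
                           if r != graph.root_cell_id]
    pt, unreachable = compute_pseudotime(graph, component_roots)
    return normalized, hvg, graph, pt, unreachable
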