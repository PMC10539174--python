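"""Cell-fate probabilities as absorption probabilities of a pseudotime
directed absorbing Markov chain on the kNN graph.

Non-terminal cells step to a kNN neighbour with probability proportional to
``exp(beta * (t_j - t_i) / scale)`` (a softmax over pseudotime increments),
so the walk drifts up pseudotime; terminal cells — the high-pseudotime tips
of the seven lineage clusters — are absorbing. Fate probabilities solve the
absorbing-chain linear system ``(I - Q) B = R`` with absorption mass
aggregated per lineage macrostate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .io import Dataset
from .preprocess import EmbeddingGraph
from ._stats import bh_adjust, welch_ttest

__all__ = [
    "TrajectoryModel",
    "define_terminal_states",
    "build_transition_matrix",
    "absorption_probabilities",
    "compare_fate_by_cluster",
    "run_fate",
]


@dataclasses.dataclass
class TrajectoryModel:
    """Row-stochastic transition matrix plus the lineage macrostates."""

    transition: sp.csr_matrix
    macrostates: dict            # lineage -> np.ndarray of terminal cell rows
    cell_ids: pd.Index
    beta: float

    def validate(self) -> None:
        rowsums = np.asarray(self.transition.sum(axis=1)).ravel()
        if not np.allclose(rowsums, 1.0, atol=1e-10):
            raise ValueError("transition rows must sum to 1 within 1e-10")
        seen = set()
        for lineage, idx in self.macrostates.items():
            s = set(map(int, idx))
            if seen & s:
                raise ValueError(f"macrostate {lineage} overlaps another")
            seen |= s


def define_terminal_states(cells: pd.DataFrame, pseudotime: np.ndarray,
                           terminal_quantile: float = 0.9,
                           lineages=None,
                           cluster_column: str = "cluster",
                           condition_column: str = "condition") -> dict:
    """Terminal cells per lineage: the top-pseudotime members of the lineage's
    terminal cluster.

    The pseudotime quantile is taken within cluster x condition and the
    selections are pooled, so an embedding offset between unintegrated
    conditions cannot exclude one condition's terminal tip.
    """
    pseudotime = np.asarray(pseudotime, dtype=float)
    clusters = cells[cluster_column].to_numpy()
    if lineages is None:
        from .simulate import LINEAGES
        lineages = [l for l in LINEAGES if l in set(clusters)]
    macrostates = {}
    cond = (cells[condition_column].to_numpy()
            if condition_column in cells.columns
            else np.full(len(cells), "all"))
    for lineage in lineages:
        members = np.flatnonzero(clusters == lineage)
        if members.size == 0:
            raise ValueError(f"lineage {lineage!r} has no cells in its cluster")
        chosen = []
        for c in np.unique(cond[members]):
            sub = members[cond[members] == c]
            pt = pseudotime[sub]
            ok = np.isfinite(pt)
            if not ok.any():
                continue
            thresh = np.quantile(pt[ok], terminal_quantile)
            chosen.append(sub[ok][pt[ok] >= thresh])
        if not chosen or sum(len(c) for c in chosen) == 0:
            raise ValueError(f"lineage {lineage!r} has no terminal cells")
        macrostates[lineage] = np.sort(np.concatenate(chosen))
    return macrostates


def build_transition_matrix(graph: EmbeddingGraph, pseudotime: np.ndarray,
                            beta: float, macrostates: dict,
                            scale: float | None = 1.0) -> TrajectoryModel:
    """Softmax-directed chain on the kNN edges.

    ``w_ij = exp(beta * clip(t_j - t_i, -scale, scale) / scale) / sum_j' ...``
    over cell i's k neighbours; terminal cells are absorbing. With
    ``scale = 1`` and pseudotime in [0, 1] the clip is inactive and the
    weight is the plain softmax over pseudotime increments.

    ``scale = None`` uses the median absolute increment over kNN edges: the
    directionality then saturates at exp(+/-beta) one typical neighbour step
    away, so the walk steps (almost) uniformly among forward neighbours
    instead of overweighting the furthest-ahead one — this keeps branch
    splits proportional to corridor cell density and is the pipeline default.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0 (the walk follows pseudotime)")
    t = np.asarray(pseudotime, dtype=float)
    n, k = graph.neighbors.shape
    dt = t[graph.neighbors] - t[:, None]
    if scale is None:
        nz = np.abs(dt[np.isfinite(dt)])
        nz = nz[nz > 0]
        scale = float(np.median(nz)) if nz.size else 1.0
    z = beta * np.clip(dt, -scale, scale) / scale
    z -= z.max(axis=1, keepdims=True)
    w = np.exp(z)
    w /= w.sum(axis=1, keepdims=True)

    terminal = np.zeros(n, dtype=bool)
    for idx in macrostates.values():
        terminal[idx] = True
    rows = np.repeat(np.arange(n), k)
    cols = graph.neighbors.ravel()
    vals = w.ravel().copy()
    keep = ~terminal[rows]
    mat = sp.csr_matrix((vals[keep], (rows[keep], cols[keep])), shape=(n, n))
    mat = mat + sp.csr_matrix(
        (np.ones(terminal.sum()), (np.flatnonzero(terminal),
                                   np.flatnonzero(terminal))), shape=(n, n))
    model = TrajectoryModel(mat.tocsr(), macrostates, graph.cell_ids, beta)
    model.validate()
    return model


def absorption_probabilities(model: TrajectoryModel) -> pd.DataFrame:
    """Per-cell lineage absorption probabilities, solving ``(I - Q) B = R``.

    Terminal cells get probability 1 for their own lineage. Transient cells
    with no path to any terminal cell raise an error listing them.
    """
    p = model.transition
    n = p.shape[0]
    lineages = list(model.macrostates)
    terminal = np.zeros(n, dtype=bool)
    lineage_of = np.full(n, -1)
    for li, lineage in enumerate(lineages):
        idx = model.macrostates[lineage]
        terminal[idx] = True
        lineage_of[idx] = li
    transient = np.flatnonzero(~terminal)

    # reachability: every transient cell must have a directed path to some
    # terminal cell (fixpoint of "has an out-edge into the reachable set")
    pattern = p.copy()
    pattern.data = np.ones_like(pattern.data)
    reach = terminal.astype(float)
    while True:
        new = ((pattern @ reach) > 0) | (reach > 0)
        if new.sum() == (reach > 0).sum():
            break
        reach = new.astype(float)
    stuck = np.flatnonzero(~(reach > 0) & ~terminal)
    if stuck.size:
        ids = list(model.cell_ids[stuck[:10]])
        raise ValueError(
            f"{stuck.size} transient cells cannot reach any terminal cell "
            f"(first few: {ids})")

    b = np.zeros((n, len(lineages)))
    for li in range(len(lineages)):
        b[lineage_of == li, li] = 1.0
    if transient.size:
        q = p[transient][:, transient]
        r = np.zeros((transient.size, len(lineages)))
        for li, lineage in enumerate(lineages):
            cols = model.macrostates[lineage]
            r[:, li] = np.asarray(p[transient][:, cols].sum(axis=1)).ravel()
        a = (sp.identity(transient.size, format="csc") - q.tocsc())
        sol = splu(a.tocsc()).solve(r)
        b[transient] = np.clip(sol, 0.0, None)
    fate = pd.DataFrame(b, index=model.cell_ids, columns=lineages)
    sums = fate.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError("fate probabilities do not sum to 1 within 1e-8")
    return fate


def compare_fate_by_cluster(fate: pd.DataFrame, cells: pd.DataFrame,
                            treated: str, vehicle: str,
                            min_cells: int = 2) -> pd.DataFrame:
    """Condition comparison of per-cell fate probabilities per (cluster,
    lineage): Welch t-test, BH across all pairs."""
    rows = []
    for cluster, sub in cells.groupby("cluster", observed=True, sort=True):
        a_idx = sub.index[sub["condition"] == treated]
        b_idx = sub.index[sub["condition"] == vehicle]
        skipped = len(a_idx) < min_cells or len(b_idx) < min_cells
        for lineage in fate.columns:
            a = fate.loc[a_idx, lineage].to_numpy()
            b = fate.loc[b_idx, lineage].to_numpy()
            t, p = (np.nan, np.nan) if skipped else welch_ttest(a, b)
            rows.append((cluster, lineage, len(a), len(b),
                         a.mean() if a.size else np.nan,
                         b.mean() if b.size else np.nan, t, p, skipped))
    table = pd.DataFrame(rows, columns=[
        "cluster", "lineage", "n_treated", "n_vehicle", "mean_treated",
        "mean_vehicle", "t", "p", "skipped"])
    table["p_adj"] = bh_adjust(table["p"])
    return table


def run_fate(dataset: Dataset, graph: EmbeddingGraph, pseudotime: np.ndarray,
             beta: float = 5.0, terminal_quantile: float = 0.9,
             scale: float | None = None):
    """Terminal states -> transition matrix -> absorption -> cluster table.

    Returns ``(fate, cluster_table, model)``. ``scale=None`` (default) uses
    the adaptive median-increment scaling.
    """
    macro = define_terminal_states(dataset.cells, pseudotime,
                                   terminal_quantile=terminal_quantile)
    model = build_transition_matrix(graph, pseudotime, beta, macro, scale=scale)
    fate = absorption_probabilities(model)
    table = compare_fate_by_cluster(fate, dataset.cells,
                                    dataset.treated, dataset.vehicle)
    return fate, table, model
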