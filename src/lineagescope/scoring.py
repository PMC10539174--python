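"""Per-cell gene-signature scoring and transcriptomic cell-cycle phase calls.

A signature score is the mean log-normalised expression of the signature
genes minus the mean over control genes drawn from expression-matched bins
(the standard bin-matched control construction). Phase assignment scores an
S and a G2M signature the same way and calls G1 when both scores are
negative, otherwise the phase of the larger score.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import Dataset, GeneSignature
from ._stats import bh_adjust, welch_ttest

__all__ = [
    "SignatureScoreResult",
    "PhaseAssignment",
    "signature_scores",
    "score_signature",
    "assign_phase",
    "builtin_cycle_signature",
]


@dataclasses.dataclass
class SignatureScoreResult:
    """Per-cell scores plus the per-cluster condition comparison."""

    scores: pd.Series              # per cell
    cluster_table: pd.DataFrame    # per cluster: means, diff, p, p_adj
    dropped_genes: tuple           # signature genes absent from the dataset


@dataclasses.dataclass
class PhaseAssignment:
    s_score: pd.Series
    g2m_score: pd.Series
    phase: pd.Series               # in {G1, S, G2M}


def _score_cells(normalized: sp.spmatrix, gene_ids: pd.Index,
                 signature: GeneSignature, n_bins: int, n_ctrl: int,
                 seed: int, salt: int = 0) -> tuple[np.ndarray, tuple]:
    """Bin-matched control score for every cell; returns (scores, dropped).

    Controls are drawn with a per-gene RNG stream derived from
    ``(seed, salt, gene index)`` so the score is invariant to the order of
    the signature and to signature genes absent from the dataset."""
    present = [g for g in signature.gene_ids if g in gene_ids]
    dropped = tuple(g for g in signature.gene_ids if g not in gene_ids)
    if not present:
        raise ValueError(
            f"no gene of signature {signature.name!r} is present in the dataset")
    x = sp.csc_matrix(normalized)
    mean_expr = np.asarray(x.mean(axis=0)).ravel()
    # genes ranked by mean expression, cut into n_bins equal-size bins
    order = np.argsort(mean_expr, kind="stable")
    bin_of = np.empty(len(gene_ids), dtype=int)
    bin_of[order] = np.minimum(
        np.arange(len(gene_ids)) * n_bins // len(gene_ids), n_bins - 1)
    sig_idx = np.array([gene_ids.get_loc(g) for g in present])
    ctrl_parts = []
    in_sig = np.zeros(len(gene_ids), dtype=bool)
    in_sig[sig_idx] = True
    for gi in sig_idx:
        pool = np.flatnonzero((bin_of == bin_of[gi]) & ~in_sig)
        if pool.size == 0:
            pool = np.flatnonzero(bin_of == bin_of[gi])
        rng_g = np.random.default_rng([int(seed), int(salt), int(gi)])
        ctrl_parts.append(rng_g.choice(pool, size=n_ctrl,
                                       replace=pool.size < n_ctrl))
    ctrl_idx = np.concatenate(ctrl_parts)
    sig_mean = np.asarray(x[:, sig_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(x[:, ctrl_idx].mean(axis=1)).ravel()
    return sig_mean - ctrl_mean, dropped


def signature_scores(normalized: sp.spmatrix, gene_ids,
                     signature: GeneSignature, n_bins: int = 25,
                     n_ctrl: int = 50, seed: int = 0) -> tuple[np.ndarray, tuple]:
    """Per-cell bin-matched control scores (no condition comparison)."""
    return _score_cells(normalized, pd.Index(gene_ids), signature,
                        n_bins, n_ctrl, seed)


def score_signature(dataset: Dataset, normalized: sp.spmatrix,
                    signature: GeneSignature, n_bins: int = 25,
                    n_ctrl: int = 50, seed: int = 0) -> SignatureScoreResult:
    """Score a signature per cell and compare conditions within each cluster.

    The per-cluster comparison is a two-tailed Welch t-test on per-cell
    scores (treated vs vehicle), BH-corrected across clusters.
    """
    scores, dropped = signature_scores(
        normalized, dataset.gene_ids, signature, n_bins, n_ctrl, seed)
    scores = pd.Series(scores, index=dataset.cell_ids, name="score")
    cells = dataset.cells
    rows = []
    if "cluster" in cells.columns:
        for cluster, sub in cells.groupby("cluster", observed=True, sort=True):
            sc = scores.loc[sub.index]
            a = sc[sub["condition"] == dataset.treated].to_numpy()
            b = sc[sub["condition"] == dataset.vehicle].to_numpy()
            t, p = welch_ttest(a, b)
            rows.append((cluster, len(a), len(b),
                         a.mean() if a.size else np.nan,
                         b.mean() if b.size else np.nan,
                         (a.mean() - b.mean()) if (a.size and b.size) else np.nan,
                         t, p))
    table = pd.DataFrame(rows, columns=[
        "cluster", "n_treated", "n_vehicle", "mean_treated", "mean_vehicle",
        "difference", "t", "p"])
    table["p_adj"] = bh_adjust(table["p"]) if len(table) else []
    return SignatureScoreResult(scores, table, dropped)


def assign_phase(dataset: Dataset, normalized: sp.spmatrix,
                 s_genes: GeneSignature, g2m_genes: GeneSignature,
                 n_bins: int = 25, n_ctrl: int = 50,
                 seed: int = 0) -> PhaseAssignment:
    """Score S and G2M signatures and call the phase per cell.

    G1 iff both scores are negative; otherwise the phase of the larger score
    (ties go to S).
    """
    gene_ids = pd.Index(dataset.gene_ids)
    s, _ = _score_cells(normalized, gene_ids, s_genes, n_bins, n_ctrl,
                        seed, salt=1)
    g2m, _ = _score_cells(normalized, gene_ids, g2m_genes, n_bins, n_ctrl,
                          seed, salt=2)
    phase = np.where((s < 0) & (g2m < 0), "G1", np.where(g2m > s, "G2M", "S"))
    idx = dataset.cell_ids
    return PhaseAssignment(pd.Series(s, index=idx, name="s_score"),
                           pd.Series(g2m, index=idx, name="g2m_score"),
                           pd.Series(phase, index=idx, name="phase"))


def builtin_cycle_signature(which: str) -> GeneSignature:
    """The bundled mouse S or G2M gene list (``which`` in {'s', 'g2m'}).

    These are the widely used cell-cycle marker lists (mouse symbol casing),
    shipped as a documented convention and overridable by any GMT input.
    """
    fname = {"s": "s_genes_mouse.txt", "g2m": "g2m_genes_mouse.txt"}[which]
    text = resources.files("lineagescope.data").joinpath(fname).read_text()
    genes = tuple(ln.strip() for ln in text.splitlines() if ln.strip())
    return GeneSignature({"s": "S_phase", "g2m": "G2M_phase"}[which], genes)
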