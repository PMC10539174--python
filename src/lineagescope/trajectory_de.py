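"""Condition-dependent gene dynamics along a trajectory, plus pseudobulk DE.

Per gene, log-normalised expression along pseudotime is fitted with cubic
B-spline smoothers on a basis shared between conditions; a nested-model
F-test compares the single shared curve against condition-specific curves.
Global condition differences are tested at the replicate level on
size-factor-normalised log2 pseudobulk profiles (independent t-test across
samples).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.interpolate import BSpline

from .io import Dataset
from ._stats import bh_adjust, student_ttest

__all__ = [
    "SmootherFit",
    "spline_basis",
    "fit_condition_smoothers",
    "test_condition_dynamics",
    "pseudobulk_condition_de",
]

GRID_POINTS = 100
DEGREE = 3


@dataclasses.dataclass
class SmootherFit:
    """Condition-specific spline fits for a set of genes on a shared basis."""

    gene_ids: pd.Index
    knots: np.ndarray                  # full knot vector (clamped cubic)
    grid: np.ndarray                   # 100-point pseudotime grid
    curves: dict                       # condition -> (n_grid x n_genes)
    coefs: dict                        # condition -> (n_basis x n_genes)
    rss_separate: np.ndarray           # per gene, both conditions fitted
    rss_shared: np.ndarray             # per gene, one shared curve
    n_obs: int
    n_basis: int
    skipped: pd.Index                  # genes skipped for insufficient span


def spline_basis(x: np.ndarray, knots: np.ndarray,
                 degree: int = DEGREE) -> np.ndarray:
    """Design matrix of clamped B-splines of ``degree`` at ``x``."""
    n_basis = len(knots) - degree - 1
    return BSpline.design_matrix(x, knots, degree, extrapolate=True
                                 ).toarray()[:, :n_basis]


def _make_knots(x: np.ndarray, n_knots: int, degree: int = DEGREE) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if n_knots > 0:
        interior = np.quantile(x, np.linspace(0, 1, n_knots + 2)[1:-1])
        interior = np.clip(interior, lo, hi)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def fit_condition_smoothers(normalized, pseudotime, condition,
                            trajectory_mask=None, n_knots: int = 6,
                            gene_ids=None, treated: str = "treated",
                            vehicle: str = "vehicle",
                            degree: int = DEGREE) -> SmootherFit:
    """Least-squares B-spline fits per gene, separately per condition, on a
    basis shared between conditions (interior knots at pseudotime quantiles
    of the trajectory cells).

    Genes are fitted on trajectory cells only. Conditions must each span at
    least ``n_knots + DEGREE + 1`` distinct pseudotime values.
    """
    x = np.asarray(
        sp.csr_matrix(normalized).todense()
        if sp.issparse(normalized) else normalized, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    cond = np.asarray(condition)
    mask = (np.ones(len(t), dtype=bool) if trajectory_mask is None
            else np.asarray(trajectory_mask, dtype=bool))
    mask = mask & np.isfinite(t)
    gene_ids = (pd.Index(gene_ids) if gene_ids is not None
                else pd.RangeIndex(x.shape[1]))

    n_basis = n_knots + degree + 1
    for c in (treated, vehicle):
        n_distinct = len(np.unique(t[mask & (cond == c)]))
        if n_distinct < n_basis:
            raise ValueError(
                f"condition {c!r} spans only {n_distinct} distinct pseudotime "
                f"values; need >= {n_basis}")

    tm = t[mask]
    knots = _make_knots(tm, n_knots, degree)
    basis = spline_basis(tm, knots, degree)
    y = x[mask]
    grid = np.linspace(knots[0], knots[-1], GRID_POINTS)
    bgrid = spline_basis(grid, knots, degree)

    coefs, curves = {}, {}
    rss_sep = np.zeros(x.shape[1])
    for c in (treated, vehicle):
        rows = cond[mask] == c
        bc, yc = basis[rows], y[rows]
        beta, *_ = np.linalg.lstsq(bc, yc, rcond=None)
        coefs[c] = beta
        curves[c] = bgrid @ beta
        rss_sep += ((yc - bc @ beta) ** 2).sum(axis=0)
    beta0, *_ = np.linalg.lstsq(basis, y, rcond=None)
    rss_shared = ((y - basis @ beta0) ** 2).sum(axis=0)

    return SmootherFit(gene_ids, knots, grid, curves, coefs,
                       rss_sep, rss_shared, n_obs=int(mask.sum()),
                       n_basis=n_basis, skipped=pd.Index([]))


def test_condition_dynamics(fit: SmootherFit,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Nested-model F-test per gene: one shared curve vs condition-specific
    curves; BH across genes.

    F = ((RSS0 - RSS1)/p) / (RSS1/(n - 2p)) with p basis functions. Genes
    whose separate fit is exact (zero residual variance) while the shared fit
    is not get p = 0 with a degenerate flag.
    """
    p_extra = fit.n_basis
    df2 = fit.n_obs - 2 * fit.n_basis
    if df2 <= 0:
        raise ValueError("not enough observations for the nested F-test")
    rss0, rss1 = fit.rss_shared, fit.rss_separate
    degenerate = rss1 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / p_extra) / (rss1 / df2)
    pvals = stats.f.sf(f, p_extra, df2)
    pvals = np.where(degenerate & (rss0 > rss1), 0.0,
                     np.where(degenerate, 1.0, pvals))
    f = np.where(degenerate, np.inf, f)
    table = pd.DataFrame({
        "gene_id": fit.gene_ids, "f_stat": f, "p": pvals,
        "degenerate": degenerate})
    table["p_adj"] = bh_adjust(table["p"])
    table["flag"] = table["p_adj"] < alpha
    return table


def _size_factors(bulk: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors per sample (genes detected in every
    sample against their geometric mean); falls back to total-count scaling
    when no gene qualifies."""
    positive = (bulk > 0).all(axis=0)
    if positive.sum() >= 1:
        logref = np.log(bulk[:, positive]).mean(axis=0)
        sf = np.exp(np.median(np.log(bulk[:, positive]) - logref, axis=1))
    else:
        totals = bulk.sum(axis=1)
        sf = totals / totals.mean() if totals.mean() > 0 else np.ones(len(bulk))
    return sf


def pseudobulk_condition_de(dataset: Dataset, alpha: float = 0.05) -> pd.DataFrame:
    """Replicate-level condition DE on normalised log2 pseudobulk profiles.

    Counts are summed per sample and scaled by median-of-ratios size factors
    (the counts of genes detected in every sample against their geometric
    mean) rather than raw totals: with asymmetric differential expression,
    total-count (CPM) scaling shifts every unchanged gene in the opposite
    direction, while the median ratio is anchored on the unchanged majority.
    Values log2(count/sf + 1) are compared between conditions per gene with
    a two-tailed independent t-test, BH across genes. All-zero genes get p = 1 by
    convention.
    """
    cells = dataset.cells
    samples = sorted(cells["sample_id"].unique())
    cond = dataset.condition_of_sample()
    if ((cond == dataset.treated).sum() < 2
            or (cond == dataset.vehicle).sum() < 2):
        raise ValueError("need >= 2 samples per condition")
    mats = []
    for s in samples:
        rows = np.flatnonzero((cells["sample_id"] == s).to_numpy())
        mats.append(np.asarray(dataset.counts[rows].sum(axis=0)).ravel())
    bulk = np.vstack(mats).astype(float)           # samples x genes
    sf = _size_factors(bulk)
    # per-million scaling against the mean effective library keeps values
    # invariant to a global sequencing-depth change
    eff_lib = (bulk.sum(axis=1) / sf).mean()
    denom = sf * max(eff_lib, 1.0) / 1e6
    logcpm = np.log2(bulk / denom[:, None] + 1.0)
    tr = [i for i, s in enumerate(samples) if cond[s] == dataset.treated]
    ve = [i for i, s in enumerate(samples) if cond[s] == dataset.vehicle]
    rows = []
    allzero = bulk.sum(axis=0) == 0
    for g in range(dataset.n_genes):
        a, b = logcpm[tr, g], logcpm[ve, g]
        if allzero[g]:
            t, p = 0.0, 1.0
        else:
            t, p = student_ttest(a, b)
        rows.append((dataset.gene_ids[g], a.mean(), b.mean(),
                     a.mean() - b.mean(), t, p))
    table = pd.DataFrame(rows, columns=[
        "gene_id", "mean_treated", "mean_vehicle", "log2fc", "t", "p"])
    table["p_adj"] = bh_adjust(table["p"])
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    table["flag"] = table["p_adj"] < alpha
    return table
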