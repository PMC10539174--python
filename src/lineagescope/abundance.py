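"""Differential cell abundance across clusters between conditions.

The tested unit is the per-sample cluster fraction: each replicate animal
contributes one composition vector, and each cluster is compared between
conditions with a two-tailed independent (pooled-variance) t-test,
BH-corrected across clusters. Clusters below a minimum total cell count (or,
optionally, below a fraction of the dataset) are excluded before correction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import Dataset
from ._stats import bh_adjust, student_ttest

__all__ = ["AbundanceResult", "cluster_fractions", "test_abundance",
           "run_abundance"]


@dataclasses.dataclass
class AbundanceResult:
    """Per-cluster test table plus the per-sample fraction matrix."""

    fractions: pd.DataFrame   # samples x clusters, rows sum to 1
    table: pd.DataFrame       # per cluster: means, SDs, t, p, p_adj, ...
    alpha: float


def cluster_fractions(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cluster composition: ``fraction[sample, cluster]``.

    Clusters absent from a sample get 0; a sample with zero cells is an
    error.
    """
    if "cluster" not in cells.columns or "sample_id" not in cells.columns:
        raise ValueError("cells table needs cluster and sample_id columns")
    counts = pd.crosstab(cells["sample_id"], cells["cluster"])
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals[totals == 0].index.tolist()
        raise ValueError(f"samples with zero cells: {bad}")
    return counts.div(totals, axis=0)


def test_abundance(fractions: pd.DataFrame, conditions: pd.Series,
                   alpha: float = 0.2, min_cells: int = 20,
                   cell_counts: pd.Series | None = None,
                   min_dataset_fraction: float | None = None) -> AbundanceResult:
    """Independent t-test per cluster on per-sample fractions, treated vs vehicle.

    ``conditions`` maps sample_id to the role ``treated``/``vehicle`` (or the
    declared labels, with exactly two distinct values where the first sorted
    value alphabetically is *not* assumed treated — pass roles explicitly via
    a Series of {'treated','vehicle'}). Direction is the sign of
    (treated mean - vehicle mean); flagged when BH-adjusted p < ``alpha``.
    """
    conditions = conditions.reindex(fractions.index)
    roles = set(conditions.unique())
    if roles != {"treated", "vehicle"}:
        raise ValueError(
            f"conditions must map samples to 'treated'/'vehicle', got {roles}")
    tr = fractions.index[conditions == "treated"]
    ve = fractions.index[conditions == "vehicle"]
    if len(tr) < 2 or len(ve) < 2:
        raise ValueError("need >= 2 samples per condition")
    rows = []
    for cluster in fractions.columns:
        n_cells = (int(cell_counts[cluster]) if cell_counts is not None
                   else None)
        excluded = False
        if n_cells is not None:
            if n_cells < min_cells:
                excluded = True
            if (min_dataset_fraction is not None
                    and n_cells < min_dataset_fraction * cell_counts.sum()):
                excluded = True
        a = fractions.loc[tr, cluster].to_numpy(dtype=float)
        b = fractions.loc[ve, cluster].to_numpy(dtype=float)
        t, p = (np.nan, np.nan) if excluded else student_ttest(a, b)
        rows.append((cluster, n_cells, a.mean(), b.mean(),
                     a.std(ddof=1), b.std(ddof=1), t, p,
                     "increased" if a.mean() >= b.mean() else "depleted",
                     excluded))
    table = pd.DataFrame(rows, columns=[
        "cluster", "n_cells", "mean_treated", "mean_vehicle",
        "sd_treated", "sd_vehicle", "t", "p", "direction", "excluded"])
    table["p_adj"] = bh_adjust(table["p"])
    table["flagged"] = table["p_adj"] < alpha
    return AbundanceResult(fractions, table, alpha)


def run_abundance(dataset: Dataset, alpha: float = 0.2,
                  min_cells: int = 20,
                  min_dataset_fraction: float | None = None) -> AbundanceResult:
    """Convenience: fractions + tests straight from a Dataset."""
    fractions = cluster_fractions(dataset.cells)
    cond = dataset.condition_of_sample().map(
        {dataset.treated: "treated", dataset.vehicle: "vehicle"})
    counts = dataset.cells.groupby("cluster", observed=True).size()
    return test_abundance(fractions, cond, alpha=alpha, min_cells=min_cells,
                          cell_counts=counts,
                          min_dataset_fraction=min_dataset_fraction)
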