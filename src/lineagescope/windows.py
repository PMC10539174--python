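"""Sliding-window pseudotime statistics.

For each overlapping pseudotime window the per-sample fraction of cells
carrying each label (e.g. cell-cycle phase) is computed; conditions are
compared window by window with a two-tailed independent t-test on the
per-sample fractions and BH correction across the tested windows of each label.
Windows are half-open ``[start, start + width)`` with the final window
closed at 1. Defaults (width 0.01, step 0.0025, adjusted p < 0.05) follow
the published analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._stats import bh_adjust, student_ttest

__all__ = ["WindowGrid", "make_windows", "window_label_fractions",
           "test_windows", "run_windows"]


@dataclasses.dataclass(frozen=True)
class WindowGrid:
    width: float
    step: float
    starts: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.width

    def membership(self, t: np.ndarray, window: int) -> np.ndarray:
        """Boolean mask of pseudotimes inside window ``window``."""
        s, e = self.starts[window], self.starts[window] + self.width
        last = window == len(self.starts) - 1
        return (t >= s) & ((t <= e) if last else (t < e))


def make_windows(width: float = 0.01, step: float = 0.0025) -> WindowGrid:
    """Window grid on [0, 1]: starts 0, step, 2*step, ... while
    start + width <= 1 (within floating-point tolerance)."""
    if not (0.0 < step <= width < 1.0):
        raise ValueError("require 0 < step <= width < 1")
    n = int(np.floor((1.0 - width) / step + 1e-9)) + 1
    starts = np.arange(n) * step
    return WindowGrid(width, step, starts)


def window_label_fractions(cells: pd.DataFrame, label_column: str,
                           grid: WindowGrid, min_cells_per_window: int = 10,
                           pseudotime_column: str = "pseudotime"):
    """Per-sample label fractions in every window.

    Returns ``(fractions, n_cells)``: ``fractions`` is a DataFrame indexed by
    (window, label) with one column per sample (NaN where the sample has
    fewer than ``min_cells_per_window`` cells in the window), ``n_cells`` a
    (window x sample) DataFrame of in-window cell counts.
    """
    if label_column not in cells.columns:
        raise ValueError(f"label column {label_column!r} missing")
    if pseudotime_column not in cells.columns:
        raise ValueError(f"pseudotime column {pseudotime_column!r} missing")
    t = cells[pseudotime_column].to_numpy(dtype=float)
    ok = np.isfinite(t) & cells[label_column].notna().to_numpy()
    samples = pd.Index(sorted(cells["sample_id"].unique()))
    labels = pd.Index(sorted(cells.loc[ok, label_column].unique()))
    # sort once; window members are contiguous slices of the sorted order
    order = np.argsort(t[ok], kind="stable")
    ts = t[ok][order]
    si = samples.get_indexer(cells.loc[ok, "sample_id"].to_numpy()[order])
    li = labels.get_indexer(cells.loc[ok, label_column].to_numpy()[order])
    onehot = np.zeros((len(ts), len(samples) * len(labels)), dtype=np.int64)
    onehot[np.arange(len(ts)), si * len(labels) + li] = 1
    prefix = np.vstack([np.zeros(onehot.shape[1], dtype=np.int64),
                        np.cumsum(onehot, axis=0)])
    w = len(grid)
    frac = np.full((w, len(labels), len(samples)), np.nan)
    ncell = np.zeros((w, len(samples)), dtype=np.int64)
    for wi in range(w):
        lo = np.searchsorted(ts, grid.starts[wi], side="left")
        if wi == w - 1:
            hi = np.searchsorted(ts, grid.starts[wi] + grid.width, side="right")
        else:
            hi = np.searchsorted(ts, grid.starts[wi] + grid.width, side="left")
        counts = (prefix[hi] - prefix[lo]).reshape(len(samples), len(labels))
        tot = counts.sum(axis=1)
        ncell[wi] = tot
        good = tot >= min_cells_per_window
        with np.errstate(invalid="ignore", divide="ignore"):
            f = counts / tot[:, None]
        f[~good] = np.nan
        frac[wi] = f.T
    idx = pd.MultiIndex.from_product([range(w), labels],
                                     names=["window", "label"])
    fractions = pd.DataFrame(frac.reshape(w * len(labels), len(samples)),
                             index=idx, columns=samples)
    n_cells = pd.DataFrame(ncell, columns=samples)
    n_cells.index.name = "window"
    return fractions, n_cells


def test_windows(fractions: pd.DataFrame, conditions: pd.Series,
                 grid: WindowGrid, alpha: float = 0.05) -> pd.DataFrame:
    """Independent t-test per (window, label) on per-sample fractions; BH within
    each label across its tested windows.

    ``conditions`` maps sample -> 'treated'/'vehicle'. Windows with fewer
    than two non-missing samples in either condition are untested (p NaN).
    """
    conditions = conditions.reindex(fractions.columns)
    tr = fractions.columns[conditions == "treated"]
    ve = fractions.columns[conditions == "vehicle"]
    rows = []
    for (wi, label), row in fractions.iterrows():
        a = row[tr].dropna().to_numpy(dtype=float)
        b = row[ve].dropna().to_numpy(dtype=float)
        if len(a) >= 2 and len(b) >= 2:
            t, p = student_ttest(a, b)
        else:
            t, p = np.nan, np.nan
        rows.append((label, grid.starts[wi], grid.starts[wi] + grid.width,
                     len(a), len(b),
                     a.mean() if a.size else np.nan,
                     b.mean() if b.size else np.nan,
                     a.std(ddof=1) if a.size > 1 else np.nan,
                     b.std(ddof=1) if b.size > 1 else np.nan, t, p))
    table = pd.DataFrame(rows, columns=[
        "label", "window_start", "window_end", "n_treated_samples",
        "n_vehicle_samples", "mean_treated", "mean_vehicle", "sd_treated",
        "sd_vehicle", "t", "p"])
    table["p_adj"] = np.nan
    for label in table["label"].unique():
        m = table["label"] == label
        table.loc[m, "p_adj"] = bh_adjust(table.loc[m, "p"])
    table["significant"] = table["p_adj"] < alpha
    return table


def run_windows(cells: pd.DataFrame, label_column: str, conditions: pd.Series,
                width: float = 0.01, step: float = 0.0025,
                min_cells_per_window: int = 10, alpha: float = 0.05,
                pseudotime_column: str = "pseudotime") -> pd.DataFrame:
    """Grid -> fractions -> tests, in one call."""
    grid = make_windows(width, step)
    fractions, _ = window_label_fractions(
        cells, label_column, grid, min_cells_per_window,
        pseudotime_column=pseudotime_column)
    return test_windows(fractions, conditions, grid, alpha=alpha)
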