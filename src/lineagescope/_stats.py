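"""Shared statistical helpers: Welch t-tests and BH adjustment conventions.

Every condition comparison in the package goes through :func:`welch_ttest`
(two-tailed, unequal variances) and every multiple-testing family through
:func:`bh_adjust` so the conventions for degenerate inputs are defined in
exactly one place.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["welch_ttest", "student_ttest", "bh_adjust"]


def _ttest(a, b, equal_var: bool) -> tuple[float, float]:
    """Shared degenerate-input conventions:

    * both groups have zero variance and equal means -> ``(0.0, 1.0)``;
    * both groups have zero variance and different means -> ``(+/-inf, 0.0)``;
    * fewer than two observations in either group -> ``(nan, nan)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return float("nan"), float("nan")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-tailed Welch (unequal-variance) t-test; used for the per-cell
    comparisons, where group sizes are large. Returns ``(t, p)``."""
    return _ttest(a, b, equal_var=False)


def student_ttest(a, b) -> tuple[float, float]:
    """Two-tailed independent (pooled-variance) t-test; used for the
    replicate-level comparisons (3 vs 4 samples), where the
    Welch-Satterthwaite approximation is measurably conservative.
    Returns ``(t, p)``."""
    return _ttest(a, b, equal_var=True)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untested hypotheses) are passed through as NaN and do not
    count towards the family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() > 0:
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
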