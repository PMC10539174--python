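"""Independent oracles used by the tests: brute-force BH and Monte-Carlo
absorption probabilities. These deliberately avoid the package's own code
paths."""

from __future__ import annotations

import numpy as np


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """Step-up BH straight from the definition:
    adj_p(i) = min over j with rank(j) >= rank(i) of m * p(j) / rank(j),
    capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        rank = pos + 1
        running_min = min(running_min, m * p[i] / rank)
        adj[i] = min(running_min, 1.0)
    return adj


def monte_carlo_absorption(transition, macrostates: dict, walks_per_cell: int,
                           rng: np.random.Generator,
                           max_steps: int = 100_000) -> np.ndarray:
    """Estimate absorption probabilities by simulating random walks.

    ``transition`` is the (dense-able) row-stochastic matrix; terminal cells
    are absorbing rows. Returns an (n_cells x n_lineages) matrix of hit
    frequencies.
    """
    p = np.asarray(transition.todense() if hasattr(transition, "todense")
                   else transition, dtype=float)
    n = p.shape[0]
    lineages = list(macrostates)
    lineage_of = np.full(n, -1)
    for li, lineage in enumerate(lineages):
        lineage_of[np.asarray(macrostates[lineage], dtype=int)] = li
    cum = np.cumsum(p, axis=1)
    state = np.repeat(np.arange(n), walks_per_cell)
    start = state.copy()
    absorbed = lineage_of[state] >= 0
    for _ in range(max_steps):
        active = ~absorbed
        if not active.any():
            break
        s = state[active]
        u = rng.random(s.size)
        nxt = _step(cum, s, u)
        state[active] = nxt
        absorbed[active] = lineage_of[nxt] >= 0
    out = np.zeros((n, len(lineages)))
    hit = lineage_of[state]
    for li in range(len(lineages)):
        np.add.at(out[:, li], start[hit == li], 1.0)
    return out / walks_per_cell


def _step(cum: np.ndarray, states: np.ndarray, u: np.ndarray) -> np.ndarray:
    # vectorised categorical draw, grouped by current state
    nxt = np.empty(states.size, dtype=np.int64)
    for s in np.unique(states):
        m = states == s
        nxt[m] = np.searchsorted(cum[s], u[m], side="right")
    return nxt
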