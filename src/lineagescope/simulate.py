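"""Synthetic branching-haematopoiesis scRNA-seq experiments.

The generator emulates the structure of an LK HSPC perturbation study: a
rooted lineage tree from HSCs to seven terminal lineages, a small number of
replicate animals per condition (3 treated, 4 vehicle), and injectable
condition effects — lineage fate bias, a G1/quiescence shift over a
pseudotime interval, an inflammatory-signature upregulation, and global
differential expression. Counts are negative binomial around a smooth
branch-program mean structure.

Two stages: :func:`simulate_latent` draws the per-cell ground truth (lineage,
pseudotime, phase, cluster); :func:`simulate_counts` turns it into a count
matrix. All ground truth is exported on the resulting tables (``true_*`` cell
columns, flag columns on the gene table) so downstream tests can assert
recovery of every injected effect.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import Dataset, TREATED, VEHICLE

__all__ = [
    "LINEAGES",
    "DEFAULT_TREE",
    "SimulationConfig",
    "paper_fate_priors",
    "paper_like",
    "null_experiment",
    "simulate_latent",
    "simulate_counts",
    "simulate_experiment",
]

#: the seven terminal lineages
LINEAGES = ("neutrophil", "monocyte", "lymphoid", "erythroid",
            "megakaryocyte", "basophil", "mast")

#: default lineage tree. Every root->leaf path has four nodes so the
#: equal-split cluster intervals agree across paths on shared segments.
DEFAULT_TREE = {
    "HSC": ["MPP"],
    "MPP": ["GMP", "MEP", "CLP"],
    "GMP": ["neutrophil", "monocyte", "basophil", "mast"],
    "MEP": ["erythroid", "megakaryocyte"],
    "CLP": ["lymphoid"],
}

# Published cluster-mean fate probabilities used as simulator defaults:
# marginal erythroid and neutrophil fate at the HSC level, and the erythroid
# share of the MEP branch (erythroid vs megakaryocyte).
_ERY_HSC = {"treated": 0.12, "vehicle": 0.15}
_NEU_HSC = {"treated": 0.16, "vehicle": 0.12}
_ERY_GIVEN_MEP = {"treated": 0.46, "vehicle": 0.56}
# relative weights for the lineages the study reports no mean for
_REST_WEIGHTS = {"monocyte": 0.25, "lymphoid": 0.20, "basophil": 0.08,
                 "mast": 0.05}


def paper_fate_priors(role: str) -> dict:
    """Default fate prior over the seven lineages for ``role``
    ('treated' or 'vehicle'), built so the marginal erythroid/neutrophil
    probabilities and the erythroid share of the MEP branch equal the
    published cluster means."""
    ery = _ERY_HSC[role]
    neu = _NEU_HSC[role]
    mk = ery * (1.0 - _ERY_GIVEN_MEP[role]) / _ERY_GIVEN_MEP[role]
    rest = 1.0 - ery - neu - mk
    wsum = sum(_REST_WEIGHTS.values())
    priors = {"erythroid": ery, "neutrophil": neu, "megakaryocyte": mk}
    for k, w in _REST_WEIGHTS.items():
        priors[k] = rest * w / wsum
    return priors


def _tree_paths(tree: dict, root: str) -> dict:
    """Map leaf -> root..leaf node path; validates the tree is a rooted tree."""
    children = {k: list(v) for k, v in tree.items()}
    paths, stack = {}, [(root, [root])]
    seen = set()
    while stack:
        node, path = stack.pop()
        if node in seen:
            raise ValueError(f"lineage tree revisits node {node!r}")
        seen.add(node)
        kids = children.get(node, [])
        if not kids:
            paths[node] = path
        for c in kids:
            stack.append((c, path + [c]))
    return paths


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the paper-like study design."""

    tree: dict = dataclasses.field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_TREE.items()})
    root: str = "HSC"
    n_treated_samples: int = 3
    n_vehicle_samples: int = 4
    cells_per_sample: int = 1000
    n_genes: int = 2000
    treated_priors: dict = dataclasses.field(
        default_factory=lambda: paper_fate_priors("treated"))
    vehicle_priors: dict = dataclasses.field(
        default_factory=lambda: paper_fate_priors("vehicle"))
    # expression model
    program_genes_per_node: int = 30
    program_lfc: float = 2.5           # log2 fold-change at full ramp
    nb_dispersion: float = 0.1         # alpha in var = mu + alpha*mu^2; 0 = Poisson
    library_mu: float = math.log(5000.0)
    library_sigma: float = 0.35
    # cell-cycle block
    base_g1: float = 0.55
    base_s: float = 0.30
    base_g2m: float = 0.15
    g1_shift: float = 0.15             # added to treated G1 inside shift_interval
    shift_interval: tuple = (0.1, 0.6)
    s_program_genes: int = 40
    s_program_lfc: float = 1.0
    g2m_program_genes: int = 40
    g2m_program_lfc: float = 1.0
    # condition-wide effects on treated cells
    signature_genes: int = 50
    signature_lfc: float = 0.5
    de_up_genes: int = 150
    de_down_genes: int = 90
    de_lfc: float = 0.8
    treated_label: str = TREATED
    vehicle_label: str = VEHICLE
    seed: int = 0

    def __post_init__(self):
        self.leaf_paths = _tree_paths(self.tree, self.root)
        leaves = set(self.leaf_paths)
        for name, priors in (("treated_priors", self.treated_priors),
                             ("vehicle_priors", self.vehicle_priors)):
            if set(priors) != leaves:
                raise ValueError(
                    f"{name} keys {sorted(priors)} do not match tree leaves "
                    f"{sorted(leaves)}")
            vals = np.array([priors[k] for k in sorted(priors)], dtype=float)
            if (vals < 0).any():
                raise ValueError(f"{name} has negative entries")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {vals.sum()!r})")
        if self.n_treated_samples < 2 or self.n_vehicle_samples < 2:
            raise ValueError("need >= 2 samples per condition for t-tests")
        base = self.base_g1 + self.base_s + self.base_g2m
        if abs(base - 1.0) > 1e-9:
            raise ValueError("phase proportions must sum to 1")
        if self.base_g1 + self.g1_shift > 1.0 or self.base_g1 + self.g1_shift < 0:
            raise ValueError("shifted G1 proportion outside [0, 1]")
        if self._n_special_genes() > self.n_genes:
            raise ValueError(
                f"effect blocks need {self._n_special_genes()} genes but "
                f"n_genes = {self.n_genes}")

    def _nodes(self) -> list:
        # deterministic preorder
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.tree.get(node, [])))
        return order

    def _n_special_genes(self) -> int:
        return (len(self._nodes()) * self.program_genes_per_node
                + self.s_program_genes + self.g2m_program_genes
                + self.signature_genes + self.de_up_genes + self.de_down_genes)

    def phase_probs(self, role: str, t: np.ndarray) -> np.ndarray:
        """(n, 3) array of (G1, S, G2M) proportions at pseudotimes ``t``."""
        t = np.asarray(t, dtype=float)
        g1 = np.full(t.shape, self.base_g1)
        if role == "treated" and self.g1_shift != 0.0:
            lo, hi = self.shift_interval
            g1 = np.where((t >= lo) & (t <= hi), self.base_g1 + self.g1_shift, g1)
        rest = 1.0 - g1
        frac_s = self.base_s / (self.base_s + self.base_g2m)
        return np.stack([g1, rest * frac_s, rest * (1.0 - frac_s)], axis=1)


def paper_like(**overrides) -> SimulationConfig:
    """The default preset: the study design with all effects injected."""
    return SimulationConfig(**overrides)


def null_experiment(**overrides) -> SimulationConfig:
    """Preset with every condition effect removed (type-I error studies).

    Both conditions share the average fate prior; no G1 shift; the signature
    genes are still flagged but carry zero fold-change; no DE block.
    """
    tp, vp = paper_fate_priors("treated"), paper_fate_priors("vehicle")
    common = {k: 0.5 * (tp[k] + vp[k]) for k in tp}
    s = sum(common.values())
    common = {k: v / s for k, v in common.items()}
    defaults = dict(
        treated_priors=dict(common), vehicle_priors=dict(common),
        g1_shift=0.0, signature_lfc=0.0, de_up_genes=0, de_down_genes=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


# -- latent stage ----------------------------------------------------------

def _cluster_of(path: list, t: float) -> tuple:
    """(cluster, branch) for pseudotime ``t`` on ``path`` with equal splits."""
    m = len(path)
    idx = min(int(t * m), m - 1)
    cluster = path[idx]
    if idx == 0:
        branch = f"{path[0]}->{path[1]}" if m > 1 else path[0]
    else:
        branch = f"{path[idx - 1]}->{path[idx]}"
    return cluster, branch


def simulate_latent(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the latent cell table: one row per cell with sample, condition,
    assigned terminal lineage, true pseudotime/branch/phase/cluster."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    rows = []
    samples = (
        [(f"treated_{i + 1}", "treated", config.treated_label,
          config.treated_priors) for i in range(config.n_treated_samples)]
        + [(f"vehicle_{i + 1}", "vehicle", config.vehicle_label,
            config.vehicle_priors) for i in range(config.n_vehicle_samples)]
    )
    leaves = sorted(config.leaf_paths)
    for sample_id, role, label, priors in samples:
        n = config.cells_per_sample
        pvec = np.array([priors[l] for l in leaves], dtype=float)
        lineage_idx = rng.choice(len(leaves), size=n, p=pvec)
        t = rng.uniform(0.0, 1.0, size=n)
        probs = config.phase_probs(role, t)
        u = rng.uniform(size=n)
        cum = np.cumsum(probs, axis=1)
        phase_idx = (u[:, None] > cum).sum(axis=1)
        phases = np.array(["G1", "S", "G2M"])[phase_idx]
        for i in range(n):
            leaf = leaves[lineage_idx[i]]
            cluster, branch = _cluster_of(config.leaf_paths[leaf], t[i])
            rows.append((f"{sample_id}_c{i:05d}", sample_id, label, leaf,
                         t[i], branch, phases[i], cluster))
    df = pd.DataFrame(rows, columns=[
        "cell_id", "sample_id", "condition", "true_lineage", "true_pseudotime",
        "true_branch", "true_phase", "true_cluster"]).set_index("cell_id")
    return df


# -- counts stage ----------------------------------------------------------

def _gene_blocks(config: SimulationConfig) -> tuple:
    """Deterministic allocation of gene index blocks to effect programs."""
    blocks, cursor = {}, 0

    def take(n):
        nonlocal cursor
        idx = np.arange(cursor, cursor + n)
        cursor += n
        return idx

    node_blocks = {node: take(config.program_genes_per_node)
                   for node in config._nodes()}
    blocks["s"] = take(config.s_program_genes)
    blocks["g2m"] = take(config.g2m_program_genes)
    blocks["signature"] = take(config.signature_genes)
    blocks["de_up"] = take(config.de_up_genes)
    blocks["de_down"] = take(config.de_down_genes)
    return node_blocks, blocks


def _gene_table(config: SimulationConfig, baseline: np.ndarray) -> pd.DataFrame:
    node_blocks, blocks = _gene_blocks(config)
    n = config.n_genes
    genes = pd.DataFrame(index=pd.Index(
        [f"g{i:05d}" for i in range(n)], name="gene_id"))
    genes["baseline"] = baseline
    program = np.array([""] * n, dtype=object)
    for node, idx in node_blocks.items():
        program[idx] = node
    genes["program_node"] = program
    for key, col in (("s", "s_program"), ("g2m", "g2m_program"),
                     ("signature", "signature"), ("de_up", "de_up"),
                     ("de_down", "de_down")):
        flag = np.zeros(n, dtype=bool)
        flag[blocks[key]] = True
        genes[col] = flag
    return genes


def simulate_counts(latent: pd.DataFrame, config: SimulationConfig,
                    seed: int | None = None) -> Dataset:
    """Generate the count matrix for a latent cell table.

    Per-cell gene means are ``baseline * 2**(sum of active log2 effects) *
    library size`` (renormalised per cell), with branch programs ramping
    linearly in pseudotime across each node's interval on the cell's path,
    phase programs on S/G2M cells, and signature/DE effects on treated cells.
    Counts are negative binomial (``var = mu + alpha*mu^2``); ``alpha = 0``
    switches to Poisson.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    n_cells, n_genes = len(latent), config.n_genes
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    genes = _gene_table(config, baseline)
    if n_cells == 0:
        counts = sp.csr_matrix((0, n_genes), dtype=np.int64)
        cells = latent.copy()
        cells.insert(2, "cluster", pd.Series(dtype=object))
        return Dataset(counts, cells, genes,
                       treated=config.treated_label, vehicle=config.vehicle_label)

    node_blocks, blocks = _gene_blocks(config)
    t = latent["true_pseudotime"].to_numpy(dtype=float)
    log2fc = np.zeros((n_cells, n_genes), dtype=np.float32)

    # branch programs, ramped within each node's interval on the cell's path
    lineage = latent["true_lineage"].to_numpy()
    for leaf, path in config.leaf_paths.items():
        cells_mask = np.flatnonzero(lineage == leaf)
        if cells_mask.size == 0:
            continue
        m = len(path)
        tc = t[cells_mask]
        for i, node in enumerate(path):
            # priming: the program starts ramping one node early (at the
            # parent interval's start) and saturates at the node's own end,
            # so sibling corridors separate before their cluster boundary
            a, b = max(i - 1, 0) / m, (i + 1) / m
            ramp = np.clip((tc - a) / (b - a), 0.0, 1.0).astype(np.float32)
            idx = node_blocks[node]
            log2fc[np.ix_(cells_mask, idx)] += (
                ramp[:, None] * np.float32(config.program_lfc))

    phase = latent["true_phase"].to_numpy()
    log2fc[np.ix_(phase == "S", blocks["s"])] += np.float32(config.s_program_lfc)
    log2fc[np.ix_(phase == "G2M", blocks["g2m"])] += np.float32(
        config.g2m_program_lfc)

    treated_mask = np.flatnonzero(
        latent["condition"].to_numpy() == config.treated_label)
    log2fc[np.ix_(treated_mask, blocks["signature"])] += np.float32(
        config.signature_lfc)
    log2fc[np.ix_(treated_mask, blocks["de_up"])] += np.float32(config.de_lfc)
    log2fc[np.ix_(treated_mask, blocks["de_down"])] -= np.float32(config.de_lfc)

    rel = np.exp2(log2fc, out=log2fc)
    rel *= baseline.astype(np.float32)[None, :]
    rel /= rel.sum(axis=1, keepdims=True)
    lib = rng.lognormal(mean=config.library_mu, sigma=config.library_sigma,
                        size=n_cells)
    mu = rel * lib[:, None].astype(np.float32)

    alpha = config.nb_dispersion
    if alpha > 0:
        counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
    else:
        counts = rng.poisson(mu)
    counts = sp.csr_matrix(counts)

    cells = latent.copy()
    cells.insert(2, "cluster", latent["true_cluster"].to_numpy())
    return Dataset(counts, cells, genes,
                   treated=config.treated_label, vehicle=config.vehicle_label)


def simulate_experiment(config: SimulationConfig) -> Dataset:
    """Latent draw + count generation under the single config seed."""
    latent = simulate_latent(config, config.seed)
    return simulate_counts(latent, config, config.seed)
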