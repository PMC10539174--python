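"""Core data container, file formats and configuration.

The in-memory convention is **cells as rows, genes as columns** everywhere.
On disk the MatrixMarket file stores genes x cells (the common public single
cell convention, e.g. CellRanger-style triplets); :func:`read_dataset`
transposes on load and :func:`write_dataset` transposes back on save.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "Dataset",
    "AnalysisConfig",
    "GeneSignature",
    "LoadError",
    "read_dataset",
    "write_dataset",
    "read_gene_signature",
]

#: default condition labels, mirroring the experimental design
TREATED = "STM2457"
VEHICLE = "Vehicle"


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclasses.dataclass
class Dataset:
    """A cell x gene count matrix with cell and gene annotation tables.

    Parameters
    ----------
    counts
        Sparse (CSR) or dense non-negative integer matrix, cells x genes.
    cells
        Table indexed by ``cell_id`` with at least ``sample_id`` and
        ``condition``; optional ``cluster``, ``pseudotime``, ``phase`` and any
        number of extra columns (preserved verbatim).
    genes
        Table indexed by ``gene_id``; optional flag columns.
    treated, vehicle
        The declared condition label pair; every ``condition`` value must be
        one of the two.
    """

    counts: sp.spmatrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    treated: str = TREATED
    vehicle: str = VEHICLE

    def __post_init__(self):
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cells) != n_cells:
            raise LoadError(
                f"cells table has {len(self.cells)} rows but the matrix has "
                f"{n_cells} cells"
            )
        if len(self.genes) != n_genes:
            raise LoadError(
                f"genes table has {len(self.genes)} rows but the matrix has "
                f"{n_genes} genes"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            raise LoadError("count matrix has negative or non-integer entries")
        if "sample_id" not in self.cells.columns:
            raise LoadError("cells table lacks a sample_id column")
        if "condition" not in self.cells.columns:
            raise LoadError("cells table lacks a condition column")
        pair = {self.treated, self.vehicle}
        seen = set(self.cells["condition"].unique())
        if not seen <= pair:
            raise LoadError(
                f"condition values {sorted(seen - pair)} outside the declared "
                f"pair {sorted(pair)}"
            )
        percond = self.cells.groupby("sample_id", observed=True)["condition"].nunique()
        if (percond > 1).any():
            bad = percond[percond > 1].index.tolist()
            raise LoadError(f"samples mapped to more than one condition: {bad}")
        if "pseudotime" in self.cells.columns:
            pt = self.cells["pseudotime"].to_numpy(dtype=float)
            ok = np.isnan(pt) | ((pt >= 0.0) & (pt <= 1.0))
            if not ok.all():
                raise LoadError("pseudotime values outside [0, 1]")

    # -- conveniences -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    def condition_of_sample(self) -> pd.Series:
        """Mapping sample_id -> condition."""
        return self.cells.groupby("sample_id", observed=True)["condition"].first()

    def samples(self, condition: str | None = None) -> list:
        m = self.condition_of_sample()
        if condition is not None:
            m = m[m == condition]
        return list(m.index)


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable analysis parameters with their defaults.

    The sliding-window geometry (width 0.01, step 0.0025) and the two
    significance thresholds (0.2 for abundance, 0.05 for windows) follow the
    published analysis; the remainder are this package's own defaults.
    """

    window_width: float = 0.01
    window_step: float = 0.0025
    window_alpha: float = 0.05
    abundance_alpha: float = 0.2
    knn_k: int = 40
    n_pcs: int = 30
    n_hvg: int = 600
    terminal_quantile: float = 0.9
    directionality_beta: float = 5.0
    min_cells_per_window: int = 10
    min_cells_per_cluster: int = 20
    trajectory_threshold: float = 0.5
    n_bins: int = 25
    n_ctrl: int = 50
    n_knots: int = 6
    tde_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.window_step <= self.window_width < 1.0):
            raise ValueError("require 0 < window_step <= window_width < 1")
        for name in ("window_alpha", "abundance_alpha", "tde_alpha"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("knn_k", "n_pcs", "n_hvg", "min_cells_per_window",
                     "n_bins", "n_ctrl"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer")
        if self.directionality_beta < 0:
            raise ValueError("directionality_beta must be >= 0")
        if not (0.0 <= self.terminal_quantile <= 1.0):
            raise ValueError("terminal_quantile must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene set (duplicates are a load error)."""

    name: str
    gene_ids: tuple

    def __post_init__(self):
        if len(self.gene_ids) == 0:
            raise LoadError(f"signature {self.name!r} is empty")
        seen, dups = set(), []
        for g in self.gene_ids:
            if g in seen:
                dups.append(g)
            seen.add(g)
        if dups:
            raise LoadError(
                f"signature {self.name!r} lists duplicate genes: {sorted(set(dups))}"
            )

    def __len__(self) -> int:
        return len(self.gene_ids)


# -- readers / writers -----------------------------------------------------

def _read_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 1:
        raise LoadError(f"{kind} table {path} has no columns")
    df = df.set_index(df.columns[0])
    if df.index.has_duplicates:
        raise LoadError(f"{kind} table {path} has duplicate ids")
    return df


def read_dataset(matrix_path, cells_path, genes_path,
                 treated: str = TREATED, vehicle: str = VEHICLE) -> Dataset:
    """Load a Dataset from MatrixMarket counts plus cell/gene TSV tables.

    The matrix on disk is genes x cells (1-based coordinate format) and is
    transposed to the in-memory cells x genes orientation.
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # pragma: no cover - message path
        raise LoadError(f"cannot parse MatrixMarket file {matrix_path}: {exc}")
    mat = sp.csr_matrix(mat).T  # disk genes x cells -> memory cells x genes
    cells = _read_table(cells_path, "cells")
    genes = _read_table(genes_path, "genes")
    if len(cells) != mat.shape[0]:
        raise LoadError(
            f"{cells_path}: {len(cells)} rows but matrix has {mat.shape[0]} cells"
        )
    if len(genes) != mat.shape[1]:
        raise LoadError(
            f"{genes_path}: {len(genes)} rows but matrix has {mat.shape[1]} genes"
        )
    return Dataset(mat, cells, genes, treated=treated, vehicle=vehicle)


def write_dataset(ds: Dataset, outdir) -> dict:
    """Write matrix.mtx (genes x cells, integer) + cells.tsv + genes.tsv.

    Round-trips through :func:`read_dataset` exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "cells": outdir / "cells.tsv",
        "genes": outdir / "genes.tsv",
    }
    coo = sp.coo_matrix(ds.counts.T)
    scipy.io.mmwrite(paths["matrix"], coo, field="integer")
    ds.cells.rename_axis("cell_id").reset_index().to_csv(
        paths["cells"], sep="\t", index=False)
    ds.genes.rename_axis("gene_id").reset_index().to_csv(
        paths["genes"], sep="\t", index=False)
    return paths


def read_gene_signature(path, name: str | None = None) -> GeneSignature:
    """Read a gene set from a one-gene-per-line file or a single-line GMT.

    GMT lines are ``name<TAB>description<TAB>gene1<TAB>gene2...``; a file is
    treated as GMT when its first line contains tabs.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise LoadError(f"gene signature file {path} is empty")
    if "\t" in lines[0]:
        fields = lines[0].split("\t")
        if len(fields) < 3:
            raise LoadError(f"GMT line in {path} has fewer than 3 fields")
        return GeneSignature(name or fields[0], tuple(fields[2:]))
    return GeneSignature(name or path.stem, tuple(lines))
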