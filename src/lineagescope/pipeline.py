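"""Config-driven orchestration of the analysis stages.

A run is described by one YAML/JSON config naming either an input dataset or
a simulation block, the stages to run, and parameter overrides. Every stage
writes one or more TSVs with a fixed column order into the output directory;
a machine-readable run log (config echo, seed, stage timings) is written at
the end. Re-running with the same config and seed reproduces byte-identical
result tables.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .abundance import run_abundance
from .fate import run_fate
from .io import (AnalysisConfig, Dataset, GeneSignature, read_dataset,
                 write_dataset, TREATED, VEHICLE)
from .preprocess import preprocess_dataset
from .scoring import assign_phase, builtin_cycle_signature, score_signature
from .trajectory_de import (fit_condition_smoothers, pseudobulk_condition_de,
                            test_condition_dynamics)
from .windows import run_windows

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "load", "preprocess", "phase", "score", "abundance",
          "fate", "windows", "tde", "pseudobulk")

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage is missing a prerequisite or the config is inconsistent."""


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return path


def _signature_from_truth(ds: Dataset, column: str, name: str) -> GeneSignature:
    if column not in ds.genes.columns:
        raise PipelineError(
            f"no signature file configured and the gene table has no "
            f"{column!r} ground-truth column")
    genes = tuple(ds.gene_ids[ds.genes[column].astype(bool)])
    return GeneSignature(name, genes)


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: dict):
        self.config = config
        self.outdir = Path(config.get("output_dir", "lineagescope_out"))
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 0))
        cond = config.get("conditions", {})
        self.treated = cond.get("treated", TREATED)
        self.vehicle = cond.get("vehicle", VEHICLE)
        params = dict(config.get("analysis", {}))
        params.setdefault("rng_seed", self.seed)
        self.analysis = AnalysisConfig(**params)
        self.ds: Dataset | None = None
        self.normalized = None
        self.hvg = None
        self.graph = None
        self.pseudotime = None
        self.phase = None
        self.fate = None
        self.outputs: dict[str, list] = {}

    # -- prerequisites ----------------------------------------------------
    def require_dataset(self, stage: str) -> Dataset:
        if self.ds is None:
            raise PipelineError(
                f"stage {stage!r} needs a dataset; run the 'simulate' or "
                f"'load' stage first")
        return self.ds

    def require_pseudotime(self, stage: str) -> np.ndarray:
        if self.pseudotime is None:
            ds = self.require_dataset(stage)
            if "pseudotime" in ds.cells.columns:
                self.pseudotime = ds.cells["pseudotime"].to_numpy(dtype=float)
            else:
                raise PipelineError(
                    f"stage {stage!r} needs pseudotime; run the 'preprocess' "
                    f"stage first")
        return self.pseudotime

    def require_preprocess(self, stage: str):
        if self.graph is None:
            raise PipelineError(
                f"stage {stage!r} needs the embedding graph; run the "
                f"'preprocess' stage first")

    def require_fate(self, stage: str) -> pd.DataFrame:
        if self.fate is None:
            raise PipelineError(
                f"stage {stage!r} needs fate probabilities; run the 'fate' "
                f"stage first")
        return self.fate

    def trajectory_mask(self, lineage: str | None, stage: str) -> np.ndarray:
        ds = self.require_dataset(stage)
        if lineage is None:
            return np.ones(ds.n_cells, dtype=bool)
        fate = self.require_fate(stage)
        if lineage not in fate.columns:
            raise PipelineError(f"unknown trajectory lineage {lineage!r}")
        return (fate[lineage] > self.analysis.trajectory_threshold).to_numpy()

    def conditions_role(self) -> pd.Series:
        ds = self.require_dataset("conditions")
        return ds.condition_of_sample().map(
            {self.treated: "treated", self.vehicle: "vehicle"})

    # -- stages -----------------------------------------------------------
    def stage_simulate(self):
        block = dict(self.config.get("simulate", {}))
        preset = block.pop("preset", "paper_like")
        block.setdefault("seed", self.seed)
        block.setdefault("treated_label", self.treated)
        block.setdefault("vehicle_label", self.vehicle)
        maker = {"paper_like": sim.paper_like, "null": sim.null_experiment}
        if preset not in maker:
            raise PipelineError(f"unknown simulation preset {preset!r}")
        cfg = maker[preset](**block)
        self.ds = sim.simulate_experiment(cfg)
        paths = write_dataset(self.ds, self.outdir)
        self.outputs["simulate"] = [str(p) for p in paths.values()]

    def stage_load(self):
        block = self.config.get("input")
        if not block:
            raise PipelineError("config has no 'input' block to load from")
        self.ds = read_dataset(block["matrix"], block["cells"], block["genes"],
                               treated=self.treated, vehicle=self.vehicle)
        self.outputs["load"] = []

    def stage_preprocess(self):
        ds = self.require_dataset("preprocess")
        a = self.analysis
        root = self.config.get("root_cell_id")
        self.normalized, self.hvg, self.graph, self.pseudotime, unreachable = \
            preprocess_dataset(ds, a.n_hvg, a.n_pcs, a.knn_k,
                               root_cell_id=root)
        ds.cells["pseudotime"] = self.pseudotime
        pt = pd.DataFrame({"cell_id": ds.cell_ids,
                           "pseudotime": self.pseudotime,
                           "unreachable": unreachable})
        emb = pd.DataFrame(
            self.graph.embedding,
            columns=[f"PC{i + 1}" for i in range(self.graph.embedding.shape[1])])
        emb.insert(0, "cell_id", ds.cell_ids)
        n, k = self.graph.neighbors.shape
        edges = pd.DataFrame({
            "source": np.repeat(ds.cell_ids.to_numpy(), k),
            "target": ds.cell_ids.to_numpy()[self.graph.neighbors.ravel()],
            "distance": self.graph.distances.ravel()})
        self.outputs["preprocess"] = [str(_write(pt, self.outdir / "pseudotime.tsv")),
                                      str(_write(emb, self.outdir / "embedding.tsv")),
                                      str(_write(edges, self.outdir / "edges.tsv"))]

    def _cycle_signatures(self) -> tuple[GeneSignature, GeneSignature]:
        ds = self.require_dataset("phase")
        block = self.config.get("cycle_genes", {})
        if "s" in block and "g2m" in block:
            from .io import read_gene_signature
            return (read_gene_signature(block["s"], "S_phase"),
                    read_gene_signature(block["g2m"], "G2M_phase"))
        if "s_program" in ds.genes.columns:
            return (_signature_from_truth(ds, "s_program", "S_phase"),
                    _signature_from_truth(ds, "g2m_program", "G2M_phase"))
        return builtin_cycle_signature("s"), builtin_cycle_signature("g2m")

    def stage_phase(self):
        ds = self.require_dataset("phase")
        if self.normalized is None:
            raise PipelineError(
                "stage 'phase' needs normalized expression; run the "
                "'preprocess' stage first")
        s_sig, g2m_sig = self._cycle_signatures()
        a = self.analysis
        self.phase = assign_phase(ds, self.normalized, s_sig, g2m_sig,
                                  n_bins=a.n_bins, n_ctrl=a.n_ctrl,
                                  seed=a.rng_seed)
        ds.cells["phase"] = self.phase.phase
        out = pd.DataFrame({"cell_id": ds.cell_ids,
                            "s_score": self.phase.s_score,
                            "g2m_score": self.phase.g2m_score,
                            "phase": self.phase.phase})
        self.outputs["phase"] = [str(_write(out, self.outdir / "phase.tsv"))]

    def stage_score(self):
        ds = self.require_dataset("score")
        if self.normalized is None:
            raise PipelineError(
                "stage 'score' needs normalized expression; run the "
                "'preprocess' stage first")
        block = self.config.get("signature", {})
        if block.get("path"):
            from .io import read_gene_signature
            signature = read_gene_signature(block["path"], block.get("name"))
        else:
            signature = _signature_from_truth(
                ds, "signature", block.get("name", "defense_to_virus"))
        a = self.analysis
        res = score_signature(ds, self.normalized, signature,
                              n_bins=a.n_bins, n_ctrl=a.n_ctrl, seed=a.rng_seed)
        cell_out = pd.DataFrame({"cell_id": ds.cell_ids,
                                 "score": res.scores})
        self.outputs["score"] = [
            str(_write(cell_out, self.outdir / "signature_scores.tsv")),
            str(_write(res.cluster_table,
                       self.outdir / "signature_cluster_tests.tsv"))]

    def stage_abundance(self):
        ds = self.require_dataset("abundance")
        if "cluster" not in ds.cells.columns:
            raise PipelineError("stage 'abundance' needs a cluster column")
        a = self.analysis
        res = run_abundance(ds, alpha=a.abundance_alpha,
                            min_cells=a.min_cells_per_cluster,
                            min_dataset_fraction=self.config.get(
                                "min_dataset_fraction"))
        frac = res.fractions.reset_index()
        self.outputs["abundance"] = [
            str(_write(res.table, self.outdir / "abundance.tsv")),
            str(_write(frac, self.outdir / "cluster_fractions.tsv"))]

    def stage_fate(self):
        ds = self.require_dataset("fate")
        self.require_preprocess("fate")
        pt = self.require_pseudotime("fate")
        a = self.analysis
        self.fate, table, _ = run_fate(
            ds, self.graph, pt, beta=a.directionality_beta,
            terminal_quantile=a.terminal_quantile, scale=None)
        out = self.fate.reset_index().rename(columns={"index": "cell_id"})
        self.outputs["fate"] = [
            str(_write(out, self.outdir / "fate_probs.tsv")),
            str(_write(table, self.outdir / "fate_cluster_tests.tsv"))]

    def stage_windows(self):
        ds = self.require_dataset("windows")
        self.require_pseudotime("windows")
        block = self.config.get("windows", {})
        label = block.get("label", "phase")
        if label not in ds.cells.columns:
            raise PipelineError(
                f"stage 'windows' needs a {label!r} cell column; run the "
                f"'phase' stage first" if label == "phase" else
                f"stage 'windows' needs a {label!r} cell column")
        mask = self.trajectory_mask(block.get("trajectory"), "windows")
        a = self.analysis
        cells = ds.cells.loc[mask]
        table = run_windows(cells, label, self.conditions_role(),
                            width=a.window_width, step=a.window_step,
                            min_cells_per_window=a.min_cells_per_window,
                            alpha=a.window_alpha)
        self.outputs["windows"] = [
            str(_write(table, self.outdir / "windows.tsv"))]

    def stage_tde(self):
        ds = self.require_dataset("tde")
        pt = self.require_pseudotime("tde")
        if self.normalized is None:
            raise PipelineError(
                "stage 'tde' needs normalized expression; run the "
                "'preprocess' stage first")
        block = self.config.get("tde", {})
        mask = self.trajectory_mask(block.get("trajectory", "erythroid"),
                                    "tde")
        genes = block.get("genes", "hvg")
        if genes == "hvg" and self.hvg is not None:
            gmask = self.hvg
        else:
            gmask = np.ones(ds.n_genes, dtype=bool)
        cond = ds.cells["condition"].to_numpy()
        a = self.analysis
        fit = fit_condition_smoothers(
            self.normalized[:, gmask], pt, cond, trajectory_mask=mask,
            n_knots=a.n_knots, gene_ids=ds.gene_ids[gmask],
            treated=self.treated, vehicle=self.vehicle)
        table = test_condition_dynamics(fit, alpha=a.tde_alpha)
        self.outputs["tde"] = [str(_write(table, self.outdir / "tde.tsv"))]

    def stage_pseudobulk(self):
        ds = self.require_dataset("pseudobulk")
        table = pseudobulk_condition_de(ds, alpha=self.analysis.tde_alpha)
        self.outputs["pseudobulk"] = [
            str(_write(table, self.outdir / "pseudobulk_de.tsv"))]


def run_pipeline(config) -> dict:
    """Run the configured stages; ``config`` is a path to YAML/JSON or a dict.

    Returns ``{"outputs": {stage: [paths]}, "log": path}``.
    """
    if not isinstance(config, dict):
        text = Path(config).read_text()
        config = yaml.safe_load(text)
    run = _Run(config)
    stages = config.get("stages")
    if not stages:
        raise PipelineError("config lists no stages to run")
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    timings = {}
    for stage in stages:
        t0 = time.perf_counter()
        getattr(run, f"stage_{stage}")()
        timings[stage] = round(time.perf_counter() - t0, 4)
    log = {
        "config": {k: v for k, v in config.items() if k != "output_dir"},
        "seed": run.seed,
        "stage_timings_s": timings,
        "outputs": run.outputs,
    }
    log_path = run.outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str))
    return {"outputs": run.outputs, "log": str(log_path)}
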