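"""End-to-end orchestration: simulate/load -> DMC -> DEG -> NPC -> cluster
-> pathway model, with deterministic seeding and per-stage outputs.

Each stage writes its table under the run directory and the run ends
with ``summary.json`` holding the feature counts surviving each stage
(sites filtered, DMC, DEG, NPCG, cluster sizes) plus pathway fits.
Rerunning with the same configuration reproduces identical bytes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .annotation import annotate_sites, genes_of
from .cluster import cluster_npcg, normalize_log, pca_samples
from .containers import SampleTable
from .methylation import filter_coverage, global_methylation, test_dmc
from .expression import test_deg
from .npc import build_gene_omics, npc_combine
from .pathway import assemble_pathway, fit_pathway_model
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Thresholds, filter settings and inputs of a pipeline run."""

    seed: int = 0
    simulation: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)  # paths when not simulating
    q_dmc: float = 0.05
    fdr_deg: float = 0.05
    p_npc: float = 0.05
    alpha_pathway: float = 0.05
    permutations: int = 1000
    promoter_halfwidth: int = 1000
    shore_width: int = 2000
    min_coverage: int = 10
    coverage_quantile: float = 0.999
    covariates: list[str] | None = None
    pathway_sets: dict = field(default_factory=dict)  # name -> list of genes

    def __post_init__(self) -> None:
        for name in ("q_dmc", "fdr_deg", "p_npc", "alpha_pathway"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.promoter_halfwidth <= 0 or self.shore_width <= 0:
            raise ValueError("promoter/shore widths must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _stage(name: str):
    def deco(func):
        def wrapper(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # ------------------------------------------------------------- inputs
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = SimulationConfig(**{**asdict(sim), "seed": config.seed})
        ann, meth, counts, samples, truth = _simulate(sim)
        io.write_annotation_beds(ann, outdir / "annotation")
        io.write_bismark_coverage(meth, outdir / "methylation")
        io.write_counts(counts, outdir / "counts.tsv")
        io.write_sample_sheet(samples, outdir / "samples.tsv")
        io.write_table(truth.cpg, outdir / "truth_cpg.tsv", index=False)
        io.write_table(truth.genes, outdir / "truth_genes.tsv", index=False)
    else:
        ann, meth, counts, samples = _load_inputs(config)
    summary["n_sites_raw"] = int(meth.n_sites)
    summary["n_genes"] = int(counts.shape[0])

    summary["global_methylation_pct"] = {
        s: round(global_methylation(meth, s), 4) for s in meth.samples}

    # ------------------------------------------------------ methylation
    filtered = _filter(meth, config)
    summary["n_sites_filtered"] = int(filtered.n_sites)
    dmc = _dmc(filtered, samples, config)
    io.write_table(dmc, outdir / "dmc.tsv", index=False)
    summary["n_dmc"] = int((dmc["status"] != "ns").sum())

    # ------------------------------------------------------- annotation
    site_ann = _annotate(filtered, ann)
    io.write_table(site_ann, outdir / "site_annotation.tsv", index=False)
    dmc_genes = genes_of(dmc, site_ann, genic_only=False)
    summary["n_dmc_genes"] = len(dmc_genes)

    # ------------------------------------------------------- expression
    deg = _deg(counts, samples, config)
    io.write_table(deg, outdir / "deg.tsv")
    summary["n_deg"] = int((deg["status"] != "ns").sum())

    # --------------------------------------------------------------- npc
    npc_table = _npc(filtered, site_ann, counts, samples, config)
    io.write_table(npc_table, outdir / "npc.tsv")
    npcg = npc_table.index[npc_table["is_npcg"]].tolist()
    summary["n_npc_genes_tested"] = int(len(npc_table))
    summary["n_npcg"] = len(npcg)

    # --------------------------------------------------------- ordination
    pca_coords, pca_var = pca_samples(counts, normalized=True)
    io.write_table(pca_coords, outdir / "pca_expression.tsv")
    summary["pca_var_explained"] = [round(float(v), 6) for v in pca_var[:3]]

    # ---------------------------------------------------------- clustering
    if len(npcg) >= 2:
        expr = normalize_log(counts.loc[npcg])
        expr = expr.sub(expr.median(axis=1), axis=0)
        cres = _cluster(expr)
        io.write_table(cres.assignment.to_frame(), outdir / "npcg_clusters.tsv")
        sizes = cres.assignment.value_counts().sort_index()
        summary["npcg_cluster_sizes"] = [int(v) for v in sizes]
    else:
        summary["npcg_cluster_sizes"] = []

    # ------------------------------------------------------ pathway model
    pw_summary = {}
    gene_meth = (build_gene_omics(filtered, site_ann, counts).proportions)
    for name, genes in (config.pathway_sets or {}).items():
        try:
            pdata = assemble_pathway(list(genes), gene_meth, counts,
                                     pathway_id=name)
            fit = fit_pathway_model(pdata, samples,
                                    alpha=config.alpha_pathway)
            io.write_table(fit.predictions,
                           outdir / f"pathway_{name}_predictions.tsv",
                           index=False)
            pw_summary[name] = {
                "coef": {k: round(float(v), 6) for k, v in fit.coef.items()},
                "p_values": {k: round(float(v), 6)
                             for k, v in fit.p_values.items()},
                "dispersion": round(fit.dispersion, 6),
                "interaction_dropped": fit.interaction_dropped,
            }
        except (ValueError, RuntimeError) as exc:
            raise StageError(f"stage 'pathway_model' failed for {name!r}: "
                             f"{exc}") from exc
    summary["pathway_fits"] = pw_summary

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


_simulate = _stage("simulate")(simulate_dataset)


@_stage("load_inputs")
def _load_inputs(config: PipelineConfig):
    inp = config.inputs
    ann = io.read_annotation_beds(inp["tss"], inp["exons"], inp["cpg_islands"],
                                  promoter_halfwidth=config.promoter_halfwidth,
                                  shore_width=config.shore_width)
    samples = io.read_sample_sheet(inp["samples"],
                                   reference=inp.get("reference"))
    meth = io.read_bismark_coverage(
        {s: inp["coverage"][s] for s in samples.sample_ids})
    counts = io.read_counts(inp["counts"])
    return ann, meth, counts, samples


@_stage("filter_coverage")
def _filter(meth, config):
    return filter_coverage(meth, min_cov=config.min_coverage,
                           upper_quantile=config.coverage_quantile)


@_stage("dmc")
def _dmc(filtered, samples: SampleTable, config):
    return test_dmc(filtered, samples, qvalue_threshold=config.q_dmc,
                    covariates=config.covariates)


@_stage("annotate")
def _annotate(filtered, ann):
    return annotate_sites(filtered.sites, ann)


@_stage("deg")
def _deg(counts, samples, config):
    return test_deg(counts, samples, fdr_threshold=config.fdr_deg,
                    covariates=config.covariates)


@_stage("npc")
def _npc(filtered, site_ann, counts, samples, config):
    go = build_gene_omics(filtered, site_ann, counts)
    seed = int(np.random.SeedSequence([config.seed, 404]).generate_state(1)[0]
               % (2**31))
    return npc_combine(go, samples, B=config.permutations, seed=seed,
                       threshold=config.p_npc)


@_stage("cluster")
def _cluster(expr):
    return cluster_npcg(expr, k=2)
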