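"""End-to-end workflow: simulate/load → differential → profiling →
correlations → networks → stratification → survival.

One :class:`PipelineConfig` carries every stage threshold; the defaults
are the standard settings of this analysis (FC ≥ 1.4, p ≤ 0.05 for
differential calls;
|r| ≥ 0.3 with p ≤ 0.05 for expression/protein correlations and p ≤ 0.01
for per-cohort methylation–expression correlations; ≥ 5-cohort gene–protein
and ≥ 20-cohort protein–protein network filters; 7 correlation-profile
clusters). Every stage writes TSV (plus SIF/GraphML for networks) and the
run ends with a JSON manifest recording parameters and the SHA-256 of every
output, so identical config + seed gives identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import correlation, diffexpr, network, profiling, stratification, survival
from .correlation import CorrelationThresholds
from .data_model import (
    OmicsMatrix,
    read_annotation,
    read_matrix,
    read_metadata,
    read_survival,
)
from .synthetic_cohort import (
    SimulationConfig,
    SyntheticBundle,
    generate,
    read_bundle,
    write_bundle,
)

logger = logging.getLogger("panmethnet")

STAGES = (
    "diffexpr", "profiling", "correlation", "network", "clustering",
    "stratification", "survival",
)


@dataclass
class PipelineConfig:
    input_dir: str | None = None  # load a written bundle; None → simulate
    out_dir: str = "panmethnet-out"
    seed: int = 0
    fc_min: float = 1.4
    p_max: float = 0.05
    r_min: float = 0.3
    p_corr_expression: float = 0.05
    p_corr_methylation: float = 0.01
    min_cohorts_gene_protein: int = 5
    min_cohorts_protein_protein: int = 20
    n_clusters: int = 7
    stratification_gene: str = "SLC22A17"
    promoter_probe: str = "cg-SLC22A17-promoter-01"
    body_probe: str = "cg-SLC22A17-body-01"
    stratification_center: str = "median"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim_raw:
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"unknown simulation keys: {sorted(bad)}")
            cfg.simulation = dataclasses.replace(SimulationConfig(), **sim_raw)
        return cfg


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty means valid."""
    problems = []
    for name in ("fc_min", "p_max", "r_min", "p_corr_expression",
                 "p_corr_methylation"):
        if getattr(config, name) <= 0:
            problems.append(f"{name} must be positive")
    for name in ("min_cohorts_gene_protein", "min_cohorts_protein_protein",
                 "n_clusters"):
        if getattr(config, name) < 1:
            problems.append(f"{name} must be >= 1")
    if config.stratification_center not in ("median", "mean"):
        problems.append("stratification_center must be median or mean")
    if config.input_dir is not None and not Path(config.input_dir).is_dir():
        problems.append(f"input_dir {config.input_dir} does not exist")
    try:
        config.simulation.validate()
    except ValueError as exc:
        problems.append(str(exc))
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.10g")


def _load_or_simulate(config: PipelineConfig) -> SyntheticBundle:
    if config.input_dir is not None:
        logger.info("loading bundle from %s", config.input_dir)
        return read_bundle(config.input_dir)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    logger.info("simulating bundle: %d cohorts, seed %d", sim.n_cohorts, sim.seed)
    return generate(sim)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write every artifact under ``config.out_dir``,
    and return the manifest (also written as manifest.json)."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k != "simulation"
        },
        "stages": {},
        "outputs": {},
    }
    produced: dict[str, Path] = {}

    def _finish_stage(name: str, started: float, files: dict[str, Path]) -> None:
        produced.update(files)
        manifest["stages"][name] = {
            "status": "ok",
            "outputs": sorted(p.name for p in files.values()),
            "seconds": round(time.monotonic() - started, 3),
        }
        logger.info("stage %s done (%.2fs)", name, time.monotonic() - started)

    current = "inputs"
    try:
        t0 = time.monotonic()
        bundle = _load_or_simulate(config)
        inputs_dir = out / "inputs"
        write_bundle(bundle, inputs_dir)
        _finish_stage("inputs", t0, {
            name: inputs_dir / fname
            for name, fname in (
                ("expression", "expression.tsv"), ("methylation", "methylation.tsv"),
                ("protein", "protein.tsv"), ("annotation", "annotation.tsv"),
                ("phenotype", "phenotype.tsv"), ("survival", "survival.tsv"),
                ("truth", "truth.tsv"),
            )
        })

        annotation = bundle.annotation
        gene_ids = list(
            annotation.loc[annotation["feature_class"] == "gene", "feature_id"]
        )

        current = "diffexpr"
        t0 = time.monotonic()
        pooled = diffexpr.differential_table(
            bundle.expression, bundle.metadata, mode="pooled",
            thresholds=(config.fc_min, config.p_max),
        )
        percohort = diffexpr.differential_table(
            bundle.expression, bundle.metadata, mode="per_cohort",
            thresholds=(config.fc_min, config.p_max),
        )
        summary = diffexpr.cohort_call_summary(percohort)
        files = {
            "diff_pooled": out / "differential_pooled.tsv",
            "diff_per_cohort": out / "differential_per_cohort.tsv",
            "diff_summary": out / "differential_cohort_summary.tsv",
            "diff_volcano": out / "differential_volcano.tsv",
        }
        _write_tsv(pooled, files["diff_pooled"])
        _write_tsv(percohort, files["diff_per_cohort"])
        _write_tsv(summary, files["diff_summary"])
        _write_tsv(diffexpr.volcano_table(percohort), files["diff_volcano"])
        _finish_stage("diffexpr", t0, files)

        current = "profiling"
        t0 = time.monotonic()
        expr_profiles = profiling.profile_expression(
            bundle.expression, bundle.metadata
        )
        meth_profiles = profiling.profile_methylation(
            bundle.methylation, bundle.metadata
        )
        files = {
            "profile_expression": out / "profile_expression.tsv",
            "profile_methylation": out / "profile_methylation.tsv",
            "grid_expression": out / "call_grid_expression.tsv",
            "grid_methylation": out / "call_grid_methylation.tsv",
        }
        _write_tsv(expr_profiles, files["profile_expression"])
        _write_tsv(meth_profiles, files["profile_methylation"])
        _write_tsv(profiling.call_matrix(expr_profiles),
                   files["grid_expression"], index=True)
        _write_tsv(profiling.call_matrix(meth_profiles),
                   files["grid_methylation"], index=True)
        _finish_stage("profiling", t0, files)

        current = "correlation"
        t0 = time.monotonic()
        expr_thr = CorrelationThresholds(config.r_min, config.p_corr_expression)
        meth_thr = CorrelationThresholds(config.r_min, config.p_corr_methylation)
        expr_expr = correlation.correlate_sets(
            bundle.expression, bundle.expression, bundle.metadata,
            mode="pooled", thresholds=expr_thr,
        )
        expr_prot_pooled = correlation.correlate_sets(
            bundle.expression, bundle.protein, bundle.metadata,
            mode="pooled", thresholds=expr_thr, source="tumor",
        )
        expr_prot = correlation.correlate_sets(
            bundle.expression.subset_features(gene_ids), bundle.protein,
            bundle.metadata, mode="per_cohort", thresholds=expr_thr,
            source="tumor",
        )
        gene_gene = correlation.correlate_sets(
            bundle.expression.subset_features(gene_ids),
            bundle.expression.subset_features(gene_ids),
            bundle.metadata, mode="per_cohort", thresholds=expr_thr,
            source="tumor",
        )
        prot_prot = correlation.correlate_sets(
            bundle.protein, bundle.protein, bundle.metadata,
            mode="per_cohort", thresholds=expr_thr, source="tumor",
        )
        expr_meth_pooled = correlation.correlate_sets(
            bundle.expression, bundle.methylation, bundle.metadata,
            mode="pooled", thresholds=expr_thr, source="tumor",
        )
        expr_meth = correlation.correlate_sets(
            bundle.expression.subset_features(gene_ids), bundle.methylation,
            bundle.metadata, mode="per_cohort", thresholds=meth_thr,
            source="tumor",
        )
        files = {
            "corr_expr_expr": out / "correlation_expression_pooled.tsv",
            "corr_expr_prot_pooled": out / "correlation_protein_pooled.tsv",
            "corr_expr_prot": out / "correlation_protein_per_cohort.tsv",
            "corr_prot_prot": out / "correlation_protein_protein.tsv",
            "corr_expr_meth_pooled": out / "correlation_methylation_pooled.tsv",
            "corr_expr_meth": out / "correlation_methylation_per_cohort.tsv",
        }
        _write_tsv(expr_expr, files["corr_expr_expr"])
        _write_tsv(expr_prot_pooled, files["corr_expr_prot_pooled"])
        _write_tsv(expr_prot, files["corr_expr_prot"])
        _write_tsv(prot_prot, files["corr_prot_prot"])
        _write_tsv(expr_meth_pooled, files["corr_expr_meth_pooled"])
        _write_tsv(expr_meth, files["corr_expr_meth"])
        _finish_stage("correlation", t0, files)

        current = "network"
        t0 = time.monotonic()
        gp_edges = network.aggregate_edges(
            pd.concat([expr_prot, gene_gene], ignore_index=True),
            config.min_cohorts_gene_protein,
        )
        pp_edges = network.aggregate_edges(
            prot_prot, config.min_cohorts_protein_protein
        )
        hubs = network.multi_degree_nodes(gp_edges, gene_ids)
        files = {
            "net_gp_tsv": out / "network_gene_protein.tsv",
            "net_gp_sif": out / "network_gene_protein.sif",
            "net_gp_graphml": out / "network_gene_protein.graphml",
            "net_pp_tsv": out / "network_protein_protein.tsv",
            "net_pp_sif": out / "network_protein_protein.sif",
            "net_hubs": out / "network_multi_gene_proteins.tsv",
        }
        network.export_network(gp_edges, "tsv", files["net_gp_tsv"])
        network.export_network(gp_edges, "sif", files["net_gp_sif"])
        network.export_network(gp_edges, "graphml", files["net_gp_graphml"])
        network.export_network(pp_edges, "tsv", files["net_pp_tsv"])
        network.export_network(pp_edges, "sif", files["net_pp_sif"])
        _write_tsv(hubs, files["net_hubs"])
        _finish_stage("network", t0, files)

        current = "clustering"
        t0 = time.monotonic()
        grid = correlation.correlation_grid(expr_prot_pooled)
        labels = correlation.cluster_profiles(
            grid, min(config.n_clusters, grid.shape[0])
        )
        files = {"clusters": out / "correlation_clusters.tsv"}
        _write_tsv(labels.rename_axis("feature_id").reset_index(),
                   files["clusters"])
        _finish_stage("clustering", t0, files)

        current = "stratification"
        t0 = time.monotonic()
        tumor_samples = list(
            bundle.metadata.loc[bundle.metadata["source"] == "tumor", "sample_id"]
        )
        groups = stratification.stratify(
            bundle.methylation, config.promoter_probe, config.body_probe,
            center=config.stratification_center, sample_ids=tumor_samples,
        )
        pairs = stratification.group_differential(
            bundle.expression, groups, config.stratification_gene
        )
        assign = groups.assignment.rename_axis("sample_id").reset_index()
        files = {
            "strat_assign": out / "stratification_assignments.tsv",
            "strat_pairs": out / "stratification_pairwise.tsv",
        }
        _write_tsv(assign, files["strat_assign"])
        _write_tsv(pairs, files["strat_pairs"])
        _finish_stage("stratification", t0, files)

        current = "survival"
        t0 = time.monotonic()
        if bundle.survival.empty:
            raise ValueError("survival stage enabled but no survival records")
        ann = survival.annotate_matrix(
            bundle.expression.subset_features(gene_ids), bundle.metadata,
            bundle.survival, p_max=config.p_max,
        )
        files = {
            "survival_annotations": out / "survival_annotations.tsv",
            "survival_volcano": out / "survival_volcano.tsv",
        }
        _write_tsv(ann, files["survival_annotations"])
        _write_tsv(survival.survival_volcano(ann), files["survival_volcano"])
        _finish_stage("survival", t0, files)
    except Exception as exc:
        manifest["stages"][current] = {"status": "FAILED", "error": str(exc)}
        manifest["outputs"] = {
            name: _sha256(p) for name, p in produced.items() if p.exists()
        }
        with (out / "manifest.json").open("w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["outputs"] = {name: _sha256(p) for name, p in produced.items()}
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
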