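"""Linked multi-cohort synthetic data with planted pan-cancer structure.

The generator emulates the data shapes of a pan-cancer compendium: ~33 tumor
cohorts (named with TCGA codes) with matched normals, a small gene network
where each gene carries several isoforms with biotype labels, 450K-style CG
probesets annotated to promoter / 1st-exon / body / 3'UTR regions, an RPPA
protein panel available only in subsets of cohorts, and OS/PFI survival
times whose hazard depends on expression.

Planted couplings use a Gaussian-copula construction: a latent standard
normal drives a gene's within-cohort expression; each probeset's latent is
correlated with it at the configured target and mapped through the logistic
function to a beta value in (0, 1), with region-specific location (promoter
probes low, gene-body probes high). Promoter couplings are negative
(methylation represses), body couplings positive (intragenic methylation
tracks transcription). Protein levels are sampled jointly with their target
gene the same way. Survival is exponential with log-hazard linear in the
standardized expression latent, censored at a fixed administrative horizon.

Everything is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data_model import (
    ANNOTATION_COLUMNS,
    EXPRESSION_FLOOR,
    OmicsMatrix,
    read_annotation,
    read_matrix,
    read_metadata,
    read_survival,
    write_annotation,
    write_matrix,
    write_metadata,
    write_survival,
)

logger = logging.getLogger("panmethnet")

#: the 33 TCGA tumor-type codes used as default cohort names
TCGA_COHORTS = (
    "ACC", "BLCA", "BRCA", "CESC", "CHOL", "COAD", "DLBC", "ESCA", "GBM",
    "HNSC", "KICH", "KIRC", "KIRP", "LAML", "LGG", "LIHC", "LUAD", "LUSC",
    "MESO", "OV", "PAAD", "PCPG", "PRAD", "READ", "SARC", "SKCM", "STAD",
    "TGCT", "THCA", "THYM", "UCEC", "UCS", "UVM",
)

#: RPPA-style protein panel (antibody target names)
DEFAULT_PROTEINS = (
    "ANNEXIN1", "SYK", "FIBRONECTIN", "ACVRL1", "CLAUDIN7", "ECADHERIN",
    "AKT", "CAVEOLIN1", "CHK2", "CIAP", "PAI1", "LCK",
)

#: logistic-scale beta location per gene region (promoter low, body high)
REGION_BETA_LOCATION = {
    "promoter": 0.15,
    "first_exon": 0.35,
    "body": 0.80,
    "utr3": 0.60,
}

BIOTYPE_OFFSET = {"coding": -0.5, "non_coding": -2.0, "retained_intron": -3.0}


@dataclass(frozen=True)
class GeneSpec:
    """One gene with its isoform inventory and probeset layout."""

    gene_id: str
    n_coding: int = 3
    n_non_coding: int = 2
    n_retained: int = 2
    probes_per_region: Mapping[str, int] = field(
        default_factory=lambda: {"promoter": 7, "first_exon": 2, "body": 9, "utr3": 2}
    )

    @property
    def isoform_biotypes(self) -> list[str]:
        return (
            ["coding"] * self.n_coding
            + ["non_coding"] * self.n_non_coding
            + ["retained_intron"] * self.n_retained
        )


@dataclass(frozen=True)
class EffectSpec:
    """Planted per-gene effects (optionally overridden per cohort).

    tumor_shift is in log2 expression units; couplings are target Pearson
    correlations between probeset beta (or protein level) and expression;
    survival_effect is the log-hazard ratio per standard deviation of
    expression (positive = high expression is deleterious).
    """

    tumor_shift: float = 1.0
    promoter_coupling: float = -0.5
    body_coupling: float = 0.3
    protein_coupling: float = 0.7
    survival_effect: float = 0.0


def default_genes() -> tuple[GeneSpec, ...]:
    return (
        GeneSpec("LCN2"),
        GeneSpec("SLC22A17"),
        GeneSpec("MMP9"),
    )


def default_effects() -> dict[str, EffectSpec]:
    # LCN2/MMP9 up in tumors, SLC22A17 down; LCN2 planted prognostic.
    return {
        "LCN2": EffectSpec(tumor_shift=1.0, survival_effect=1.0),
        "SLC22A17": EffectSpec(tumor_shift=-1.0),
        "MMP9": EffectSpec(tumor_shift=1.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_cohorts: int = 33
    n_tumor: int = 200
    n_normal: int = 50
    genes: tuple[GeneSpec, ...] = field(default_factory=default_genes)
    effects: Mapping[str, EffectSpec] = field(default_factory=default_effects)
    cohort_effects: Mapping[tuple[str, str], EffectSpec] = field(default_factory=dict)
    noise_sd: float = 0.5
    baseline_expression: float = 3.0
    cohort_sd: float = 0.3
    isoform_noise_sd: float = 0.3
    beta_latent_sd: float = 0.6
    proteins: tuple[str, ...] = DEFAULT_PROTEINS
    #: latent within-cohort correlation between gene pairs (unordered ids)
    gene_corr: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("LCN2", "MMP9"): 0.5}
    )
    baseline_survival_median_days: float = 1000.0
    censor_horizon_days: float = 2000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 tumor and 2 normal samples per cohort")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for gene in self.genes:
            if gene.gene_id not in self.effects:
                raise ValueError(f"no effects configured for gene {gene.gene_id!r}")
        for eff in list(self.effects.values()) + list(self.cohort_effects.values()):
            for name in ("promoter_coupling", "body_coupling", "protein_coupling"):
                r = getattr(eff, name)
                if not -1.0 < r < 1.0:
                    raise ValueError(f"infeasible correlation target {name}={r}")
        for pair, r in self.gene_corr.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"infeasible gene correlation {pair}={r}")
        self.gene_latent_cholesky()

    def gene_latent_cholesky(self) -> np.ndarray:
        """Cholesky factor of the latent gene–gene correlation matrix."""
        gene_ids = [g.gene_id for g in self.genes]
        corr = np.eye(len(gene_ids))
        for (a, b), r in self.gene_corr.items():
            if a in gene_ids and b in gene_ids:
                i, j = gene_ids.index(a), gene_ids.index(b)
                corr[i, j] = corr[j, i] = r
        try:
            return np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "gene_corr matrix is not positive definite"
            ) from exc

    def cohort_names(self) -> list[str]:
        names = list(TCGA_COHORTS[: self.n_cohorts])
        for i in range(len(names), self.n_cohorts):
            names.append(f"SYN{i + 1:02d}")
        return names

    def effect_for(self, gene_id: str, cohort: str) -> EffectSpec:
        return self.cohort_effects.get((gene_id, cohort), self.effects[gene_id])


@dataclass
class SyntheticBundle:
    expression: OmicsMatrix
    methylation: OmicsMatrix
    protein: OmicsMatrix
    annotation: pd.DataFrame
    metadata: pd.DataFrame
    survival: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# feature layout
# ---------------------------------------------------------------------------

def _expression_features(genes: Sequence[GeneSpec]) -> list[tuple[str, str, str, str]]:
    """(feature_id, gene, feature_class, biotype) for genes + isoforms."""
    rows = []
    for g in genes:
        rows.append((g.gene_id, g.gene_id, "gene", "not_applicable"))
        for i, biotype in enumerate(g.isoform_biotypes, start=1):
            rows.append((f"{g.gene_id}-iso{i}", g.gene_id, "isoform", biotype))
    return rows


def _probe_features(genes: Sequence[GeneSpec]) -> list[tuple[str, str, str]]:
    """(probe_id, gene, region) in promoter→3'UTR order per gene."""
    rows = []
    for g in genes:
        for region in ("promoter", "first_exon", "body", "utr3"):
            for i in range(g.probes_per_region.get(region, 0)):
                rows.append((f"cg-{g.gene_id}-{region}-{i + 1:02d}", g.gene_id, region))
    return rows


def build_annotation(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    pos = 1000
    for fid, gene, fclass, biotype in _expression_features(config.genes):
        rows.append((fid, gene, fclass, biotype, "not_applicable",
                     "chr1", str(pos), str(pos + 1000), "+"))
        pos += 2000
    for pid, gene, region in _probe_features(config.genes):
        rows.append((pid, gene, "probeset", "not_applicable", region,
                     "chr1", str(pos), str(pos + 2), "+"))
        pos += 100
    for prot in config.proteins:
        rows.append((f"RPPA-{prot}", prot, "protein", "not_applicable",
                     "not_applicable", "", "", "", ""))
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def protein_panel(config: SimulationConfig) -> pd.DataFrame:
    """Per-protein availability across the nine tumor groups and the gene
    each protein is coupled to (round-robin over the gene set).

    The first half of the panel is measured in every tumor group; the rest
    only in a third of the groups, so cohort panels genuinely differ.
    """
    gene_ids = [g.gene_id for g in config.genes]
    rows = []
    for i, prot in enumerate(config.proteins):
        target = gene_ids[i % len(gene_ids)]
        if i < len(config.proteins) // 2:
            groups = tuple(range(1, 10))
        else:
            groups = tuple(g for g in range(1, 10) if g % 3 == i % 3)
        rows.append((f"RPPA-{prot}", target, groups))
    return pd.DataFrame(rows, columns=["protein_id", "target_gene", "tumor_groups"])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _coupled_latent(rng: np.random.Generator, z: np.ndarray, rho: float) -> np.ndarray:
    """Latent standard normal with correlation rho against z."""
    eps = rng.standard_normal(z.shape[0])
    return rho * z + np.sqrt(1.0 - rho * rho) * eps


def generate(config: SimulationConfig) -> SyntheticBundle:
    """Generate a fully linked bundle; same seed → identical bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cohorts = config.cohort_names()
    annotation = build_annotation(config)
    panel = protein_panel(config)

    expr_features = [r[0] for r in _expression_features(config.genes)]
    probe_features = _probe_features(config.genes)
    probe_ids = [p[0] for p in probe_features]
    protein_ids = list(panel["protein_id"])

    sample_ids: list[str] = []
    meta_rows: list[tuple] = []
    expr_cols: list[np.ndarray] = []
    meth_cols: list[np.ndarray] = []
    prot_cols: list[np.ndarray] = []
    surv_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    lam0 = np.log(2.0) / config.baseline_survival_median_days

    for c_idx, cohort in enumerate(cohorts):
        tumor_group = (c_idx % 9) + 1
        baseline_offset = float(rng.normal(0.0, config.cohort_sd))
        n_t, n_n = config.n_tumor, config.n_normal
        n = n_t + n_n
        is_tumor = np.concatenate([np.ones(n_t, bool), np.zeros(n_n, bool)])
        ids = [f"{cohort}-T{i + 1:04d}" for i in range(n_t)] + [
            f"{cohort}-N{i + 1:04d}" for i in range(n_n)
        ]
        sample_ids.extend(ids)
        for sid, t in zip(ids, is_tumor):
            meta_rows.append((sid, cohort, "tumor" if t else "normal", tumor_group))

        expr_block = np.empty((len(expr_features), n))
        meth_block = np.empty((len(probe_ids), n))
        prot_block = np.full((len(protein_ids), n), np.nan)
        log_hazard = np.full(n_t, np.log(lam0))

        e_row = 0
        m_row = 0
        chol = config.gene_latent_cholesky()
        z_joint = chol @ rng.standard_normal((len(config.genes), n))
        gene_latents: dict[str, np.ndarray] = {}
        for g_idx, g in enumerate(config.genes):
            eff = config.effect_for(g.gene_id, cohort)
            z = z_joint[g_idx]
            gene_latents[g.gene_id] = z
            mean = config.baseline_expression + baseline_offset + np.where(
                is_tumor, eff.tumor_shift, 0.0
            )
            gene_value = mean + config.noise_sd * z
            gene_value = np.maximum(gene_value, EXPRESSION_FLOOR)
            expr_block[e_row] = gene_value
            e_row += 1
            for biotype in g.isoform_biotypes:
                iso = (
                    gene_value
                    + BIOTYPE_OFFSET[biotype]
                    + config.isoform_noise_sd * rng.standard_normal(n)
                )
                expr_block[e_row] = np.maximum(iso, EXPRESSION_FLOOR)
                e_row += 1

            for pid, pgene, region in probe_features:
                if pgene != g.gene_id:
                    continue
                rho = (
                    eff.promoter_coupling
                    if region in ("promoter", "first_exon")
                    else eff.body_coupling
                )
                # couple tumor probes to expression; normals stay uncoupled
                z_probe = np.where(
                    is_tumor,
                    _coupled_latent(rng, z, rho),
                    rng.standard_normal(n),
                )
                loc = logit(REGION_BETA_LOCATION[region])
                meth_block[m_row] = expit(loc + config.beta_latent_sd * z_probe)
                m_row += 1

            log_hazard = log_hazard + eff.survival_effect * z[:n_t]
            truth_rows.append(
                (g.gene_id, cohort, eff.tumor_shift, eff.promoter_coupling,
                 eff.body_coupling, eff.protein_coupling, eff.survival_effect,
                 config.baseline_expression + baseline_offset)
            )

        for p_idx, (pid, target, groups) in enumerate(
            panel.itertuples(index=False, name=None)
        ):
            if tumor_group not in groups:
                continue
            eff = config.effect_for(target, cohort)
            z_prot = _coupled_latent(rng, gene_latents[target], eff.protein_coupling)
            prot_block[p_idx, :n_t] = z_prot[:n_t]

        times = rng.exponential(1.0 / np.exp(log_hazard))
        event = (times <= config.censor_horizon_days).astype(int)
        obs = np.minimum(times, config.censor_horizon_days)
        for sid, t, e in zip(ids[:n_t], obs, event):
            surv_rows.append((sid, "OS", float(t), int(e)))
            surv_rows.append((sid, "PFI", float(t * 0.8), int(e)))

        expr_cols.append(expr_block)
        meth_cols.append(meth_block)
        prot_cols.append(prot_block)

    expression = OmicsMatrix(
        pd.DataFrame(np.hstack(expr_cols), index=expr_features, columns=sample_ids),
        "expression_log2fpkm",
    )
    methylation = OmicsMatrix(
        pd.DataFrame(np.hstack(meth_cols), index=probe_ids, columns=sample_ids),
        "methylation_beta",
    )
    protein = OmicsMatrix(
        pd.DataFrame(np.hstack(prot_cols), index=protein_ids, columns=sample_ids),
        "protein_rppa",
    )
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "cohort", "source", "tumor_group"]
    )
    metadata["tumor_group"] = metadata["tumor_group"].astype("Int64")
    survival = pd.DataFrame(
        surv_rows, columns=["sample_id", "endpoint", "time", "event"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "cohort", "tumor_shift", "promoter_coupling",
                 "body_coupling", "protein_coupling", "survival_effect",
                 "baseline_expression"],
    )
    return SyntheticBundle(
        expression, methylation, protein, annotation, metadata, survival,
        truth, config,
    )


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "expression": "expression.tsv",
    "methylation": "methylation.tsv",
    "protein": "protein.tsv",
    "annotation": "annotation.tsv",
    "metadata": "phenotype.tsv",
    "survival": "survival.tsv",
    "truth": "truth.tsv",
}


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.expression, directory / BUNDLE_FILES["expression"])
    write_matrix(bundle.methylation, directory / BUNDLE_FILES["methylation"])
    write_matrix(bundle.protein, directory / BUNDLE_FILES["protein"])
    write_annotation(bundle.annotation, directory / BUNDLE_FILES["annotation"])
    write_metadata(bundle.metadata, directory / BUNDLE_FILES["metadata"])
    write_survival(bundle.survival, directory / BUNDLE_FILES["survival"])
    bundle.truth.to_csv(directory / BUNDLE_FILES["truth"], sep="\t", index=False)


def read_bundle(directory: str | Path) -> SyntheticBundle:
    directory = Path(directory)
    return SyntheticBundle(
        expression=read_matrix(
            directory / BUNDLE_FILES["expression"], "expression_log2fpkm"
        ),
        methylation=read_matrix(
            directory / BUNDLE_FILES["methylation"], "methylation_beta"
        ),
        protein=read_matrix(directory / BUNDLE_FILES["protein"], "protein_rppa"),
        annotation=read_annotation(directory / BUNDLE_FILES["annotation"]),
        metadata=read_metadata(directory / BUNDLE_FILES["metadata"]),
        survival=read_survival(directory / BUNDLE_FILES["survival"]),
        truth=pd.read_csv(directory / BUNDLE_FILES["truth"], sep="\t"),
        config=None,
    )
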