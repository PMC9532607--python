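# panmethnet

Pan-cancer expression–methylation–protein–survival profiling of small gene
networks.

## The problem

How a small set of interacting genes — for instance the secreted
lipocalin LCN2, its receptor SLC22A17, and the matrix metalloproteinase
MMP9 — behaves across dozens of tumor types is usually asked of compendium
data: RNA-seq expression for tumor and normal samples, Illumina 450K DNA
methylation beta values at CG probesets annotated to promoter, 1st-exon,
gene-body and 3′UTR regions, RPPA protein panels measured in subsets of
cohorts, and overall-survival (OS) / progression-free-interval (PFI)
endpoints. `panmethnet` implements that analysis as one tested pipeline
for anyone who wants to run it on Xena-dialect matrices, or to study its
statistical behaviour on simulated cohorts with known ground truth.

## The method

For two sample groups with log2-scale means m₁ and m₂, the signed fold
change is

    FC = ±2^|m₂ − m₁|,   sign(FC) = sign(m₂ − m₁)

tested with a two-tailed unpaired (Welch) t-test; a feature is *up* when
FC ≥ 1.4 and p ≤ 0.05 and *down* when FC ≤ −1.4 and p ≤ 0.05. Cohort
medians are profiled against the normal-tissue interquartile range
(type-7 quantiles) with Tukey-fence outlier flags; methylation states use
median beta (≥ 0.6 methylated, ≤ 0.2 unmethylated, otherwise partial).
Pearson correlations (|r| ≥ 0.3; p ≤ 0.05, or p ≤ 0.01 for per-cohort
methylation–expression runs) are computed pooled and per cohort over
pairwise-complete samples; per-cohort significant pairs aggregate into
concordance networks (≥ 5 cohorts for gene–protein edges, ≥ 20 for
protein–protein; *total* concordance when every significant cohort agrees
in sign, *partial* otherwise). Tumor samples can be stratified into four
groups by promoter-probe and body-probe methylation around their central
values (group 1 = promoter-low/body-high … group 4 =
promoter-high/body-low) and compared pairwise. Features are annotated
against OS and PFI with a median split and the log-rank test, directions
called by restricted-mean survival. Details, assumptions and numerical
choices are in [docs/methods.md](docs/methods.md).

A synthetic multi-cohort generator (`panmethnet.synthetic_cohort`) plants
tumor shifts, promoter/body methylation couplings (Gaussian copula →
logistic betas), protein couplings, and expression-dependent hazards, and
records every planted value in a truth table, so all downstream stages are
testable offline.

## Worked example

```python
import dataclasses
from panmethnet import (SimulationConfig, generate, differential_table,
                        correlate_sets, stratify, group_medians,
                        annotate_feature)

cfg = dataclasses.replace(SimulationConfig(),
                          n_cohorts=4, n_tumor=100, n_normal=40, seed=11)
bundle = generate(cfg)

pooled = differential_table(bundle.expression, bundle.metadata, mode="pooled")
print(pooled.set_index("feature_id").loc["LCN2", ["fc", "p_value", "call"]])
# fc 1.85, p 1.6e-40, call "up"      (planted tumor shift +1 log2-unit)
# SLC22A17 on the same table: fc -2.07, call "down"  (planted shift -1)

corr = correlate_sets(
    bundle.expression.subset_features(["SLC22A17"]),
    bundle.methylation.subset_features(["cg-SLC22A17-promoter-01"]),
    bundle.metadata, mode="pooled", source="tumor")
print(corr.iloc[0][["r", "p_value", "n"]])
# r -0.401 over n = 400 tumor samples: the planted negative
# promoter-methylation -> expression coupling, attenuated by pooling

tumor = list(bundle.metadata.query("source == 'tumor'")["sample_id"])
groups = stratify(bundle.methylation, "cg-SLC22A17-promoter-01",
                  "cg-SLC22A17-body-01", sample_ids=tumor)
print(group_medians(bundle.expression, groups, "SLC22A17"))
# medians {1: 2.20, 2: 2.21, 3: 1.95, 4: 1.86}: the promoter-low groups
# (1, 2) sit clearly above the promoter-high groups (3, 4), with group 4
# lowest; groups 1 and 2 are near-tied here because the promoter coupling
# dominates the weaker body coupling at this sample size
```

The survival stage, on the same bundle's ACC cohort, calls LCN2
*unfavorable* for OS (log-rank χ² = 44.3, p = 2.9e-11) — recovering the
planted +1 log-hazard per expression SD.

## Command line

```bash
panmethnet simulate --seed 1 --out bundle/          # write a bundle
panmethnet run-all --config cfg.yaml --seed 1 --out results/
panmethnet diffexpr --expression bundle/expression.tsv \
    --phenotype bundle/phenotype.tsv --mode per_cohort --out diff.tsv
```

`run-all` executes every stage (differential, profiling, correlation,
networks, clustering, stratification, survival), writes TSV/SIF/GraphML
artifacts and a `manifest.json` with SHA-256 hashes of every output;
identical config and seed reproduce identical hashes.

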