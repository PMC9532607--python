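# Methods

## Scope

`panmethnet` is a pan-cancer multi-omic profiling pipeline for small gene
networks. It takes Xena-dialect matrices — RNA-seq expression on the
log2(fpkm + 0.001) scale, Illumina 450K methylation beta values, RPPA
protein levels — together with feature annotation, sample phenotype and
survival tables, and produces: tumor-vs-normal differential tables,
quartile/outlier expression profiles, methylation-state profiles, pooled
and per-cohort Pearson correlation tables, cross-cohort concordance
networks, a four-group promoter/body methylation stratification, and
log-rank survival annotations. A synthetic cohort generator with planted
effects makes every stage testable without any external download.

## Statistics

**Signed fold change.** For two groups of log2 expression values,
FC = ±2^|mean₂ − mean₁|, positive when group 2 has the larger mean and
negative otherwise, so |FC| ≥ 1 by construction; equal means give +1 (a tie
is a non-call regardless of sign). Differential significance is a
two-tailed unpaired t-test, Welch's unequal-variance form by default
(pooled-variance is available via `equal_var=True`). A feature is called up
when FC ≥ 1.4 and p ≤ 0.05, down when FC ≤ −1.4 and p ≤ 0.05. Calls use raw
p-values; a Benjamini–Hochberg column is emitted for reference only and
never feeds the calls.

**Quartile and outlier profiling.** A cohort's tumor median is compared
with the 1st/3rd quartiles of the matched normal distribution; quantiles
use linear interpolation (R type-7, the default of most statistical
environments), configurable. "Abnormal" cohorts are flagged with Tukey
fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) computed over the per-cohort medians —
the standard boxplot rule, chosen because no sharper definition of an
outlying cohort median exists for this analysis.

**Methylation states.** A probeset in a cohort is *methylated* when its
median beta ≥ 0.6, *unmethylated* when ≤ 0.2, *partial* in between. The
boundary at 0.2 is closed on the unmethylated side; 0.6 is closed on the
methylated side. (The partial band is sometimes printed elsewhere with its
bounds inverted; the only coherent reading, 0.2 < β < 0.6, is used here.)

**Correlation.** Sample Pearson r with a two-sided p from the t transform
t = r·√((n−2)/(1−r²)), n − 2 df, pairwise-complete observations (RPPA
panels differ by cohort, so listwise deletion would discard whole
cohorts). A pair is significant when |r| ≥ 0.3 and p ≤ 0.05 for
expression/protein runs, or p ≤ 0.01 for per-cohort methylation–expression
runs; both thresholds are plain config keys. The minimum n for a reported r
is 3, the mathematical floor. Correlation profiles are grouped with
agglomerative average-linkage clustering on Euclidean distances (seven
clusters in the default configuration); rows are sorted lexicographically
before linkage and labels renumbered by first appearance, so the output is
deterministic.

**Concordance networks.** Per-cohort significant correlations are
aggregated per unordered feature pair; an edge requires significance in at
least 5 cohorts (gene–protein) or 20 cohorts (protein–protein). Concordance
is *total_positive*/*total_negative* when every significant cohort agrees
in sign and *partial* otherwise; non-significant cohorts are ignored
entirely (r = 0 cannot be significant, so no tie rule is needed). mean_r is
averaged over the significant cohorts only, since the network summarizes
sign agreement, not magnitude. Exports are SIF (interaction type = the
concordance class), GraphML with all edge fields as attributes, and TSV.

**Four-group stratification.** Tumor samples are split at the central value
of one promoter probeset and one gene-body probeset, computed over all
included samples: group 1 = promoter low / body high, 2 = low/low,
3 = high/high, 4 = high/low. The default center is the median, with
`--center mean` available — both appear in the field's usage and neither is
silently preferred. Values exactly at the center go to "low"
(deterministic; configurable). All six group pairs are tested with the
signed FC and Welch's t, with group medians and IQ ranges reported. The
operation is generic over any (gene, promoter probe, body probe) triple.

**Survival.** Features are dichotomized at the median of the included
samples (ties to the low group — the grouping rule behind retrieved
survival scores is rarely stated, so this common default is used and
recorded in output metadata). Groups are compared with the standard
two-group log-rank chi-square (1 df, hypergeometric variance at each
distinct event time; delegated to lifelines, cross-checked in the test
suite against a hand-coded observed-minus-expected table). Direction is
called only at p ≤ 0.05: *favorable* when the high-expression group has the
larger restricted-mean survival over the observed horizon, *unfavorable*
otherwise. Restricted-mean comparison operationalizes the otherwise manual
"better curve" judgement. No Cox modeling, hazard ratios or covariate
adjustment.

## Synthetic cohort generator

The generator emulates the shapes of a TCGA/GTEx-style compendium, not its
empirical distributions (no batch effects, copy-number structure, or
realistic marginal distributions — conclusions from passing tests concern
the pipeline's statistics, not biology):

- **Cohorts.** 33 cohorts named with TCGA codes, each with 200 tumor and 50
  normal samples by default, and a per-cohort baseline expression offset
  ~N(0, 0.3 log2-units).
- **Expression.** Per gene, per sample: baseline 3.0 log2 units + cohort
  offset + tumor shift (for tumor samples) + noise_sd × z, with z a
  standard-normal latent and noise_sd = 0.5 log2-units; values are floored
  at log2(0.001). Default shifts: +1 (LCN2), −1 (SLC22A17), +1 (MMP9).
  Gene latents are jointly Gaussian with a configurable gene–gene
  correlation (default: LCN2–MMP9 at +0.5). Each gene carries 7 isoforms
  (3 coding, 2 non-coding, 2 retained-intron) at biotype-specific offsets
  (−0.5 / −2 / −3 log2-units) plus isoform noise (sd 0.3).
- **Methylation.** 20 probesets per gene (7 promoter, 2 first-exon, 9 body,
  2 3′UTR). For tumor samples each probe's latent is correlated with the
  gene latent at the planted coupling (promoter/first-exon: −0.5;
  body/3′UTR: +0.3 by default), then mapped through the logistic function
  with region-specific location (promoter ≈ 0.15, first exon ≈ 0.35,
  body ≈ 0.80, 3′UTR ≈ 0.60) and latent scale 0.6 — a Gaussian-copula
  construction, chosen because only correlation signs and rough magnitudes
  are specified by the analyses the generator serves. The logistic map
  attenuates the Pearson correlation slightly (measured ≈ −0.49 for a −0.5
  target at these settings), well inside the tolerances used downstream.
  Normal-sample probes are uncoupled. All betas are strictly inside (0, 1).
- **Protein.** A 12-antibody RPPA-style panel, each protein coupled to one
  gene (round-robin) at latent correlation 0.7; measured in tumor samples
  only. Half the panel is available in all nine tumor-groups; the rest only
  in a third of the groups, so per-cohort panels genuinely differ and
  pairwise-complete handling is exercised.
- **Survival.** Exponential event times with log-hazard linear in the
  standardized expression latent (default: +1 per SD for LCN2 only, so one
  planted prognostic gene exists), baseline median 1000 days,
  administrative censoring at 2000 days (~25–35% censored — typical
  follow-up truncation). PFI times are a scaled copy of OS times; the two
  endpoints share event indicators, which is sufficient for exercising the
  endpoint plumbing but carries no independent signal.
- **Determinism.** The entire bundle is a pure function of the seed.

## Pipeline

Stages run in method order (inputs → differential → profiling →
correlation → network → clustering → stratification → survival); each
writes TSV (plus SIF/GraphML for networks) and the run ends with a
manifest recording parameters and SHA-256 hashes of every artifact.
Identical config + seed reproduces identical hashes. A failing stage
aborts the run, names itself in the raised error, and leaves a FAILED
marker in the manifest. Stage timings in the manifest are informational
and excluded from the determinism contract (hashes cover artifact bytes
only).

## Numerical and design choices

- Matrix cells are written as the shortest round-tripping float
  representation; read→write round trips are byte-identical.
- Missing values are never coerced to numbers: "" and "NA" (any case) read
  as missing, "NA" is written, and all statistics drop missing values
  pairwise.
- The t statistic uses the group1 − group2 sign convention; group1 is the
  normal/reference group in differential tables, so negative t accompanies
  tumor up-regulation.
- `align_samples` orders the intersection by the first matrix and is
  idempotent.
- Cohorts lacking a tumor or normal group, features with <2 values per
  group, correlation pairs with n < 3, and single-group median splits are
  skipped with logged reasons, never errors — sparse features must not
  abort a pan-cancer sweep.
- Problem sizes in the test and acceptance workloads: 100 simulation seeds
  per recovery/calibration rate at 200 samples per cohort, and a 33-cohort
  bundle (200 tumor + 50 normal per cohort; 24 expression features, 60
  probesets, 12 proteins) for the end-to-end run — large enough for the
  planted-effect tolerances, small enough to run routinely on one CPU.

## Known limitations

- The generator's couplings act within cohorts through a single latent per
  gene; it cannot express probe-specific effect heterogeneity within a
  region, confounding between methylation and tumor purity, or isoform
  switching.
- PFI carries no signal independent of OS (see above).
- The concordance networks tally signs over cohorts where a pair is
  significant; a pair strongly but sub-threshold correlated everywhere
  produces no edge, which is faithful to the filtering design but
  discards information a meta-analytic approach would keep.
- No multiple-testing correction enters any call by design; the emitted BH
  column shows how much survives correction, and on real compendium-scale
  data the raw-p calls will include false positives at the nominal rate.
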