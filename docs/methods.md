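# Methods

`methylpso` re-implements, as a tested library, a differential DNA-methylation
analysis for case/control CpG-array cohorts of the kind used to study CD4+
T cells in skin psoriasis (PsO) and psoriatic arthritis (PsA): probe quality
filtering, normalization, batch adjustment, moderated-t differential calling
at position (DMP) and region (DMR) level, promoter over-representation
analysis, multivariate group separation, and healthy-control-standardized
gene-set methylation scores, including a variant filtered on correlation with
the PASI skin-activity index. A synthetic-cohort generator with planted
ground truth makes every stage verifiable without external data.

## Scales: β and M

Methylation is carried on two scales. The proportion scale β ∈ [0, 1] is used
for effect sizes, score models and visual summaries; the logit scale
M = log2(β/(1−β)) is variance-stabilized and is the scale for every linear
model (normalization, batch adjustment, moderated t). β is clipped to
[ε, 1−ε] with ε = 0.001 (configurable) before the logit so M stays finite;
`beta_to_m`/`m_to_beta` are mutual inverses on the open interval to 1e-12.

## Probe filtering

A probe is removed when flagged SNP-associated, non-CpG (CH) or
cross-reactive in the manifest, or when it fails detection. Detection
failures are carried as a per-probe-per-sample boolean mask; the default rule
drops a probe failing in *any* retained sample (the strictest minfi-style
reading — the fraction threshold is configurable via `max_fail_fraction`).
Removal categories may overlap; the report counts the union once, so
`n_retained = n_input − |union|` always holds and filtering is idempotent.

## Normalization

Quantile normalization maps every sample onto the across-sample mean of
sorted columns; ties receive the mean of the reference values over their
rank span. Probe-type-aware normalization (BMIQ) is out of scope because the
data model carries no type I/II chemistry; quantile normalization alone is
the implemented strategy. Note one consequence used in the tests: a purely
global additive batch shift is removed by quantile normalization itself,
while probe-specific batch effects are left for the batch model.

## Batch adjustment

`combat_adjust` is the parametric empirical-Bayes location/scale model:
per-probe standardization under a design that includes batch indicators and
protected biological covariates (group, age, sex), per-batch location (γ)
and scale (δ²) estimates shrunk toward a normal and an inverse-gamma prior
fit by the method of moments, iterative refinement of the shrunken effects,
then removal. A batch aliased with a protected covariate is an error; a
single batch passes through unchanged with a warning. The implementation is
checked against Bioconductor `sva::ComBat` on a fixture (agreement to ~1e-5;
residual difference is iteration tolerance). Which covariates deserve
adjustment is decided by an explicit screen (`screen_covariates`): the
association of each candidate with the top principal components
(correlation for numeric, ANOVA for categorical covariates), reported as a
minimum p-value and logged, with p < 0.05 as the conventional inclusion
line. The screen informs, the configuration decides.

## Moderated t, DMPs

Per probe, ordinary least squares of M on an intercept, the group indicator
and optional covariates. Variance shrinkage follows the standard
empirical-Bayes moderated-t model: the prior degrees of freedom d0 and prior
variance s0² are fit by the method of moments on log sample variances
(digamma/trigamma bias corrections, Newton inversion of the trigamma), and

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g),
    t_g = β̂_g / (s̃_g √v),  on d0 + d_g degrees of freedom.

When the log-variance moment is non-positive (no excess dispersion) d0 is
capped at +∞ and s0² is the geometric mean of the per-probe variances, which
reduces exactly to the common variance when all probes share one variance.
`prior_df=0` recovers the ordinary per-probe t; `prior_df=inf` the fully
pooled-variance t — both are tested against independent closed-form oracles
to 1e-8, and the default fit is tested against R `limma` to 1e-8.

A DMP is a probe with Benjamini–Hochberg q < 0.05 and |Δβ| > 0.1 (both
thresholds configurable). Δβ is the comparison-minus-reference difference of
group mean β computed on the *normalized* β matrix (back-converted from the
analysis M matrix), so the effect filter and the test see the same
post-normalization data. Direction: Δβ < 0 is hypomethylated in the
comparison group. Contrasts use a small group algebra — `"PsO+PsA"` is the
union — with the reference group listed first.

## DMRs

Region calling is a transparent greedy clustering, not a kernel smoother:
probes that individually pass the DMP thresholds are walked in genomic
order; consecutive qualifying probes on one chromosome with inter-probe gap
≤ 1000 bp (the typical window scale of kernel-based callers) form a
candidate, and candidates with ≥ 5 CpGs are emitted. The region p combines
member probes by signed Stouffer z (a min-q alternative is available by
flag) and is BH-adjusted across candidates. Output coordinates are 0-based
half-open (BED); manifest positions are 1-based (Illumina convention), with
conversion at the writer only.

## Scores

A score model standardizes each member DMP against healthy controls:
SV = (value − Mean_HC)/SD_HC with the moments computed exclusively on HC
samples, and total score = Σ SV per sample. SD is the population SD
(ddof = 0, switchable), so each SV has mean 0 and SD exactly 1 over HC and
the HC mean total score is 0 to machine precision — an identity the tests
assert. Scores are computed on β values (an M-scale variant is a flag).
Member probes are those DMPs whose gene annotation intersects the gene set;
zero-variance probes are excluded with a warning. Interferon membership
classification partitions differentially methylated genes into type I only
/ type II only / type I+II / non-IFN with one-decimal percentages.

The disease-activity variant first computes, per candidate probe, the
Pearson correlation between β and PASI across all samples with a recorded
PASI (pre- and post-treatment samples pooled when present; the sample set
is whatever the supplied sheet contains), keeps probes with |r| strictly
above 0.7, then fits the HC-standardized score and reports the correlation
of total scores with PASI.

## Multivariate

PCA is the SVD of column-centered sample-by-DMP β data (no unit-variance
scaling by default; both PCA and PLS-DA expose a `scale` flag). PLS-DA is
NIPALS PLS2 against the centered one-hot group encoding, handling the
three-class HC/PsO/PsA case natively; initialization is deterministic (the
response column with the largest variance, levels sorted for stability),
convergence tolerance 1e-10, at most 500 iterations, no RNG. The
correlation circle ranks probes by |Pearson r| against a component's score
vector, keeping |r| > 0.9 and truncating to the top 20 by default.

## Enrichment

Over-representation uses the hypergeometric upper tail, identical to the
one-sided Fisher exact test (asserted to 1e-12), with Bonferroni correction
across the sets actually tested (overlap ≥ 1). The universe is the set of
genes with at least one probe surviving preprocessing — the array-design
background — not the whole genome. Hypo- and hypermethylated promoter gene
lists are tested separately. Promoter context means region class TSS1500,
TSS200 or 5'UTR.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Baseline** per-probe methylation from a three-component Beta mixture
  (shape pairs (2,18), (10,10), (18,2); weights 0.55/0.10/0.35), the
  canonical bimodal array β distribution.
* **Noise and batch** on the M scale: i.i.d. normal noise (SD 0.8 by
  default), additive slide offsets and a multiplicative slide variance
  factor. Slides are assigned sex- and group-balanced so batches are not
  confounded with biology.
* **Planted DMPs**: promoter probes shifted by a signed Δβ (default 0.2,
  half hyper / half hypo) in patient groups, applied on the β scale *after*
  noise so the realized group-mean Δβ equals the configured effect.
  Hypermethylated probes start in a low-methylation baseline range
  (β ≈ 0.10–0.40) and hypomethylated ones high (0.60–0.90), so shifts stay
  inside the valid range. A PsA-specific subset is configurable (off by
  default). Planted probes are never QC-flagged — planted signal must
  survive filtering.
* **Disease activity**: patients carry a latent activity (half-normal
  + 0.2); PASI is a monotone noisy map of it onto the 0–40 clinical range.
  Promoter CpGs of "score genes" (drawn from hypomethylated planted genes
  into IFN_I / IFN_II / IL17_TNF sets, plus background genes) are coupled
  negatively to the latent on the M scale, with a shared per-sample noise
  component sized so the correlation between activity and mean score-gene β
  is ≈ −0.8 by default (`pasi_link_r`).
* **Cohort design** defaults to 8 HC / 12 PsO / 8 PsA with group-typical
  age distributions (≈29 / 41 / 55 years), deliberately reproducing an
  age–group confound of the kind real psoriatic-arthritis cohorts show;
  adjusting for age therefore costs real power, which is visible when
  covariates are included in a contrast.
* **Treatment series**: a configurable patient subset gains post-treatment
  samples in which planted and activity-coupled deviations shrink toward
  the HC mean by a recovery fraction (default 0.9) and PASI falls with the
  shrunken latent. The pre-treatment noise realization is reused, so
  recovery 0 reproduces the pre-treatment sample exactly and recovery 1
  leaves pure baseline-plus-noise.

All randomness derives from one master seed through per-artifact
`SeedSequence` streams (layout/manifest/cohort/treatment): a fixed seed gives
byte-identical outputs, and regenerating one artifact does not perturb the
others.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: probe type I/II chemistry and dye bias, spatial
chip artifacts, cell-composition heterogeneity, realistic linkage between
neighboring CpGs (probes are noise-independent, so DMR clustering is
exercised by fixtures rather than by the cohort generator), genomic
annotation realism, and any real effect-size distribution — planted effects
are homogeneous at the configured Δβ. Error-control results on synthetic
cohorts demonstrate correctness of the machinery under its own model, not
performance on EPIC data.

## Problem sizes and budgets

The simulation benchmarks use desk-scale cohorts chosen to keep the full
suite fast while leaving the per-probe statistics realistic: the
error-control benchmark uses 20 cohorts of 20,000 probes with 500 planted
DMPs at Δβ = 0.2 and noise SD 0.8 (8 HC vs 20 patients); direction and
multivariate checks use 2,000–5,000-probe cohorts over 10 seeds. On one CPU
the entire test suite runs in well under a minute of simulation time.

## Known limitations

* The DMR caller is a gap-clustering rule; it will not merge across a
  single non-qualifying CpG the way kernel smoothers can.
* The non-parametric ComBat variant is not implemented.
* Treatment-series contrasts are run unpaired (sex-corrected,
  quantile-only normalization); a paired model would gain power with
  matched pre/post samples.
* Gene identifiers are plain uppercased symbols; no Entrez/Ensembl mapping
  is performed.
* Enrichment reproduces a plain hypergeometric ORA; web services compute
  differently ranked statistics and their p-values are not comparable.
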