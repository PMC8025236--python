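# Methods

This note records the models implemented in `mirstem`, their assumptions,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter for
reproducibility.

## qPCR miRNA profiling (`mirstem.profiling`)

**Detection.** A measurement is detected iff its Ct is present and
strictly below the detection ceiling (default 28 cycles). Equality at the
ceiling is excluded: the two natural readings of the filtering rule
("> 28 excluded" vs "< 28 kept") leave equality undefined, and the strict
keep-below rule is the conservative resolution. Assays left with no
detected measurement in one of the compared groups are dropped entirely
rather than imputed — amplification failure in one group carries no usable
fold-change information and any imputation rule would be invented.

**Normalization.** ΔCt = Ct − median(housekeeping Cts of the same
sample); relative expression 2^(−ΔCt). The median over ≥1 housekeeping
controls is robust to a single failed control. A sample with no detected
housekeeping assay is a hard, named error: nothing downstream is
meaningful for it.

**Differential calling.** log₂FC(A vs B) = mean ΔCt(B) − mean ΔCt(A)
(lower ΔCt = higher expression, and a 1-cycle ΔΔCt is exactly a 2-fold
change). The test is a two-sided Welch *t* on replicate ΔCt values: the
replicate counts here are tiny and group variances need not be equal, so
Welch is the safe default; the test used is recorded in output metadata.
Calling requires strictly |log₂FC| > 0.5 **and** raw *p* < 0.05. No
multiple-testing correction is applied by default, matching the
raw-*p* convention of the assay; a Benjamini–Hochberg option exists
(`fdr=True`). Power at these settings is limited by arithmetic, not
implementation: with 3 replicates/group the *t* statistic has 4 df, and
at a planted 1-cycle shift with 0.25-cycle technical noise plus the
housekeeping-median noise the noncentral-*t* power is ≈ 0.86 (≈ 0.97 with
4 replicates). The test suite asserts agreement with this theory rather
than an unattainable recovery rate.

**Overlap testing.** Regulated sets from independent models are compared
by the one-sided (enrichment) Fisher exact test under the hypergeometric
null on the shared assay universe.

**Protocol arithmetic.** Composite dilution factors are the product of
serial dilution steps (e.g. 1:4 then 1:20 → 1:80 for the low-sample-input
protocol, 1:4 then 1:50 → 1:200 for the reference protocol). RIP loading
percentage = 100 × RIP copies / (input copies / input fraction), default
input fraction 5%.

## Cohort stratification (`mirstem.stratify`)

Features are z-scored (sample sd, ddof = 1); zero-variance features are
dropped with a warning. Clustering is agglomerative with Ward's
minimum-variance criterion on Euclidean distances (the classical
Lance–Williams form, i.e. squared Euclidean inside the objective), cut to
exactly *k* clusters. *k* is user-supplied — the published analyses fixed
2 or 3 by inspection — and a silhouette-based `suggest_k` is provided but
never auto-applied. Whether cohort matrices should be log-transformed
before standardization is dataset-dependent and unstated in the sources
these analyses emulate, so `log2(x+1)` preprocessing is a flag, default
on.

Cluster × annotation association uses the uncorrected Pearson χ² with
df = (r−1)(c−1). Per-cell calls use standardized (adjusted) residuals
r_ij = (O−E)/√(E(1−row margin)(1−col margin)) flagged at |r| > 1.96; the
underlying post-hoc method in the emulated figures is unnamed, and
adjusted residuals are the standard choice.

## Target de-repression (`mirstem.derepression`)

**Global shift.** median(log₂FC | predicted targets) − median(log₂FC |
others), SEM by seeded bootstrap (default 1,000 resamples), significance
by two-sided Mann–Whitney. The median is used throughout because miRNA
loss-of-function effects are small relative to the background spread.

**Ranking and binning.** Genes are sorted by log₂FC descending — bin 1 is
the most up-regulated, which is where de-repressed targets concentrate
after knockdown — with ties broken lexicographically by gene id so the
partition is deterministic (fold-change ties at 0 are common). Bin sizes
are ⌊N/B⌋ with the remainder distributed one each to the lowest-index
bins; the partition is exact and total.

**Enrichment.** Per bin, expected = bin size × (targets/N); the effect is
log₂((obs+ε)/(exp+ε)) with ε = 0.5 applied only when obs = 0, keeping the
log finite without biasing non-empty bins. The Pearson χ² statistic on
the 2×2 (in-bin vs rest) × (target vs other) table is always reported;
the *p*-value switches to Fisher's exact test when any expected cell is
below 5 (the usual validity bound for the χ² approximation).

**Selection and consensus.** `fixed_paper` selects bins 1–4 (top) and
7–10 (bottom) of a 10-bin table; `adaptive` takes the maximal prefix of
significantly enriched bins and the maximal suffix of significantly
depleted ones. Consensus sets are the strict intersection across **all**
experiments (majority voting is available but off by default: strictness
is what buys specificity at these weak effect sizes). Direct targets are
the consensus up-set ∩ predicted targets, with a df = 1 Pearson χ² of
target status × consensus membership over the full annotated universe.
The analogous published statistic for this construction could not be
reproduced from its printed marginals under any obvious 2×2, so the
implementation documents its table and treats no printed value as ground
truth.

## Limiting dilution (`mirstem.limiting_dilution`)

Single-hit model: each injected cell initiates independently, so
P(take | dose d) = 1 − exp(−f·d). The MLE of f comes from a binomial GLM
with cloglog link, intercept log f, and log(dose) as a fixed-unit offset
(statsmodels). The default 95% CI is Wald on log f back-transformed
(matching ELDA-style reporting); a profile-likelihood interval is
available (`ci_method="profile"`). Saturated assays — no takes anywhere,
or takes everywhere — have no interior MLE and return one-sided bounds
with a `boundary_flag` instead of failing, because transplantation tables
saturate routinely: with zero takes the 95% upper bound solves
P(no takes | f) = 0.05 in closed form; with all takes the lower bound
solves P(all take | f) = 0.05 numerically.

Group comparison is a likelihood-ratio test (shared f vs group-specific
f, df = 1), preferred over Wald for its behavior at small counts.
Adequacy of the single-hit assumption is a Wald test of slope = 1 in the
free-slope cloglog regression on log(dose); it needs ≥ 2 distinct doses
to be identified. Frequencies are reported both as f and as
"1 in round(1/f)".

Phenotype formulas: sphere-forming efficiency = 100 × spheres/cells
plated; caliper tumor volume = L·W²/2 with L the longest diameter
(swapped inputs are corrected with a warning).

## Dose–response (`mirstem.dose_response`)

4PL: y = bottom + (top−bottom)/(1+(x/IC50)^hill), decreasing for
hill > 0 and equal to (top+bottom)/2 exactly at x = IC50. The fit is
unweighted least squares (the loss used by common commercial 4PL
implementations is undocumented; unweighted is recorded in metadata) on
(top, bottom, log IC50, log hill) — the log parameterization conditions
the problem and enforces positivity. Initialization is deterministic:
top = max y, bottom = min y, IC50 = geometric mid-concentration,
hill = 1. Bounds: IC50 ∈ [min conc/100, max conc×100], hill ∈ (0.1, 10].
Ascending (activation-shaped) data are auto-detected by the sign of the
log-concentration regression slope and handled by reflecting the
response, so the reported hill stays positive. Flat data are returned as
a flagged degenerate fit (IC50 unidentifiable), and fewer than 4 distinct
concentrations is an error. Standard errors come from the Gauss–Newton
covariance with a delta-method back-transform for IC50 and hill.

Relative potency is a shared-shape parallel fit (common top, bottom,
hill; group-specific log-IC50), ratio = IC50_ref/IC50_test with a Wald CI
on the log-IC50 shift — the parallel construction is more stable than a
ratio of independent IC50s, though the independent ratio is also
reported. Shape heterogeneity is screened by an F-test of the constrained
fit against the two free fits; *p* < 0.01 attaches a warning but the
ratio is still reported.

## Synthetic data (`mirstem.synthetic`)

The generators emulate the summary-table level the analysis consumes; no
sequencing reads, FACS scatter or image data are simulated. Noise
families are the minimal ones the downstream statistics assume: Normal
for Ct values, log₂ fold-changes and viability; Bernoulli/binomial for
limiting-dilution takes.

Defaults are the study-scale conditions: 11,000 expressed genes, 945
predicted targets, planted target shift +0.10 log₂ over a
Normal(0, 0.5) background, 4 independent profiles; housekeeping Ct
20 cycles, technical sd 0.25 cycles, detection ceiling 28 cycles. The
background sd of 0.5 log₂ units is a free default (no dispersion is
published for per-gene fold changes at this scale) and remains
configurable. Planted targets receive context scores uniform in
[−0.60, −0.15) — below the prediction threshold; the magnitude is never
used downstream. Cohort matrices assign features round-robin to driver
clusters with means separated by a configurable number of standardized
units and an annotation that matches the true cluster with configurable
probability.

**Seeding.** A single global seed expands into fixed per-generator
substreams via `SeedSequence(entropy=seed, spawn_key=(offset,))`, so
adding a generator never perturbs existing streams and identical
(config, seed) pairs are bit-identical. The spawn-key construction
matters: seeding with a `[seed, offset]` entropy list leaves measurable
correlation across sequential seeds (the ensemble variance of
hypergeometric bin counts inflates by ~20%), which the calibration tests
detect.

**What passing tests show.** The generators plant exactly the structure
the estimators assume (Normal backgrounds, independent profiles,
single-hit takes, shared 4PL shapes). Recovery on synthetic data
therefore validates the inference machinery — calibration, power at the
planted effect sizes, invariances — but not robustness to the ways real
data deviate: heavy-tailed fold-change distributions, correlated
experiments sharing batch structure, qPCR efficiency differences between
assays, extra-binomial variation in transplantation takes, or
non-sigmoidal viability artifacts.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo sizes were chosen to put sampling error well inside each
asserted tolerance: 50 seeds at full 11,000-gene scale for shift
recovery; 500 datasets for the null-calibration checks (with the
bin-enrichment calibration referred to the exact hypergeometric null,
since the 2×2 statistic is discrete and a continuous-uniform reference
misstates its size); 2,000 simulated assays for limiting-dilution CI
coverage; 200 noisy curves for 4PL parameter recovery; 50 replicated
experiments per condition for the fold-sensitivity medians. The
acceptance script's dose–response conditions plant the IC50 triple
(3,560, 511, 71 nM) with a shared hill of 1 and viability noise sd 0.05
over 10 log-spaced concentrations × 3 replicates.

## Known limitations

* The limiting-dilution Wald CI undercovers slightly for very small
  assays (few animals per dose); the profile-likelihood option is
  preferable there.
* The 4PL fitter assumes a single sigmoid; biphasic responses are
  averaged over, not detected (the shape-heterogeneity F-test flags only
  between-group disagreement).
* The ranked-bin consensus is a strict intersection: one failed
  experiment empties the consensus rather than degrading it (use the
  majority option deliberately if that is the failure mode).
* Cohort stratification consumes subtype labels; it does not compute
  molecular subtypes, survival models or network analyses.
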