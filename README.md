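# mirstem

Quantitative analysis of miRNA-driven stem-cell phenotypes in mammary
tissue and breast cancer: qPCR miRNA differential calling, tumor-cohort
stratification by miRNA signatures, ranked-bin detection of de-repressed
direct miRNA targets, single-hit limiting-dilution estimation of
tumor-initiating-cell (TIC) frequency, and four-parameter logistic (4PL)
dose–response potency analysis — with a synthetic-data generator that
plants known ground truth for every stage.

## Who this is for

Labs quantifying cancer-stem-cell (CSC) biology face a recurring set of
statistical tasks that sit between bench data and publication figures:

* **TaqMan qPCR miRNA profiling** of sorted stem vs. progenitor
  populations (e.g. PKH26-retaining cells): detection filtering at a Ct
  ceiling, ΔCt normalization over the median of housekeeping controls,
  and differential calling at |log₂FC| > 0.5, *p* < 0.05.
* **Cohort stratification**: Ward hierarchical clustering of standardized
  tumor expression matrices (TCGA/METABRIC-style) and χ² contingency
  analysis of cluster × subtype/receptor-status tables with per-cell
  standardized residuals.
* **Direct-target discovery after miRNA loss of function.** miRNA
  knockdown shifts its targets up only slightly (≈ +0.1 log₂), below any
  conventional fold-change cutoff. The ranked-bin strategy implemented
  here sorts each expression profile from most up- to most down-regulated,
  splits it into 10 equal-count bins (≈ N/10 genes/bin), scores per-bin
  enrichment of predicted targets as log₂(observed/expected) with a
  contingency *p*, intersects the enriched top bins across independent
  experiments, and finally intersects that consensus up-set with the
  predicted-target list to call high-confidence direct targets.
* **Limiting-dilution transplantation.** Under the single-hit model,
  P(tumor | dose *d*) = 1 − exp(−*f·d*) where *f* is the TIC frequency.
  Taking cloglog of both sides gives log *f* + log *d*, so *f* is the
  intercept of a binomial GLM with complementary log-log link and
  log(dose) offset — the ELDA construction. Groups are compared by a
  likelihood-ratio test; the single-hit assumption is checked by testing
  slope = 1 in a free-slope fit.
* **Drug sensitivity.** 4PL curves
  y = bottom + (top − bottom)/(1 + (x/IC50)^hill), with relative potency
  between conditions from a shared-shape parallel fit (common top, bottom,
  hill; group-specific log-IC50).

## Worked example

Simulate the study-scale de-repression design (11,000 genes, 945
predicted targets carrying a +0.10 log₂ shift over a 0.5-sd background,
four independent profiles), then run the ranked-bin inference:

```python
from mirstem.synthetic import SyntheticConfig, simulate_derepression_profiles
from mirstem import derepression as dr

cfg = SyntheticConfig(seed=1)
profiles, annot, truth = simulate_derepression_profiles(cfg)

shift = dr.global_shift(profiles["exp1"], annot, seed=1)
bins = {e: dr.rank_and_bin(p) for e, p in profiles.items()}
sel = {e: dr.select_bins(dr.bin_enrichment(b, annot)) for e, b in bins.items()}
cons = dr.consensus_sets(bins, sel)
direct = dr.direct_targets(cons, annot)
```

which prints (via the result objects):

```
median shift = +0.087 +/- 0.015 (Wilcoxon p = 8.72e-09)
consensus up: 286  down: 288
direct targets: 39 (chi2 = 9.52, p = 2.03e-03)
```

The estimated target shift matches the planted +0.10 within its bootstrap
SEM; the strict four-experiment intersection leaves a few hundred
consensus genes, and the 39 called direct targets are significantly
enriched over the random-overlap expectation (χ², df = 1).

Limiting-dilution analysis is a statsmodels-style model/results pair:

```python
from mirstem.synthetic import simulate_ld_assay
from mirstem.limiting_dilution import LimitingDilutionModel, compare_frequencies

ctrl = simulate_ld_assay(1/200, [100, 500, 2500], 10, seed=2, group="CTRL")
kd   = simulate_ld_assay(1/1000, [100, 500, 2500], 10, seed=3, group="KD")
print(LimitingDilutionModel.from_dataframe(ctrl).fit().summary())
print(compare_frequencies(ctrl, kd).summary())
```

```
Single-hit limiting dilution estimate (CTRL)
  frequency      : 0.003683 per cell (1 in 272)
  95% CI         : [0.001951, 0.00695] (wald)
  log-likelihood : -8.6976
  boundary       : none
Frequency ratio 5.27 (LRT = 13.009, df = 1, p = 0.00031)
```

The planted fivefold frequency difference (1/200 vs 1/1000) is recovered
as 5.27× with *p* < 0.001.

## Command line

Every stage is also a subcommand of the `mirstem` executable:

```bash
mirstem simulate derepression --seed 1 --out sim/
mirstem derepress --profiles sim/profile_exp1.tsv --profiles sim/profile_exp2.tsv \
    --targets sim/targets.tsv --out results/
mirstem ldassay --table takes.tsv --compare CTRL KD
mirstem dose --table viability.tsv --reference CTRL
mirstem run --config pipeline.yaml        # full pipeline from a YAML config
```

Exit codes: 0 success, 2 validation failure, 3 stage failure. All tables
are plain TSV (CSV auto-detected by extension); logs go to stderr and
machine-readable summaries to `summary.json`.

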