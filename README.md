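# pgxsig

Multi-SNP pharmacogenetic signature discovery for trial-style cohorts,
implemented as a four-stage pipeline:

1. **Screening** (`pgxsig.screen`) — per-SNP logistic association on extreme
   response phenotypes, a staged candidate funnel across two discovery
   cohorts with per-cohort p cutoffs, LD de-duplication, and a placebo
   filter that removes prognostic (as opposed to predictive) markers.
2. **Modeling** (`pgxsig.bma`) — spike-and-slab Bayesian model averaging for
   logistic regression via an exact Polya-Gamma data-augmentation Gibbs
   sampler (no external MCMC dependency; the kernel is numba-compiled).
   SNPs are selected by posterior inclusion probability and zero-excluding
   credible intervals in fits with and without baseline covariates, then
   refitted by plain maximum likelihood into the final signature model.
3. **Evaluation** (`pgxsig.evaluate`) — predicted probabilities, ROC/AUC,
   the "top-left" classification threshold, signature-positive/negative
   group annualized-relapse-rate comparison, a bootstrap test for AUC
   differences between cohorts, and leave-one-out subset models.
4. **Characterization** (`pgxsig.characterize`) — quintile binning of
   predicted probabilities with per-bin clinical summaries (response rates,
   MRI measures, ARR reduction, time to first relapse, NEDA3/NEDA4).

Supporting modules: `pgxsig.simulate` (synthetic cohorts with
Hardy-Weinberg genotypes, logistic outcomes, relapse/lesion/EDSS processes
and a null placebo arm), `pgxsig.phenotypes` (ARR endpoints, extreme
response classes, the relapse-free definition with its 47-day efficacy
window, confirmed EDSS progression, NEDA composites), `pgxsig.qc`
(call-rate filtering, exact Hardy-Weinberg test, inheritance-model
encoding/selection, LD), and `pgxsig.io` (VCF, PLINK text, clinical CSV,
YAML configs, TSV artifacts).

## Command line

```sh
pgxsig simulate --n-subjects 400 --seed 1 --out-prefix out/cohort
pgxsig label out/cohort.clinical.csv --out out/labels.csv
pgxsig qc out/cohort.vcf --out out/qc.tsv
pgxsig fit out/cohort.vcf out/cohort.clinical.csv --out out/model.json
pgxsig evaluate out/model.json out/cohort.vcf out/cohort.clinical.csv --out out/perf.tsv
pgxsig characterize out/model.json out/cohort.vcf out/cohort.clinical.csv --out out/bins.tsv
pgxsig run-all --outdir out/run            # full pipeline, built-in config
pgxsig run-all --config cfg.yaml --outdir out/run
```

`run-all` executes all stages in order on simulated cohorts (or on files
named in the config), writing per-stage TSV/JSON artifacts plus a manifest;
identical config and seed reproduce byte-identical artifacts.

## Notes

- Genotypes are coded as minor-allele counts; `dominant` coding flags
  carriers of two minor-allele copies.
- Credible intervals from the spike-and-slab posterior are conditional on
  inclusion (equal-tailed quantiles over draws where the term is in the
  model); excluded-state zeros are never mixed into a CI.
- The classification threshold is estimated once on discovery data and
  frozen for independent cohorts.
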