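# methdrift

Quantitative analysis of promoter DNA methylation in paired primary
colorectal carcinomas and their liver metastases.

When a colorectal tumor metastasizes to the liver, does it acquire *new*
epigenetic silencing events (clonal selection of specific genes), or does its
methylation landscape merely drift — the same loci, methylated in a larger
fraction of cells? The two explanations leave different fingerprints in
bisulfite-pyrosequencing data: a change in **methylation frequency** (a locus
crossing the methylated/unmethylated boundary between tumor sites) versus a
change in **methylation density** (the percent of methylated CpG sites at an
already-methylated locus rising, e.g. with increased clonal purity or
continued accumulation over cell divisions). `methdrift` implements the full
analysis pipeline for distinguishing them, for epigenomics researchers
working with candidate-gene pyrosequencing panels and two-channel
methylated-CpG-island-amplification microarrays (MCAM).

## What it computes

* **Density calls** — a locus is methylated when its methylation density
  (mean percent methylation over assayed CpG sites) is strictly above a
  cutoff, 15% by default.
* **CIMP classification** — a tumor is CpG-island-methylator-phenotype
  positive when ≥ 2 of the 6 panel markers (MINT1, MINT2, MINT31, p16, p14,
  MLH1) are methylated.
* **Paired drift calls** — for each (patient, locus) measurement pair with
  both the primary and metastasis density observed, a concordance label
  (binarize both sides) and an independent drift label: a meaningful
  increase/decrease requires fold change > 2 *and* at least one density
  > 15%. Per-gene z-scores, z = (x − μ_g)/σ_g with the sample SD, support
  panel-level scoring.
* **Group statistics** — two-sided Mann-Whitney U tests (exact enumeration
  for small tie-free groups, tie-corrected normal approximation otherwise),
  normal-approximation confidence intervals μ ± z·s/√n, and χ²/Fisher
  contingency tests with the expected-cell < 5 rule.
* **MCAM processing** — MA coordinates A = ½·log₂(Cy5·Cy3),
  M = log₂(Cy5/Cy3) per probe, within-array lowess normalization of M on A,
  gene-level means, hypermethylation calls at normalized log₂ ratio > 1
  (~2-fold), and 2–3-sample Venn overlap summaries.
* **Synthetic cohorts** — a generator with separately controllable per-locus
  methylation frequency, beta-mixture densities, time-dependent
  frequency-gain/loss and density-inflation drift, tumor purity, and
  dye-biased two-channel array signals, emitting ground truth for recovery
  tests.

## Worked example

```python
import methdrift as md
from methdrift.datasets import load_example_cohort

cohort = load_example_cohort()   # synthetic study-shaped cohort
enum = md.enumerate_measurement_pairs(cohort.matrix, cohort.meta)
calls = md.classify_pairs(enum.records)
summary = md.summarize_pairs(calls)
print(f"measurement pairs: {summary.n_pairs_total} "
      f"(+{enum.n_excluded_missing} excluded for missing values)")
print(f"concordant: {summary.n_concordant} ({summary.percentages['concordant']})")
print(f"increase:   {summary.n_increase} ({summary.percentages['increase']})")

call = md.classify_pair(13.4, 27.4)
print(f"pair (13.4, 27.4): fold={call.fold:.2f} drift={call.drift} "
      f"concordance={call.concordance}")
```

prints

```
measurement pairs: 205 (+3 excluded for missing values)
concordant: 200 (98%)
increase:   7 (3%)
pair (13.4, 27.4): fold=2.04 drift=increase concordance=discordant
```

The example cohort has 16 matched primary/metastasis pairs over 13 loci with
three missing values, hence 205 complete measurement pairs. A primary at
13.4% and a metastasis at 27.4% is a 2.04-fold increase with one side above
15%, so it counts both as a drift *increase* and as binarization-*discordant*
— the two labels answer different questions and are reported separately.

The scoring and normalization steps are also exposed as scikit-learn-style
estimators (`MethylationBinarizer`, `GeneZScorer`, `CIMPClassifier`,
`PairDriftClassifier`, `TwoChannelLowessNormalizer`) that compose with
sklearn pipelines, and as a CLI:

```sh
methdrift simulate --seed 7 --out-prefix cohort
methdrift paired cohort_methylation.tsv cohort_metadata.tsv
methdrift report --outdir run --seed 7
```

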