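# cfgi — genomic instability scoring of low-pass cell-free DNA WGS

Tumors shed DNA into plasma, and the copy-number imbalances of that
circulating tumor DNA leave a dosage footprint in shallow whole-genome
sequencing of cell-free DNA.  `cfgi` implements a complete analysis stack
for turning ~3 million aligned reads per plasma sample into a scalar
**instability score (I-score)** and downstream cohort analyses, aimed at
researchers studying prognosis in pancreatic ductal adenocarcinoma and
similar settings where a single blood draw must stand in for a tissue
biopsy.

## The model

The genome (hg19 autosomes chr1–chr22) is tiled into 2897 bins of 1 Mb;
bins in low-mappability regions are excluded.  Reads with mapping quality
< 60 and PCR duplicates are discarded, and each sample's per-bin relative
read frequency RF_bin is LOESS-corrected for GC bias.  Against a panel of
healthy controls providing the per-bin mean M_bin and standard deviation
SD_bin of corrected frequencies,

    Z_bin = (RF_bin − M_bin) / SD_bin

and, after LOESS smoothing of adjacent bins along each chromosome,

    I-score = ln Σ_bin |smoothed Z_bin| .

Samples are dichotomized into low/high instability at a cohort-derived
cutoff (the Contal–O'Quigley maximal standardized log-rank statistic;
7.3 is the shipped default).  On top of the per-sample score the package
provides:

* **Segmentation and concordance** — recursive binary change-point
  segmentation of Z-profiles and Pearson correlation between matched
  plasma and tissue profiles at segment resolution;
* **Recurrent regions** — a simplified amplitude-weighted recurrence
  score (G-score) per bin with a cyclic-shift permutation null and
  Benjamini–Hochberg FDR (regions at q < 0.25), plus interval overlap
  with a bundled table of curated pancreatic-cancer genes;
* **Gene sum score (GSS)** — direction-aware 0/1 gene scoring at |Z| > 2,
  log-rank ranking, five-fold cross-validated selection of the best
  (top-N genes, integer cutoff) pair, and scoring of external
  GISTIC-style thresholded call matrices;
* **Survival layer** — association tests, Kaplan–Meier/log-rank, Cox
  proportional-hazards models with backward elimination (Efron ties),
  Harrell's C-index, and the optimal-cutpoint scan;
* **Synthetic data** — negative-binomial bin counts with GC bias, planted
  copy-number segments diluted by tumor fraction (bin multiplier
  1 + f·(c−2)/2), and clinical cohorts with exact marginal hazard ratios
  for both progression-free and overall survival.

## Worked example

The survival layer on a simulated 315-patient cohort (239 low / 76 high
instability, true progression-free-survival hazard ratio 2.69, ~40%
censoring):

```python
from cfgi.simulate import simulate_cohort
from cfgi.survival import cox_fit, contal_oquigley

co = simulate_cohort(seed=0)
co["high"] = (co.group == "high").astype(int)
print(cox_fit(co, "pfs_time", "pfs_event", ["high"]))
print(contal_oquigley(co.i_score, co.os_time, co.os_event))
```

prints

```
covariate    hr  ci_low  ci_high   p
     high 2.608   1.915    3.551 0.0
CutpointResult(cutpoint=7.43, max_statistic=2.72, candidates_evaluated=248)
```

— the Cox model recovers the planted hazard ratio (2.61 vs a generative
2.69, within sampling error of a single replicate), and the maximal
log-rank scan places the optimal I-score cutpoint near the generative
group boundary of 7.3.

## The analysis

The numbered scripts under `analysis/` run the full study on a
scaled-down simulated genome (6 chromosomes × 40 Mb, 240 bins), writing
bulky intermediates under `scratch/sim/` and summary tables under
`results/`:

1. `01_simulate_study.py` — 38 controls, a 100-patient plasma cohort
   with shared driver segments in the high-burden group, 10 matched
   plasma/tissue pairs, and a 315-patient clinical table;
2. `02_instability_scores.py` — reference panel, per-patient I-scores,
   cohort-derived cutoff;
3. `03_segmentation_concordance.py` — tissue-baseline segmentation and
   plasma concordance (median segment-resolution r² ≈ 0.87 at tumor
   fraction 0.3);
4. `04_recurrent_regions.py` — cohort recurrence calling (the three
   planted driver regions are the top-scoring calls) and the hg19
   curated-gene census (7 oncogenes and 5 poor-prognosis genes in
   amplification regions; 4 tumor suppressors and 1 oncogene in the
   deletion region);
5. `05_gene_sum_score.py` — gene-level scoring and cross-validated GSS
   selection (no null gene enters the union set);
6. `06_survival_analysis.py` — association tests, cutpoint, Cox models
   and C-index on the clinical table.

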