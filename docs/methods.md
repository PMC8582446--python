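# Methods

This note records the models, defaults and design decisions behind
`cfgi`, in the spirit of the methods documentation of statistical
genetics packages: enough detail to re-derive every number the package
produces, and an explicit account of what the synthetic data do and do
not establish.

## Bin backbone

The coordinate system is a tiling of the autosomes (chr1–chr22) into
fixed-size bins, 1 Mb by default.  Each chromosome is tiled
independently with a possibly short final bin, so the bin count is
Σ ceil(L/10⁶); for the bundled hg19 lengths this is 2897.  Sex
chromosomes are excluded: tiling them would overshoot that count, and a
mixed-sex control panel would make chrX/chrY dosage a confounder rather
than a signal.  Coordinates are 1-based closed internally; BED I/O
converts from 0-based half-open.

Bins overlapping an exclusion list by ≥ 1 bp are flagged unusable (the
conservative reading, since no overlap fraction is canonical).  The
identity of real low-mappability bins depends on a mappability track we
do not regenerate; tests emulate an exclusion list of the realistic size
(163 bins) to exercise the bookkeeping.  Reads are assigned to the bin
containing their leftmost aligned position — for sparse single-end
short-read counting the difference from midpoint assignment is under one
bin.  Reads below mapping quality 60, duplicate-flagged reads, and
secondary/supplementary records are never counted.

GC content per bin comes from a reference FASTA when one is available
(`gc_from_fasta`); all simulated genomes carry a synthetic GC track
(`synthetic_gc`, a slow sinusoid plus jitter clipped to [0.30, 0.60]) —
a labelled stand-in, not measured hg19 GC.

## GC correction and the reference panel

GC bias is removed per sample by degree-1 LOESS of relative frequency
against GC (statsmodels `lowess`), span 0.75, with 2 robustness
iterations so that strongly aberrant (copy-number) bins do not drag the
trend.  The correction is additive — rf − trend(gc) + mean(rf) — then
clipped at zero and renormalized to sum 1, which keeps the profile a
relative-frequency vector.  Correcting frequencies rather than raw
counts, and the additive form, are package choices; both are exposed
(span, iterations) and the flat-bias identity is tested.

LOESS is not a projection, so a second correction pass is not exactly a
no-op.  Measured tolerances, asserted in the tests: under a linear GC
trend the second pass moves no bin by more than 1% of the mean relative
frequency; under the simulator's strongly curved default bias (a
Gaussian bump that a span-0.75 local-linear fit under-resolves) the
bound is 5%.  An absolute per-bin bound of ~10⁻⁶ is attainable only in
the linear regime at full genome scale.

The panel stores, per usable bin, the mean and sample standard deviation
(n−1 denominator; the unbiased choice, documented rather than canonical)
of the corrected control frequencies.  Bins with SD below 10⁻⁹ are
excluded from Z-scores — a near-constant bin would turn measurement
noise into unbounded scores.  For a held-out control the per-bin Z has
variance ≈ 1 + 1/n_controls, which the suite checks by simulation.

## Smoothing and the I-score

Z-scores are LOESS-smoothed against bin index independently per
chromosome (adjacent-bin smoothing is only meaningful within a
chromosome); window = max(4 bins, 5% of the chromosome's usable bins),
degree 1, no robustness iterations — robust reweighting would treat
genuine focal amplifications as outliers and erase them.  Chromosomes
with fewer than 4 usable bins pass through unsmoothed with a warning.
The I-score is the natural log of the genome-wide sum of absolute
smoothed Z; an all-zero profile is reported as missing with a reason
rather than −∞.  Classification is strict: high iff score > cutoff, so
a score exactly at the cutoff is low.  The shipped default cutoff 7.3 is
cohort-derived, not structural; the survival layer re-derives a cutoff
for any cohort.

## Segmentation and concordance

Segmentation is recursive binary splitting: per chromosome, the split
maximizing the pooled-variance two-sample t-statistic is accepted when
its permutation p-value (best-split statistic recomputed on ≥ 1000
within-chromosome shuffles, add-one estimator) falls below alpha = 0.01;
accepted splits recurse on both flanks (minimum segment width 2 bins).
This deliberately omits circular binary segmentation's pruning and
undo-splits machinery; what survives downstream is change-point
location, which the suite verifies against an exhaustive single-split
oracle on short profiles and against planted steps.  The permutation
stream is a single seeded generator consumed depth-first (left flank
before right), making results bit-reproducible.

Plasma/tissue concordance projects the plasma Z-profile onto the
matched tissue segmentation — each baseline segment gets the mean plasma
Z over bins whose midpoints it contains (midpoint membership avoids
edge double-counting) — and reports Pearson r and r² across segments
(≥ 3 segments required; zero-variance vectors yield a missing value).
On simulated pairs sharing segments (plasma tumor fraction 0.3, tissue
undiluted), median r² runs ~0.85–0.95.

## Recurrent regions

Aberration calls threshold the smoothed Z at strictly > +2 (amp) and
< −2 (del).  The per-bin, per-direction recurrence score is the
amplitude-weighted frequency Σ_samples |z|·1[call] / n_samples.  The
null preserves each sample's aberration spectrum but destroys positional
recurrence: every sample's per-chromosome contribution vector is
cyclically shifted by an independent uniform offset.  Shift streams are
seeded from a digest of each sample's own call/amplitude content, which
makes the region list exactly invariant under sample reordering (two
byte-identical samples would share a stream — harmless in practice and
the price of order invariance).  Per-bin empirical p-values (add-one)
are Benjamini–Hochberg adjusted within direction across usable bins, and
maximal runs with q < 0.25 become regions (region G = max member G,
region q = min member q).  The full GISTIC2.0 peel-off and
arm-level/focal decomposition are intentionally out of scope; the
planted-recurrence and null-FDR tests define what the simplified scorer
is warranted to do.

## Gene sum score

Gene-level Z is the length-weighted mean of overlapping usable-bin Z
(weights = bp overlap).  Scoring is direction-aware and strict: 1 for an
amplification-region gene with Z > 2 or a deletion-region gene with
Z < −2, else 0; genes with no usable-bin overlap score 0 with a warning.
Genes are ranked by the two-group log-rank p between score-1 and score-0
patients (degenerate columns get the sentinel p = 1; ties break by
symbol for determinism).  Five-fold cross-validation with simple random
seeded folds (refolded until every fold has an event): each training
fold ranks genes, scans N in 1..50 and integer GSS cutoffs, and keeps
the (N, cutoff) minimizing the training log-rank p — ties resolve toward
the smaller cutoff, then smaller N.  Admissible cutoffs must leave at
least 10% of the cohort on each side (`MIN_GROUP_FRAC`): degenerate
splits make the asymptotic log-rank anti-conservative on held-out folds
(measured ~0.08 null rejection at nominal 0.05), and the guard mirrors
the 10% trim used for continuous cutpoints.  The consensus sets are the
intersection (overlap) and union of the fold selections.  External
GISTIC-style matrices (−2..2) score 1 only for ±2 calls.

The hot loops use a vectorized risk-set log-rank implementation
(`cfgi._stats`), cross-checked against lifelines to 9 significant
figures in the tests; user-facing Kaplan–Meier and log-rank go through
lifelines itself.

## Survival layer

Associations between the instability groups use pooled-variance t-tests
for continuous covariates and Pearson chi-square *without* continuity
correction for categorical ones, switching to Fisher's exact test for
2×2 tables with any expected count below 5 — these conventions reproduce
published contingency-table p-values exactly from their own counts.
Cox models use lifelines (Efron ties); backward elimination repeatedly
drops the largest Wald p ≥ 0.05.  Harrell's C counts ties as ½ through
lifelines' `concordance_index`, verified against pair enumeration.

The optimal cutpoint scans every observed marker value inside the
[10%, 90%] quantile window, computes the log-rank score statistic S_c
for the split marker > c, and standardizes by sqrt(s²(D−1)) with D the
number of distinct event times and s² = Σ a_i²/(D−1),
a_i = 1 − Σ_{j≤i} 1/(D−j+1).  The cutpoint is the candidate maximizing
the standardized |S_c| (ties toward the smaller cut).  Because the
statistic depends on the marker only through its ordering, the cutpoint
is equivariant under monotone transforms.

## Synthetic data

The generator is first-class, tested code, and its defaults *are* the
study conditions: 38 controls, 3.1 million reads per sample, and
clinical cohorts of 315 patients split 239 low / 76 high instability
with group hazard ratios 2.69 (progression-free) and 3.07 (overall
survival) and ~40% censoring.

Counts are negative-binomial (Gamma–Poisson) around a GC-dependent
expectation; dispersion 0.02 reflects the overdispersion of low-pass WGS
bin counts relative to Poisson.  The default bias curve is a smooth
multiplicative bump peaking near GC 0.45 — only its removability is
asserted, not its exact shape.  Planted copy-number segments multiply
the expected bin depth by 1 + f·(c−2)/2 for tumor fraction f and copy
number c (tissue is f = 1), renormalized to constant total depth.

Clinical cohorts draw death times as exponential with hazard
λ_d·hr_os^g, and progression times with the high-group rate solved so
that PFS = min(progression, death) has *exactly* the requested marginal
hazard ratio; this construction keeps both endpoints proportional
hazards and guarantees PFS ≤ OS per patient.  One uniform censoring time
per patient is shared by both endpoints, with the horizon solved
numerically (Brent) so the mean PFS censoring fraction hits the target.
Baseline medians default to 7 months (PFS) and 12 months (OS); the pair
(hr_pfs, hr_os) must keep the implied progression rate positive, else
the generator refuses.  The cutpoint-recovery design draws the marker
uniformly on [5, 10] with a hazard step (HR 3) strictly above 7.3.

What the simulations do **not** establish: fragment-size effects,
mappability structure, GC bias of real chemistry, clonal heterogeneity,
non-proportional hazards, or informative censoring.  Passing tests show
the estimators recover their own generative models at realistic sizes —
not that any cohort-specific published value would be reproduced from
raw patient data.

## Problem sizes

Tests and the analysis scripts run on a 6-chromosome × 40 Mb genome
(240 bins) at 500k reads per sample — large enough that panel SDs,
LOESS windows and permutation nulls behave as at full scale, while the
whole suite stays fast.  Hazard-ratio recovery averages 200 replicate
315-patient cohorts; cutpoint recovery takes the median of 100.  The
per-gene CV designs use 200 patients × 30 genes (10 planted with
per-gene hazard ratio 1.8 at prevalence 0.3 — each planted gene is
individually prognostic, matching the method's premise).

## Known limitations

* The recurrence scorer is a simplified GISTIC: no peel-off, no
  arm/focal decomposition, no gene-level significance — single-bin
  regions at marginal q are expected under FDR control.
* LOESS span defaults (0.75 for GC, 5% of a chromosome for smoothing)
  are conventions, not fitted constants; strongly curved GC bias is
  under-corrected at span 0.75 (see tolerances above).
* The CV gene selection tunes (N, cutoff) on the training fold only
  (no nested CV), the plain reading of the procedure it implements.
* `segment` is quadratic in the worst case (permutations × recursion);
  it is intended for ~10²–10³ bins per chromosome, not base-pair grids.
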