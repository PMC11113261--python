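# Methods

## Background and model

Cell-free DNA (cfDNA) in blood plasma consists mostly of nucleosome- and
chromatosome-protected fragments left behind by nuclease digestion, so the
geometry of a person's chromatin is readable from aligned cfDNA fragments
alone.  `nucleoclock` works with two integral summaries of that geometry:

* the **fragment-size distribution** — dominated by the chromatosome
  footprint (~167 bp), with secondary modes near `NRL + 167` and
  `2·NRL + 167` from di- and tri-nucleosome fragments;
* the **phasogram** — the histogram of pairwise genomic distances between
  fragment centres on the same chromosome.  Because fragment centres track
  nucleosome dyads, the phasogram oscillates with period equal to the
  nucleosome repeat length (NRL).

The **NRL** is estimated as the slope of an ordinary least-squares fit of
phasogram peak position against peak order k (peak k sits near `k·NRL`).
The slope form is robust to a constant offset — the intercept absorbs any
linker/footprint shift — and to missing harmonics, because order indices
may skip values.

Age enters through three downstream analyses:

1. **NRL–age correlation**: Pearson correlation (two-sided t-distributed
   p-value) between per-sample NRL estimates and chronological age; a
   paired t-test is available for matched group designs.
2. **Differential-occupancy PCA**: per-sample occupancy = fragments
   overlapping each 100-bp bin, scaled to fragments-per-million; per-bin
   Welch t-tests between age groups with Benjamini–Hochberg FDR select
   differential bins; PCA fitted on standardised occupancy over those bins
   (discovery samples only) stratifies the cohort, and held-out samples are
   projected with the frozen discovery standardisation.
3. **Aging clocks**: linear age predictors over either feature kind
   (size-frequency vector over 100–600 bp, or the smoothed normalised
   phasogram over 120–2000 bp), evaluated on a held-out 20% split and
   reusable as an age-group classifier via the predicted age as ROC score.

## The synthetic cohort generator

Real cfDNA cohorts of the kind this pipeline targets are controlled-access,
so every stage is validated against a simulator with known ground truth.

Each cohort lives on one synthetic chromosome (`chrS`).  Nucleosome arrays
follow the statistical-positioning picture of chromatin: array **barriers**
(boundary elements such as CTCF sites or TSSs) are drawn once per cohort
with uniform spacing in [2.5, 5] kb and are shared by every subject.
Within an array, dyad j sits at

    barrier + j · NRL_subject + jitter_j,

with `NRL_subject = beta0 + beta1 · age + N(0, sigma_subject)`.  The
per-dyad jitter has total SD 20 bp, split into a cohort-shared component
(75% of the variance, representing sequence-encoded positioning
preferences common to all individuals) and a subject-specific remainder.
This sharing is what makes per-bin occupancy comparable across subjects —
as it is in real cohorts, where people share one genome and largely one
nucleosome map — while each subject's own NRL still sets the within-array
spacing that phasograms measure.  A fully per-subject lattice
(`barrier_spacing_range=None`, `jitter_shared_frac=0`) is available for
controlled experiments; with per-subject lattices, lattice phase at a fixed
bin decorrelates between subjects within `~NRL²/ΔNRL` bp, and binned
occupancy stops being comparable across people at all.

Fragments are mono-, di- or tri-nucleosomal with age-linked weights: raw
weights `(w_mono0, w_di0 + d_di·age, w_tri0 + d_tri·age)` renormalised to
sum to one, so the di/tri share declines with age.  A k-nucleosome fragment
spans k adjacent dyads of one array (never a barrier), centred on the span
midpoint, with length = span + `N(mu_mono, sd_len)`; expected lengths are
therefore `mu_mono`, `NRL + mu_mono` and `2·NRL + mu_mono`.  Exactly
`n_fragments_per_subject` fragments are emitted, clipped to genome bounds.

Optionally a set of 100-bp bins is planted whose sampling rate is
multiplied by `1 + (f_max − 1)·(age − age_lo)/(age_hi − age_lo)`.  A
fragment counts as "in" a bin when it *overlaps* it, so a planted factor of
2 produces a genuine 2× binned occupancy under the pipeline's
overlap-counting rule (weighting by centre membership would dilute the
effect to ~1.3× through neighbouring fragments).

Default parameters (units bp unless noted): `beta0 = 185`,
`beta1 = 0.02 bp/year` (≈1.5 bp across an adult lifespan),
`sigma_subject = 0.5`, `dyad_jitter_sd = 20`, `jitter_shared_frac = 0.75`,
`mu_mono = 167`, `sd_len = 15`, mixture at age 0 = (0.55, 0.30, 0.15) with
slopes (−0.0015, −0.0010) per year, genome 20 Mb, 200,000 fragments per
subject, ages uniform on [25, 100] years.  Magnitudes follow chromatosome
biology and the ~1–2 bp per-lifespan NRL drift the pipeline is designed to
resolve; the mixture slopes are test scaffolding, not biological claims.

Reproducibility: subject i draws from an RNG stream seeded by
`(cohort seed, i)`; barriers and shared jitter use dedicated cohort-level
streams.  Cohorts are therefore order-independent and any subject can be
regenerated in isolation.

**What the generator does not emulate**: real genome sequence (no GC or
mappability bias), chromatin-state heterogeneity, sub-nucleosomal
fragments, the 10.4-bp helical-pitch periodicity, inter-individual copy
number or cell-type composition differences, and sequencing error.  Tests
passing on this generator show that the estimators recover their own
generative parameters at realistic noise levels — not that real cohorts
carry signals of that strength.

## Numerical choices

* **Phasogram**: exact integer pair counts by comparing each sorted centre
  with its k-th successor until all gaps exceed `d_max` (default 2000 bp);
  ordered pairs i<j, same chromosome, pooled over chromosomes.  No
  all-pairs matrix is ever formed.
* **Smoothing**: Savitzky–Golay, window 51 bp, polynomial order 3, applied
  once to the normalised counts; raw counts are kept untouched.
* **Peak detection**: prominence-based local maxima (default threshold 5%
  of the smoothed signal range in the fit region, floor 1e-15) at
  d ≥ 120 bp, the fit start excluding the zero-lag shoulder.  Peak
  positions are refined to sub-bin precision by parabolic interpolation,
  which removes most of the 1-bp quantisation bias.
* **Order assignment**: a coarse period is taken as the dominant
  DFT-amplitude period scanned over 120–260 bp in 0.25-bp steps, then
  `k = round(position/period)`.  Peaks more than a quarter period from an
  integer multiple are discarded — di-nucleosome fragment centres sit
  mid-way between dyads and generate half-period sub-harmonics that would
  otherwise corrupt the fit.  Ties on the same k keep the more prominent
  peak; k ≤ 10.
* **NRL fit**: OLS of position on k with intercept; an estimate is flagged
  unreliable (not discarded) when the slope leaves [120, 260] bp, R² < 0.95
  or the slope SE exceeds 2 bp.  NRL estimation pre-filters fragments to
  the mono-nucleosome window (120–200 bp) so centres track single dyads;
  the clock's distance features deliberately keep all fragments, because
  the half-period structure carries mixture (hence age) information.
* **Differential bins**: Welch t-test per bin (Wilcoxon rank-sum optional
  for ≥4 per group), BH FDR at alpha = 0.05, bins empty in all samples
  excluded before testing.  With fewer than two samples per group the
  method falls back to moderated fold-change ranking (pseudocount = 5% of
  mean occupancy; threshold 1.5×), flagged as `method="fold_change"`.
* **PCA**: per-region standardisation over discovery samples, constant
  regions dropped with a warning, full-rank SVD so explained-variance
  ratios sum to one; projection always reuses discovery means/SDs.
* **Clock**: with hundreds of correlated features and tens of samples a raw
  multiple regression is underdetermined, so the default is
  principal-component regression — standardise on the training split,
  project on the top-k training PCs (k = 10), OLS on the scores — which is
  a linear model in the original features.  Ridge regression
  (alpha = 1.0) on standardised features is the alternative mode.  The
  80/20 split is a seeded random partition stratified by age tertile so
  test ages span the cohort range even at small n.  PCR relies on the age
  signal lying in high-variance feature directions (true for both feature
  kinds here); it is not robust to adversarial isotropic noise features
  with no variance advantage, where the ridge mode is preferable.
* **AUC**: rank (Mann–Whitney U) formula with average-rank tie correction;
  verified in tests against trapezoidal ROC integration.

## Problem sizes used in the automated checks

Test and acceptance runs scale the simulations to desk size; each choice
was fixed by a power calculation before freezing the suite:

* NRL recovery: 20 Mb genome, 200,000 fragments per subject (estimator
  SD ≈ 0.13 bp, bias ≈ 0.01 bp over 20 seeds).
* NRL–age cohorts: n = 60, 5 Mb, 50,000 fragments per subject (estimator
  SD ≈ 0.20 bp versus a 0.43 bp age-signal SD at beta1 = 0.02).
* Differential bins: 250 kb, 300,000 fragments per subject, 50 planted 2×
  bins, 5 vs 5 subjects (measured recall 0.86–0.96); null FDR at 100 kb,
  50,000 fragments, 50 seeds.
* Clocks: n = 80, 2 Mb, 100,000 fragments per subject, with a steeper
  mixture link — weights (0.45, 0.35, 0.20) at age 0, slopes
  (−0.003, −0.0018) per year — as the strong-drift condition.

## Known limitations

* NRL is genome-wide; no per-chromatin-state or region-specific NRLs.
* The phasogram assumes enough local fragment density for within-array
  pairs; very shallow samples fail peak detection and surface as flagged
  rows in cohort tables.
* The differential-bin test treats bins independently; neighbouring bins of
  a planted bin are partially enriched through fragment overlap and may be
  discovered alongside it.
* Clock hyper-parameters (k, ridge alpha, feature windows) are exposed
  configuration, and the defaults were chosen for the synthetic benchmark;
  real-cohort use would tune them by cross-validation.
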