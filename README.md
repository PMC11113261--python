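# nucleoclock

Nucleosomics of cell-free DNA: fragment-size distributions, nucleosome
distance phasograms, nucleosome repeat length (NRL) estimation,
differential-occupancy PCA stratification, and linear aging clocks — plus a
synthetic cfDNA cohort simulator that gives every stage a known ground
truth.

## Who this is for

Plasma cfDNA is mostly nucleosome-protected DNA, so aligned cfDNA fragments
encode the chromatin geometry of their cells of origin.  This package is
for liquid-biopsy and chromatin researchers who have per-sample fragment
BED files (chrom, start, end; 0-based half-open) plus a sample/age table
and want to ask: *does nucleosome spacing drift with age in this cohort,
and how well do cfDNA distributions predict chronological age?*

## The quantities it computes

* **Fragment-size distribution** — 1-bp histogram over 100–600 bp;
  mono/di/tri-nucleosome proportions as frequency mass in configurable
  windows (defaults 120–200 / 275–420 / 440–600 bp).
* **Phasogram** — counts of ordered same-chromosome fragment-centre pairs
  at each distance d ≤ 2000 bp, computed exactly with a sorted sliding
  window.
* **NRL** — peaks of the Savitzky–Golay-smoothed phasogram are assigned
  harmonic orders k from a coarse spectral period, and the NRL is the OLS
  slope of peak position on k:  `position ≈ intercept + NRL · k`, with R²,
  slope SE and a reliability flag.
* **NRL–age statistics** — Pearson r with two-sided p; optional paired
  t-test between matched groups.
* **Differential occupancy** — per-sample fragments-per-million occupancy
  in 100-bp bins; per-bin Welch t-tests with Benjamini–Hochberg FDR select
  differential bins; PCA over those bins (fitted on discovery samples,
  held-out samples projected with frozen standardisation) stratifies the
  cohort.
* **Aging clocks** — principal-component regression (default k = 10; ridge
  available) of age on either the size distribution or the smoothed
  phasogram, evaluated on a seeded 80/20 age-stratified split; the
  predicted age doubles as the ROC score for an age-group classifier with
  a rank-formula (Mann–Whitney) AUC.

See `docs/methods.md` for the model, the simulator, and every numerical
default.

## Worked example

Simulate a 12-subject cohort and estimate each subject's NRL:

```sh
nucleoclock simulate --n-subjects 12 --genome-length 2000000 \
    --n-fragments 100000 --seed 5 --out-dir cohort/
nucleoclock nrl --bed-dir cohort/ --meta cohort/metadata.tsv --out nrl.tsv
```

which prints the per-group summary (ungrouped samples pool under "all"):

```
group       mean     median      var  n
  all 186.220844 186.391024 0.204028 12
```

and `nrl.tsv` holds one row per sample, e.g.

```
sample_id  age        nrl        slope_se  r_squared  n_peaks  flag
S000       55.2338..  185.6435.. 0.1523..  0.999994   10
```

The cohort was simulated with NRL = 185 + 0.02·age + subject noise, so the
fitted spacings near 186 bp at ages 25–100 recover the generative model.
Train and evaluate an aging clock on the same cohort:

```sh
nucleoclock train --bed-dir cohort/ --meta cohort/metadata.tsv \
    --feature-kind size_dist --k 4 --seed 0 --out-dir clock/
# -> test r=0.999 mse=4.92 medae=1.51
nucleoclock classify --predictions clock/predictions.tsv --split all
# -> AUC = 1.000
```

Here r is the Pearson correlation between predicted and chronological age
on the held-out split, MSE is in years², the median absolute error is in
years, and the AUC scores the ≤55 vs >55 year split using predicted age.

The same pipeline is importable as a library
(`from nucleoclock import read_fragments, nrl_from_fragments, ...`); the
CLI subcommands are thin wrappers over those functions.

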