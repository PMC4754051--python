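# Methods

## Detection, well QC and the expression scale

Single-cell RT-qPCR yields one cycle-threshold (Ct) value per well × gene;
lower Ct means higher abundance. A reaction with no amplification is stored
as the sentinel 999. Detection uses a limit of detection (LOD) of 30
cycles with a strict inequality: Ct < 30 is detected, Ct = 30 is not. Wells
are retained only if the housekeeper GAPDH is detected — a well without
housekeeper signal indicates a failed sort or failed reverse transcription,
not a biological state.

Downstream correlation and PCA need a continuous scale that keeps censored
(undetected) reactions in the analysis. We use the LOD-anchored transform
expression = max(0, 30 − Ct), so undetected reactions contribute 0 and
detected reactions a positive value monotone in abundance. This is a design
choice: raw Ct with dropouts treated as missing, or binary detection calls,
are alternatives; `perm_corr_test` accepts 0/1 detection values (giving a
phi coefficient) and records the scale used in its output. Analyses are run
without housekeeping-gene normalisation of individual Ct values, standard
practice for single-cell RT-qPCR where per-cell housekeeper expression is
itself noisy.

## Batch adjustment

Chips (batches) are aligned additively on the housekeepers GAPDH and ACTB.
For each batch the shift is the mean over the two housekeepers of the
difference in mean detected Ct relative to the reference batch, averaged
over QC-passing wells only (undetected housekeeper reactions carry no Ct
and cannot enter a mean). The shift is subtracted from every measured Ct of
the batch; sentinels are untouched, so detection calls change only if a
shift moves a Ct across the LOD. The procedure is idempotent (re-adjusting
returns shifts of 0) and recovers a planted shift exactly when the shifted
wells are technical copies of reference wells.

Technical-replicate reliability is summarised per gene as the squared
Pearson correlation of Ct over wells measured on both chips (≥3 pairs
required); the exclusion threshold defaults to r² < 0.5 and is
configurable, since "poor reliability" has no canonical numeric cutoff.
Dilution-series linearity is the per-gene r² of Ct on log2 dilution over
detected points.

## Phenotype and cortical-layer classification

A QC-passing well is a neuron iff any of MAP2 / NCAM1 / TUBB3 is detected.
Laminar identity uses the canonical marker sets — deep: BCL11B (CTIP2) and
TBR1; upper: CUX1, POU3F2 (BRN2) and SATB2 — with four mutually exclusive
categories: *deep* (≥1 deep, 0 upper), *upper* (symmetric), *mixed* (≥1 of
each) and *none*. "Unambiguously assignable" therefore means markers of
exactly one class detected, whatever their number. GABAergic status is GAD1
detection in a neuron; GAD1 in a non-neuronal well creates no call. Glial
marker detection (GFAP / OLIG2) is flagged independently; in pathological
synthetic inputs a well can carry both neuron and glia flags, in which case
neuron status drives layer assignment and the co-flag is reported.

Composition across groups (e.g. culture ages) is compared with a chi-square
test of homogeneity on the category × group table; when more than 20% of
expected counts fall below 5 the test switches to a seeded Monte-Carlo
exact test (fixed margins, chi-square ordering statistic), and the test
used is recorded in the result.

## Permutation co-expression test

For each gene pair, Pearson correlation is computed over QC-passing
neurons; then the second gene's values are permuted across wells (always
the second gene — irrelevant in distribution, fixed for reproducibility).
The empirical two-tailed p-value is add-one smoothed,
p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm), so p is floored at
1/(n_perm+1) and never zero; the default is 10 000 permutations. For n ≤ 8
wells an exhaustive mode enumerates all n! permutations and returns the
exact proportion (the identity permutation counts, so a perfectly
correlated pair of 4 wells gets p = 2/24). Zero-variance genes make a pair
not evaluable, excluded from the Benjamini–Hochberg family; BH is applied
across the evaluable pairs tested in a run.

## PCA and the cluster-separation test

PCA is computed on centred (not variance-scaled) expression; sign
indeterminacy is fixed by forcing the largest-magnitude loading of each
component positive. Separation of two labelled groups on the first two PCs
is tested by computing, per point, the Euclidean distance to its own group
centroid and to the pooled centroid of all points, and applying a two-sided
Wilcoxon signed-rank test to the paired distances over all points (zero
differences excluded). Under the null both centroids estimate the same
location and the paired differences are symmetric around zero; under
separation own-centroid distances are systematically smaller. The wording
of this procedure admits an unpaired reading; a rank-sum variant is
available behind `paired=False`, with the paired signed-rank the default as
the only reading that uses individual points against both centroids.

## Single-cell RNA-seq QC and normalisation

A gene is detectable in a cell iff at least one fragment is assigned
(count ≥ 1). Cell QC applies three filters, each evaluated once on the full
input cohort (single pass, no re-fitting):

* **low_gene_count** — detected-gene count below the Tukey boxplot lower
  fence Q1 − 1.5·IQR of the cohort ("boxplot lower limit" read as Tukey's
  rule); needs ≥4 cells.
* **high_mito** — fraction of assigned fragments on mitochondrial genes
  strictly above 0.15. The fraction is computed over assigned counts, the
  only information present in a count matrix.
* **pca_outlier** — Euclidean distance from the cohort centroid in the
  top-2 PC space of size-factor-normalised log1p counts exceeding 5× the
  MAD of all cells' distances.

Both cohort-relative rules flag cells *relative to the cohort*: on a noisy
but healthy cohort the 5×MAD distance rule fires on a few percent of cells
by construction (distances are roughly Rayleigh; 5×MAD sits near 2.3σ), and
the boxplot fence has a small lower-tail rate. Planted-failure recovery is
therefore checked per filter — the mito filter must flag exactly the
planted high-mito cells, the complexity filter exactly the planted
low-complexity cells — on a cohort homogeneous in library size (size
factors 0.8–1.25×), because with wider library variation the fence
correctly flags genuine small libraries too.

Size factors follow the median-of-ratios rule: per-gene geometric means are
taken over genes with nonzero counts in every cell, and each cell's factor
is the median of its count/geomean ratios over those genes. Factors are
defined up to a global constant; recovery against planted truth is measured
as mean relative error after removing that constant (the per-cell maximum
under gamma-Poisson noise is sampling-dominated and not informative about
the estimator). When no gene is nonzero in all cells (possible once
low-complexity cells are present) a pseudocount of 1 extends the geometric
means to all genes; the error message points there.

FPKM is counts / (length_kb × assigned fragments per million), with gene
lengths from the annotation table and total assigned fragments per cell as
the per-million denominator. The DE post-filter takes an external per-gene
significance flag plus group means and detection fractions, and retains a
gene only if some group has detection fraction > 0.10 and mean FPKM > 1
(both strict) and the sign of the detection-fraction change matches the
sign of the mean-level change (zero change fails). The DE test itself is
out of scope; `ranksum_de_flags` ships as a clearly labelled synthetic
stand-in so the post-filter can be exercised end to end on simulated data.

## Synthetic data

`simulate_qpcr` draws wells from six archetypes (deep / upper / mixed /
markerless neurons, glia, failed wells) with a largest-remainder allocation
of the composition, assigns chips round-robin, and emits for each truly
expressing gene a Gaussian Ct (default mean 20, sd 2, clipped above 0) plus
the chip's additive shift; dropout is i.i.d. Bernoulli per gene per cell
(default detection probability 0.85), the simplest mechanism compatible
with single-cell qPCR practice. Neurons express the identity markers, a
synaptic background programme and, with probability `gaba_fraction`
(default 0.24), GAD1. What this does *not* emulate: Ct-correlated dropout
(weakly expressed genes dropping out more), melting-curve artefacts,
chip-position effects, or cross-well contamination — so passing tests show
the pipeline's rules are implemented correctly, not that they are robust to
those real-data failure modes.

`simulate_counts` draws gamma-Poisson (negative binomial) counts with
log-normal baseline means (log-mean 1.5, log-sd 1.0, i.e. typical counts in
the tens at Smart-seq-like depth), dispersion 0.2, uniform true size
factors (default 0.5–2×), 13 mitochondrial genes by default and gene
lengths uniform in 0.5–10 kb. Planted outliers alternate between mito
inflation (~50% of the library) and complexity collapse (90% of genes
zeroed), with the kind recorded in the ground truth.

The worked-example fixture is fully deterministic: detected reactions sit
at Ct 20 (any value below the LOD would do; a constant keeps the fixture
byte-stable) and its classification marginals equal the published taxonomy
— 478 wells, 406 housekeeper-positive, 380 neurons, 184 single-layer, 85
mixed, 111 layer-negative, 91 GABAergic. Within the 184 single-layer
neurons the 100 deep / 84 upper split is a placeholder (only the aggregate
is published) and nothing downstream depends on it. Note 406/478 = 84.9%.

## Problem sizes and numerical choices

The calibration experiments use 1000 null gene pairs of 100 cells at 1000
permutations (type-I error against the binomial 95% envelope
[3.7%, 6.4%]), 50 000 sampled permutations against exhaustive enumeration
for 4–6 wells (agreement within 0.01), 100 null replicates of 200 points
for the cluster test, 50 cells × 1000 genes for size-factor recovery and
50 wells per chip for batch-shift recovery. Permutation comparisons use a
1e-12 tolerance on |r| to keep ties stable under floating-point noise;
composition Monte-Carlo uses 10 000 tables by default. Degenerate inputs
fail loudly: constant matrices for PCA, all-sentinel wells for QC, groups
with no cells for composition tests, cells with zero totals for FPKM.
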