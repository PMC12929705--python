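# Methods

This note documents the models, estimators and numerical choices in
`cytotraits`, in the order the pipeline applies them.

## Event model and synthetic data

The generator emulates per-event cytometry tables from a resource-limitation
experiment on a unicellular/colonial cyanobacterium, with 5 treatments
(control, high pCO₂, low N, low P, low L) × 4 replicates, and a field
series.

* **Channels.** 18 optical channels: four informative (FSC, SSC, FL670 =
  phycocyanin fluorescence, FL692 = chlorophyll-a fluorescence) and 14
  distractor filters. Channel values are lognormal — peak-height data are
  right-skewed — with a per-channel coefficient of variation (default 0.5
  informative, 0.4 distractors) and log-scale correlation ρ = 0.8 between
  the two pigment channels. Six distractors are deliberately collinear
  (ρ = 0.85–0.92) with an informative parent channel, so the collinearity
  filter has realistic work; the rest are independent. With the five
  derived ratio traits this reproduces a ~23-candidate trait screen
  reducing to eight.
* **Treatment effects.** Each treatment multiplies channel medians by a
  factor (control ≡ 1). Signs follow the limitation physiology: low N
  raises FSC (arrested growth, carbon accumulation) and depresses SSC and
  both pigments, with phycocyanin hit hardest (PC:Chl-a falls); low L
  raises both pigments (low-light acclimation); low P raises phycocyanin
  but lowers chlorophyll-a; high pCO₂ is a mild variant of the control.
  Magnitudes (e.g. 0.30 for FL670 under low N) are free parameters chosen
  to give unambiguous, recoverable contrasts at n ≈ 10³ events.
* **Spread design.** Each treatment also scales the log-scale standard
  deviation of its events: low_N 0.55 < low_L 0.90 < control 1.00 <
  high_pCO2 1.20 < low_P 1.40. This plants a known rank order of
  functional richness (hypervolume size), used as ground truth by the
  recovery tests.
* **Debris.** 10% of events are drawn uniform-on-log-scale between 1 and
  1/20 of the channel baseline — a broad dim cloud the clustering stage
  must remove.
* **Field series.** Sample *i* carries a gradient value g ∈ [0, 1]; its
  effect vector is the geometric interpolation low_L^(1−g) · low_N^g
  (effects are multiplicative, so interpolation is log-linear). The
  metadata report TN rising and light falling monotonically in g, so the
  TN:light ratio is a strictly monotone index of the planted
  light-limited → nitrogen-limited transition. The sign convention of this
  covariate is a generator convention for rank-association checks, not an
  ecological claim; in real lakes nitrogen limitation is expected at *low*
  TN:light.
* **Bioassay.** Day-0 fluorescence ~100 a.u. (10% CV); 4-day growth rate
  0.10 d⁻¹, plus 0.25 d⁻¹ for the addition matching the designed limiting
  nutrient; day-4 noise 8% CV, 3 replicates per treatment.

Everything is a pure function of (config, seed, sample indices) through
`numpy.random.SeedSequence`, so tables are bitwise reproducible.

What the generator does **not** emulate: instrument drift, spectral
spillover/compensation, doublets and colony-size structure, day-to-day
acquisition effects, or taxonomic mixtures in the field. Passing tests
therefore demonstrate that the estimators recover structure of this
statistical form, not that the pipeline is robust to every artefact of
real cytometry.

## Gating

Clustering runs on log₁₀(x+1)-transformed channels (the +1 keeps zero
events finite; the inverse 10^y − 1 restores original values to machine
precision). The density clusterer is scikit-learn's HDBSCAN with
`min_cluster_size` = 1% of events (floor 25), `min_samples` = 10 and
`cluster_selection_epsilon` = 0.15 log₁₀ units. The epsilon merges
sub-clusters closer than ~0.15 decades: without it the excess-of-mass
selection fragments a single homogeneous population into mode-proximal
shells and labels most events noise; 0.15 is small enough that genuinely
distinct populations (≥ ~1 decade apart) are never merged. The target
population is the largest cluster whose median FL670 exceeds the global
median (cyanobacteria are phycocyanin-bright); when no cluster is brighter
than the global median, the size-qualified cluster with the highest median
FL670 is taken.

Field samples are additionally restricted to particles of 0.5–10 µm
(closed interval), using a log–log least-squares line through bead modes
of known size (modes found by 1-D k-means on log FSC; supplied sizes must
be strictly increasing in FSC order).

## Traits and standardisation

The eight traits, in fixed order: cell_size = FSC, granularity = SSC,
gas_vesicle = FSC^β/SSC, phycocyanin = FL670, chlorophyll_a = FL692,
pc_per_size = FL670/FSC, chla_per_size = FL692/FSC, pc_chla = FL670/FL692.
The cell-volume proxy in the gas-vesicle trait is FSC^β with β = 1 by
default — a deliberate refusal to commit to an optical sizing model; β is
exposed for users with a calibrated volume relation. Events with a zero in
a denominator channel are dropped and counted.

The collinearity filter works on |Pearson r| of log₁₀ values: while any
unprotected pair exceeds the threshold (default 0.8), the member of the
worst pair with the larger mean |r| to the remaining candidates is
dropped. A keep-list exempts traits with distinct ecological meaning
(e.g. the two pigment fluorescences) from elimination.

Standardisation is log₁₀ then z-score with **population** sd (ddof 0) so
that results are bitwise reproducible and a stored model can be re-applied
to field data exactly.

## Integrated phenotype

PCA is computed by SVD of the centred standardised trait matrix; axes are
ordered by variance, and each axis is sign-fixed so its largest-magnitude
loading is positive. All events are weighted equally. Axis significance
uses a permutation null that shuffles each trait column independently
(n_perm default 999 at the operation level; the orchestrated pipeline uses
199, which resolves α = 0.05 comfortably at its sample sizes); axis *j* is
significant when its observed eigenvalue exceeds the 1−α quantile of the
j-th permuted eigenvalues. Hypervolumes are built on the significant axes
among the first two (the dominant pair of dimensions), falling back to the
first two when none is significant.

Functional clustering of the 20 treatment-replicate mean profiles uses
k-means (10 restarts, fixed seed) for k = 1..k_max; k is the maximiser of
the second difference of the within-cluster sum of squares (the explicit
elbow rule). Identical profiles short-circuit to k = 1.

## Hypervolumes and functional diversity

The functional space of a replicate is the highest-density region of a
product-Gaussian KDE of its scores, with per-dimension Silverman
bandwidths h_j = σ_j (4/((d+2)n))^(1/(d+4)).

* **Threshold.** The data points are (to KDE accuracy) a sample from the
  estimated density, each carrying mass 1/n; the 95% region is therefore
  delineated by the density of the lowest point among the ⌈0.95·n⌉
  densest data points. (The alternative reading — weighting points by
  their density values — retains roughly half the Gaussian reference
  region and is inconsistent with the closed-form check below.)
* **Support points.** Proposals are drawn from the KDE mixture (random
  data point + bandwidth-scaled Gaussian noise) and rejected below the
  threshold; the survivors follow the KDE restricted to the region. A
  second thinning stage accepts each survivor with probability
  threshold/f̂(x), which makes the stored support cloud *exactly uniform*
  inside the region — the property the intersection and dispersion
  estimators rely on. Default support size m = 500·d; the seed is a
  mandatory part of the API.
* **Volume (richness).** vol ≈ P̂(R) · mean(1/f̂) over the stage-1 sample,
  with P̂(R) the accepted/proposed ratio (an unbiased estimate of the KDE
  mass of the region). On standard-normal 2-D scores this reproduces the
  analytic 95% highest-density ellipse π·χ²₂(0.95)·(1+h²) within ~4%; the
  residual is the threshold rule measuring the data spread rather than
  the KDE-inflated spread, and shrinks with n.
* **Evenness.** Overlap ∫ min(f_R, u) between the region-restricted,
  renormalised KDE f_R and the uniform density u on the region, computed
  over the uniform support points; 1 = perfectly even occupancy.
* **Dispersion.** Mean Euclidean distance of the uniform support points to
  their centroid.
* **Jaccard.** Intersection volume estimated symmetrically as
  ½[vol_a·frac(a-support in R_b) + vol_b·frac(b-support in R_a)]; union =
  vol_a + vol_b − intersection; clipped to [0, 1]. Two hypervolumes built
  from the same data and seed give J = 1 exactly.

A dense-grid integrator of the identical KDE (`cytotraits.gridref`,
2-D only, 400² cells) serves as the brute-force reference; the Monte-Carlo
indices agree with it within a few percent at the default support sizes.
An acceptance-rate guard raises an error below 10⁻⁴ instead of looping
forever on degenerate thresholds.

## Treatment inference

FD indices are compared across treatments with the tie-corrected
Kruskal–Wallis test (χ² approximation, g−1 df). Post hoc pairs use the
Conover–Iman statistic on pooled ranks,
t = (R̄_i−R̄_j)/√(S²·(N−1−H)/(N−g)·(1/n_i+1/n_j)) with df = N−g, two-sided
p, Benjamini–Hochberg correction over all 10 treatment pairs per index,
and significance at α = 0.01. No installed Python package provides
Conover–Iman, so the statistic is implemented here and unit-checked
against the hand-evaluated rank formula.

Bioassay limitation calls: per-replicate growth g = ln(day4/day0)/4;
nutrient X is limiting when mean g(+X) exceeds mean g(control) in a
one-sided Welch test (default α = 0.05); N+P co-limitation is called when
only the combined addition responds. Note that the *joint* event
"N called and P not called" has success probability ≈ 1−α even at
overwhelming effect size, because spurious P calls occur at the test
level; recovery checks therefore evaluate the call at α = 0.01 (the
pipeline's post hoc significance threshold), while level calibration is
verified separately at α = 0.05.

## Field fingerprinting

The joint phenotype space standardises the pooled culture+field events
(log₁₀/z on the pooled set; a culture-anchored switch applies the culture
model unchanged) and fits one PCA on the concatenation. Each field
sample's centroid (mean score over the axes in use; samples under 10
events are skipped with a warning) is assigned to the Euclidean-nearest
treatment centroid, with exact ties broken by label order and flagged;
membership of each treatment's hypervolume (density ≥ threshold) is
reported alongside as the softer, region-based view. Gradient association
is Spearman's ρ between the TN:light covariate and each axis coordinate.

## Problem sizes and defaults

The orchestrated runs use 1,500–2,000 events per sample, 20 culture
samples and 28 field samples, n_perm = 199 for axis significance, and
m = 500·d support points per hypervolume — sizes at which every recovery
statistic in the test-suite is far from its decision boundary while a full
culture+field run completes in about a minute on one core. All stage
seeds derive from one master seed via `SeedSequence`, so reruns are
byte-identical.

## Known limitations

* The Silverman bandwidth assumes roughly Gaussian marginals; strongly
  multimodal scores get over-smoothed hypervolumes (visible as evenness
  compression between clumped and uniform cases).
* The volume estimator's small residual bias (threshold measured on data
  spread, not KDE spread) is common to all indices built from the same
  region and cancels in comparisons at equal n, but richness values at
  very different n are not exactly commensurable.
* Hypervolume membership of field centroids is reported, not used as the
  assignment rule; a centroid can be nearest to one treatment while lying
  inside none or several hypervolumes.
* The collinearity filter is greedy; with many candidates near the
  threshold the retained set depends on input order (deterministically).
* No compensation, doublet discrimination or time-drift correction is
  attempted; inputs are assumed pre-processed to clean event tables.
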