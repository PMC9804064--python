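# Methods

`microdyn` implements a source-space EEG microstate analysis operating on
parcel (region-of-interest) time courses — for example the 78 cortical
regions of an AAL parcellation — rather than on sensor topographies. The
package covers the full chain: synthetic cohort generation, GFP-peak
extraction, polarity-invariant modified k-means clustering with kneedle
model-order selection, backfitting, temporal/syntactic sequence
statistics including the Hurst exponent, microstate-segmented wPLI
connectivity with MVPA decoding, and two-group nonparametric comparison.

## Microstate model

A microstate is a quasi-stable spatial pattern of activity lasting tens
of milliseconds. The model assumes each sample's parcel vector x_t is,
up to amplitude and polarity, one of k prototype maps a_1..a_k:

    x_t ≈ ± GFP_t · a_{L_t} + noise,

with GFP_t the global field power (spatial standard deviation across
parcels) and L_t the per-sample label. Clustering is performed on the
spatial patterns at GFP peaks only, where topographic signal-to-noise
is maximal.

**Spatial correlation convention.** All analysis-side similarity is the
Pearson correlation across parcels (spatial mean removed), squared under
polarity invariance. Polarity invariance is on by default even in source
space, because parcel time courses obtained as first principal
components of region voxels carry arbitrary sign; `polarity_invariant=False`
is available for envelope-like inputs.

**Modified k-means.** Samples and centroids are spatially demeaned and
L2-normalised; assignment maximises squared correlation; the centroid
update is the first principal direction of the member maps. Because
GFP_t is the spatial SD of x_t, the global explained variance

    GEV = Σ_t (GFP_t · corr(x_t, a_{L_t}))² / Σ_t GFP_t²

decomposes over clusters into leading eigenvalues of the member scatter
matrices, so each update step is exactly optimal for GEV and the
iteration is monotone. Initialisation is k-means++-style seeding on
correlation distance (1 − corr²); uniform seeding was observed to hit
merged/split-state optima on large peak pools (~4·10^5 maps), ++-seeding
removes them in practice. Defaults: 20 restarts, tolerance 1e-6 on GEV
change, 500 iterations maximum; empty clusters are reseeded from the
worst-fit sample.

**Model order.** GEV is computed for k = 2..20 by independent fits and
the knee of the (normalised) GEV-vs-k curve is located with the kneedle
algorithm (sensitivity 1.0). If no local maximum of the difference curve
clears its threshold — e.g. a perfectly linear curve — `select_k` falls
back to the smallest k whose GEV increment drops below 1%.

**Backfitting.** GFP-peak samples take the centroid with minimal
distance 1 − corr²; every other sample inherits the label of the
temporally nearest peak (earlier peak on ties; terminal peaks extend to
the scan edges). No temporal smoothing or minimum-duration
post-processing is applied.

## Sequence statistics

Run-length encoding gives, per class: mean duration (ms), coverage
(fraction of samples) and occurrence (runs per second). Boundary runs
truncated by the scan edges are included by default (keeps the identity
occurrence·duration ≈ coverage tight); `include_boundary_runs=False`
excludes them. Syntax is defined on run transitions, so the k×k matrix
has a structurally zero diagonal; group-level syntax is the unweighted
mean of per-scan probability matrices, so long scans do not dominate.

**Hurst exponent.** Each bipartition of the label alphabet maps the
sequence to a ±1 series; the exponent is the slope of log F(s) vs log s
from order-1 detrended fluctuation analysis, averaged over all
2^(k−1)−1 bipartitions for k ≤ 8 (a seeded sample of 63 otherwise).
The default DFA window range is 500–40000 samples (2–160 s at 250 Hz,
clamped at a quarter of the sequence length). The lower end matters:
within a dwell the walk is ballistic (local slope ≈ 1.5 at small
windows) and the crossover extends to roughly 10–20 mean dwells, so
windows below ~0.5 s would measure the dwell length, not long-range
dependence. With the default range, memoryless semi-Markov sequences
read H ≈ 0.5 and fGn-modulated sequences (target 0.8) read H ≈ 0.67–0.71
at 600-s scans — the estimator compresses toward 0.5 because rank-mapped
occupancy drift transfers only part of the fGn autocorrelation into the
label walk.

**Non-random syntax.** The surrogate null preserves the run-label
multiset and shuffles order among arrangements with no two adjacent runs
equal. Uniform-permutation rejection sampling is infeasible here (a
permutation is adjacency-valid with probability ≈ exp(−R/k)), so each
surrogate is a uniform shuffle followed by local collision repair with
validity checks; type-I calibration of the resulting p-values is
verified in the test suite against exact null draws (run labels of a
uniform-transition chain, which conditional on their multiset are
exactly uniform over valid arrangements). p-values use the +1
correction, p = (1 + #{surrogate ≥ observed}) / (1 + n_surrogates), and
a two-sided variant doubles the smaller tail. With two labels every
arrangement alternates and all p-values are 1 by construction.

## State-segmented connectivity and MVPA

Per band (delta 1–4, theta 4–8, alpha 8–13, beta 13–30 Hz) the analytic
signal is obtained by zero-phase 4th-order Butterworth filtering and the
Hilbert transform. Samples of one state are concatenated in time order
(phase jumps at the seams accepted; a seam-dropping variant is a flag)
and chopped into non-overlapping 5-s windows; the residual tail is
dropped. Per window the weighted phase lag index

    wPLI_ij = |mean_t Im S_ij(t)| / mean_t |Im S_ij(t)|,  S_ij = z_i z_j*

is computed (original, non-debiased estimator; 0 where the denominator
vanishes, e.g. pure zero-lag coupling). Numerator and denominator are
kept separately so pooled matrices (per state, and the static background
over all windows) aggregate exactly.

**Amplitude confound in state-segmented decoding.** Even when the
underlying pairwise coupling is identical in every state, the state maps
themselves give each state a distinct spatial amplitude profile, and the
wPLI estimator's noise floor depends on the local signal-to-noise of
each parcel pair — so state identity leaks weakly into the connectivity
features through amplitude alone. Label-permutation MVPA correctly
detects this, which means above-chance decoding of microstate identity
from segmented connectivity does not by itself establish state-specific
coupling. The package's calibration tests therefore build their true
null with equal-magnitude sign-flip state maps (identical amplitude
profile in every state), for which permutation p-values are verified
uniform; with generic maps and identical coupling the rejection rate is
measurably above nominal (~10% at 0.05 for 600-s scans in our
simulations), quantifying the confound rather than a defect of the test.

Weighted-degree vectors (row sums) of the per-window matrices are the
MVPA features. The decoder is shrinkage LDA (Ledoit–Wolf, equivalent to
scikit-learn's `lsqr`/`auto` behind a standardiser, implemented directly
in NumPy so the permutation null stays cheap; multinomial logistic
regression is a config option), evaluated by stratified 5-fold
cross-validation. Significance comes from full CV re-runs under label
permutation with the +1-corrected p-value, so 1000 permutations bottom
out at p ≈ 0.001. A class with fewer windows than folds is an error —
callers should generate longer recordings rather than silently merging
classes. Edge-level reporting ranks all (state, edge) pairs by
|state wPLI − static wPLI| and returns the top fraction (default 1%),
ties broken lexicographically.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
with full ground truth:

- **Maps:** k unit-norm random parcel vectors, rejection-sampled until
  all pairwise |cosine| ≤ 0.5 (identifiability cap).
- **Sequences:** semi-Markov — run labels follow an embedded chain with
  zero-diagonal row-stochastic transition matrix (initial state from its
  stationary distribution); dwells are gamma draws (mean 100 ms,
  dispersion/shape 1.0 = exponential, truncated at 1 sample). Defaults
  emulate a 250-Hz, 600-s scan and a 27 + 57 two-group design.
- **Long-range dependence:** when a target Hurst exponent is set, each
  state's dwell draws are rank-mapped onto an independent fractional
  Gaussian noise series (exact Davies–Harte circulant embedding). The
  dwell marginals are unchanged while state occupancy acquires slow
  drift. Per-state modulation is essential: a single shared fGn scales
  all dwells together, cancels out of occupancy shares, and leaves the
  label walk memoryless — measured H was indistinguishable from the
  unmodulated case, while per-state modulation yields H ≈ 0.7 at
  target 0.8.
- **Rendering:** active map × rectified broadband (1–30 Hz) noise
  envelope (unit RMS, so GFP peaks arise naturally), plus optional
  state-conditional phase-lagged sinusoid pairs at band-centre
  frequencies (amplitude 3 × strength × per-parcel map RMS, so a
  strength-1 pair dominates the zero-lag map component and reaches
  wPLI ≥ 0.9), plus white noise (default SD 0.05 ≈ half the per-parcel
  map RMS at 78 parcels, i.e. spatial SNR ≈ 2), band-limited to 1–30 Hz.
- **Group differences:** multiplicative on dwell means and additive on
  transition-matrix logits.

What the generator does **not** emulate: anatomically realistic map
geometry, 1/f spectra and narrowband oscillatory bursts, source-leakage
correlations between parcels, artifacts, or inter-subject map
variability. Passing recovery tests therefore demonstrates correctness
of the estimators under the model's assumptions, not robustness to real
EEG's violations of them.

## Group comparison

Per-class duration/coverage/occurrence are compared between groups with
two-sided Wilcoxon rank-sum tests (exact enumeration when both n ≤ 10
and no ties; otherwise normal approximation with tie correction and
continuity correction). Benjamini–Hochberg FDR is applied within each
indicator's family of k class-wise tests; syntax cells form their own
family of k(k−1) tests. Raw and adjusted p-values are always both
reported; α = 0.05 throughout; Shapiro–Wilk normality p-values annotate
but never gate the nonparametric tests. Cohort summaries use chi-square
(Fisher exact for 2×2 tables with an expected cell below 5) for
categorical variables and Welch's t by default (rank-sum optional) for
continuous ones.

## Reproducibility and problem sizes

Every stochastic component takes a seed; the pipeline derives one seed
per stage from a master seed via `SeedSequence([master, stage_index])`,
so stages are independently reproducible and a rerun of the same
configuration is numerically identical. The test suite exercises the
full design at study scale — 84 scans × 600 s × 78 parcels, 5000 peaks
per scan pooled into 420,000 clustering samples — with reduced k-means
restarts (2–3, with ++-seeding) for the k = 2..20 scan; calibration
simulations use 20-parcel, 300–400-s scans, 100-permutation nulls and
200 repeats. These sizes were chosen to keep a complete run on one CPU
in the tens of minutes while leaving every statistical check
well-powered.

## Known limitations

- The Hurst estimator is scale-range dependent by nature; estimates from
  different window ranges are not comparable, and at 600-s scans the
  usable range tops out near 150 s.
- The surrogate shuffler is approximately, not exactly, uniform over
  adjacency-valid arrangements (verified well-calibrated, but extreme
  label imbalance could bias it; it errors out on degenerate multisets).
- MVPA pools windows across scans by default; scan identity is recorded
  but grouped cross-validation is left to the caller.
- `wilcoxon_ranksum` switches to the normal approximation in the
  presence of any ties, even at small n.
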