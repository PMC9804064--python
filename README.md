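# microdyn

Source-space EEG **microstate dynamics**: segmentation of parcel-level
brain activity into quasi-stable states, statistics of their temporal
organisation, and state-resolved functional connectivity. The package
targets the analysis design used to compare consciousness levels between
patient groups (e.g. minimally conscious vs vegetative state), but every
stage is generic: it consumes parcel × time matrices at any sampling
rate and group labels of any two-arm design.

Because clinical EEG cohorts of this kind are rarely shareable, the
package ships a first-class synthetic cohort generator with known ground
truth — planted spatial maps, semi-Markov state sequences with
controllable dwell times, syntax, long-range dependence, and
state-conditional phase-lagged coupling — so the entire pipeline is
testable end to end without any data download.

## The method

For parcel vectors x_t and k unit-norm prototype maps a_1..a_k, samples
at peaks of the global field power GFP_t (the spatial SD across parcels)
are clustered by polarity-invariant modified k-means, maximising the
global explained variance

    GEV = Σ_t (GFP_t · corr(x_t, a_{L_t}))² / Σ_t GFP_t² ,

where corr is spatial Pearson correlation and L_t the assigned state.
The model order k is the knee of the GEV-vs-k curve (kneedle algorithm,
k = 2..20). Labels are backfitted to whole scans via the nearest GFP
peak. From the label sequences the package computes per-class mean
duration, coverage and occurrence, the run-transition ("syntax") matrix
with a surrogate test for non-randomness, and the Hurst exponent of the
sequence (bipartition random-walk embedding + detrended fluctuation
analysis). Band-limited analytic signals (delta/theta/alpha/beta) are
segmented by state into 5-s windows; weighted-phase-lag-index (wPLI)
matrices per window yield weighted-degree features from which a
cross-validated linear decoder (shrinkage LDA) predicts the state
label, with a label-permutation null. Group contrasts use Wilcoxon
rank-sum tests with Benjamini–Hochberg FDR per indicator family.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
import numpy as np
from microdyn import (make_state_maps, SequenceParams, GroupSpec, iter_cohort_scans,
                      bandpass, gfp_trace, sample_peaks, scan_k, select_k, fit_kmeans,
                      backfit, class_stats, hurst_exponent, match_maps)

k = 5
T = np.full((k, k), 1 / (k - 1)); np.fill_diagonal(T, 0)
maps = make_state_maps(k, n_parcels=32, max_abs_corr=0.5, seed=1)
params = SequenceParams(transition_matrix=T, dwell_mean=100.0, duration_s=120.0, fs=250.0)
spec = GroupSpec(n_scans=(5, 5), params=params, maps=maps, noise_sd=0.05, seed=42)

rng = np.random.default_rng(0)
pool, scans = [], []
for scan, seq in iter_cohort_scans(spec):
    ts = bandpass(scan, 1.0, 30.0)
    trace = gfp_trace(ts)
    pool.append(ts.data[:, sample_peaks(trace.peak_indices, 2000, rng)].T)
    scans.append(ts)
pool = np.vstack(pool)
print(f"pooled peak maps: {pool.shape}")

curve = scan_k(pool, k_range=(2, 10), restarts=5, seed=0)
k_hat = select_k(curve)
print(f"selected k = {k_hat}")
model = fit_kmeans(pool, k_hat, restarts=10, seed=0)
_, corrs = match_maps(model.maps, maps.maps)
print(f"GEV = {model.gev:.3f}, mean |corr| to planted maps = {corrs.mean():.3f}")

seq_hat = backfit(scans[0], model, gfp_trace(scans[0]))
st = class_stats(seq_hat, k=k_hat)
print("mean duration (ms):", np.round(st.duration_ms, 1))
print("coverage:", np.round(st.coverage, 3))
print(f"Hurst exponent: {hurst_exponent(seq_hat):.3f}")
```

Output:

```
pooled peak maps: (20000, 32)
selected k = 5
GEV = 0.894, mean |corr| to planted maps = 0.989
mean duration (ms): [82.2 80.9 87.2 85.6 83.6]
coverage: [0.203 0.185 0.213 0.197 0.201]
Hurst exponent: 0.581
```

The knee of the GEV curve recovers the five planted states and the
fitted maps match the planted ones almost perfectly (|corr| 0.99).
Coverage is uniform as generated. Backfitted mean durations sit a little
below the generative 100 ms — occasional mislabelled peaks split runs in
two, a known bias of winner-take-all backfitting. The Hurst exponent of
a backfitted memoryless sequence reads just above 0.5.

A full run — simulate → prep → cluster → backfit → stats → connect →
compare, with per-stage artifacts, log and report — is one command:

```bash
microdyn run --out runs/demo --seed 7       # or: microdyn run --config config.yaml
```

Stage subcommands (`microdyn simulate|prep|cluster|backfit|stats|connect|compare`)
re-run individual stages against the same run directory.

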