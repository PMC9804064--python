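"""Synthetic parcel-space cohorts with planted microstate structure.

The patient recordings behind this kind of analysis are rarely shareable,
so every downstream stage is exercised against generated data whose
ground truth is known exactly. A scan is built in three layers:

1. a semi-Markov state sequence — dwell times drawn from a gamma
   distribution (mean/dispersion parameterised), successor states from a
   zero-diagonal row-stochastic transition matrix; optionally the dwell
   draws are rank-mapped onto fractional Gaussian noise to plant
   long-range dependence (target Hurst exponent in (0.5, 1));
2. a spatial rendering — the active state's unit-norm parcel map,
   amplitude-modulated by a rectified broadband envelope (so GFP peaks
   arise naturally), plus optional state-conditional narrowband
   phase-lagged parcel pairs (planting connectivity signatures), plus
   white noise; the sum is band-limited to 1-30 Hz;
3. a two-group cohort — group differences planted multiplicatively on
   dwell means and additively on transition-matrix logits, emulating a
   minimally-conscious vs vegetative-state contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .core import ParcelTimeSeries, StateSequence, default_parcel_labels

__all__ = [
    "StateMapSet",
    "SequenceParams",
    "Coupling",
    "GroupSpec",
    "Cohort",
    "fractional_gaussian_noise",
    "make_state_maps",
    "sample_state_sequence",
    "render_timeseries",
    "generate_cohort",
    "iter_cohort_scans",
    "BAND_EDGES",
]

# Canonical narrowband edges (Hz); shared with the connectivity module.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

_BROADBAND = (1.0, 30.0)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class StateMapSet:
    """k spatial state maps over parcels, unit L2 norm per map."""

    maps: np.ndarray  # (k, n_parcels)
    parcel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be (k, n_parcels)")
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("each map must have unit L2 norm (within 1e-9)")
        if not self.parcel_labels:
            self.parcel_labels = default_parcel_labels(self.maps.shape[1])
        if len(self.parcel_labels) != self.maps.shape[1]:
            raise ValueError("parcel label count mismatch")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.maps.shape[1]

    def pairwise_abs_corr(self) -> np.ndarray:
        """|cosine similarity| between distinct maps (diagonal zeroed)."""
        c = np.abs(self.maps @ self.maps.T)
        np.fill_diagonal(c, 0.0)
        return c


@dataclass
class SequenceParams:
    """Generative parameters of one semi-Markov label sequence.

    dwell_mean is in milliseconds per state; dwell_dispersion is the gamma
    shape parameter (1 = exponential/Markov dwells, larger = more peaked,
    quasi-stable dwells). target_hurst, when set, plants long-range
    dependence in the dwell series via fractional-Gaussian-noise rank
    mapping and must lie strictly inside (0.5, 1).
    """

    transition_matrix: np.ndarray  # (k, k), row-stochastic, zero diagonal
    dwell_mean: np.ndarray | float  # ms, per state or scalar
    dwell_dispersion: np.ndarray | float = 1.0
    target_hurst: float | None = None
    duration_s: float = 600.0
    fs: float = 250.0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        T = self.transition_matrix
        if T.ndim != 2 or T.shape[0] != T.shape[1] or T.shape[0] < 2:
            raise ValueError("transition_matrix must be square with k >= 2")
        if np.any(np.abs(np.diag(T)) > 0):
            raise ValueError("transition_matrix diagonal must be exactly 0")
        if np.any(T < 0):
            raise ValueError("transition probabilities must be nonnegative")
        rowsums = T.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            bad = np.flatnonzero(np.abs(rowsums - 1.0) > 1e-9)
            raise ValueError(
                f"rows {bad.tolist()} of transition_matrix do not sum to 1 "
                "(a zero row would make the state absorbing)"
            )
        k = T.shape[0]
        self.dwell_mean = np.broadcast_to(
            np.asarray(self.dwell_mean, dtype=float), (k,)
        ).copy()
        if np.any(self.dwell_mean <= 0):
            raise ValueError("dwell_mean must be positive")
        self.dwell_dispersion = np.broadcast_to(
            np.asarray(self.dwell_dispersion, dtype=float), (k,)
        ).copy()
        if np.any(self.dwell_dispersion <= 0):
            raise ValueError("dwell_dispersion must be positive")
        if self.target_hurst is not None and not (0.5 < self.target_hurst < 1.0):
            raise ValueError("target_hurst must lie in (0.5, 1)")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")

    @property
    def k(self) -> int:
        return self.transition_matrix.shape[0]

    def stationary_run_distribution(self) -> np.ndarray:
        """Stationary distribution of the embedded run-label chain."""
        T = self.transition_matrix
        vals, vecs = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def stationary_coverage(self) -> np.ndarray:
        """Expected time-coverage: run distribution weighted by dwell means."""
        pi = self.stationary_run_distribution()
        w = pi * self.dwell_mean
        return w / w.sum()


@dataclass(frozen=True)
class Coupling:
    """One planted phase-lagged parcel pair, active during one state."""

    state: int
    parcel_i: int
    parcel_j: int
    band: str = "alpha"
    phase_lag_rad: float = math.pi / 2
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.parcel_i == self.parcel_j:
            raise ValueError("coupling requires two distinct parcels")
        if self.band not in BAND_EDGES:
            raise ValueError(f"unknown band {self.band!r}; choose from {sorted(BAND_EDGES)}")
        if not (-math.pi < self.phase_lag_rad <= math.pi):
            raise ValueError("phase_lag_rad must lie in (-pi, pi]")
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("strength must lie in [0, 1]")


@dataclass
class GroupSpec:
    """Two-group cohort description with planted group differences."""

    n_scans: tuple[int, int]
    params: SequenceParams
    maps: StateMapSet
    group_names: tuple[str, str] = ("MCS", "VS")
    dwell_multipliers: tuple[float, float] = (1.0, 1.0)
    transition_logit_offsets: tuple[np.ndarray | None, np.ndarray | None] = (None, None)
    coupling: list[Coupling] = field(default_factory=list)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_scans) != 2 or min(self.n_scans) < 1:
            raise ValueError("n_scans must be two counts >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.maps.k != self.params.k:
            raise ValueError("maps and sequence params disagree on k")

    def group_params(self, which: int) -> SequenceParams:
        """Sequence parameters for group 0 or 1 with offsets applied."""
        p = self.params
        T = p.transition_matrix
        offset = self.transition_logit_offsets[which]
        if offset is not None:
            T = _offset_transition_logits(T, np.asarray(offset, dtype=float))
        return replace(
            p,
            transition_matrix=T,
            dwell_mean=p.dwell_mean * self.dwell_multipliers[which],
        )


def _offset_transition_logits(T: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Shift off-diagonal transition logits additively, renormalise rows."""
    if offset.shape != T.shape:
        raise ValueError("logit offset must match transition matrix shape")
    out = np.zeros_like(T)
    k = T.shape[0]
    off = ~np.eye(k, dtype=bool)
    with np.errstate(divide="ignore"):
        logits = np.where(off & (T > 0), np.log(np.maximum(T, 1e-300)), -np.inf)
    logits = logits + np.where(off, offset, 0.0)
    w = np.exp(logits)
    w[~off] = 0.0
    rowsum = w.sum(axis=1, keepdims=True)
    if np.any(rowsum == 0):
        raise ValueError("logit offsets removed all transitions from a row")
    out = w / rowsum
    return out


@dataclass
class Cohort:
    """Generated scans plus the full ground truth needed for recovery tests."""

    scans: list[ParcelTimeSeries]
    sequences: list[StateSequence]
    maps: StateMapSet
    manifest: dict


# --------------------------------------------------------------------------
# fractional Gaussian noise (Davies-Harte circulant embedding)
# --------------------------------------------------------------------------


def fractional_gaussian_noise(
    n: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact stationary fGn of length ``n`` with Hurst exponent ``hurst``.

    Uses circulant embedding of the fGn autocovariance
    ``gamma(h) = (|h+1|^{2H} - 2|h|^{2H} + |h-1|^{2H}) / 2``; the circulant
    eigenvalues are nonnegative for H in (0, 1), so the construction is
    exact up to floating point. Unit marginal variance.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    if n == 1:
        return rng.standard_normal(1)
    h2 = 2.0 * hurst
    k = np.arange(n, dtype=float)
    gamma = 0.5 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)
    # circulant first row: gamma_0..gamma_{n-1}, gamma_n, gamma_{n-1}..gamma_1
    gamma_n = 0.5 * ((n + 1.0) ** h2 - 2.0 * float(n) ** h2 + (n - 1.0) ** h2)
    c = np.concatenate([gamma, [gamma_n], gamma[:0:-1]])
    lam = np.fft.fft(c).real
    lam = np.clip(lam, 0.0, None)  # guards tiny negative rounding residues
    m = 2 * n
    v = np.empty(m, dtype=complex)
    v[0] = rng.standard_normal()
    v[n] = rng.standard_normal()
    re = rng.standard_normal(n - 1)
    im = rng.standard_normal(n - 1)
    v[1:n] = (re + 1j * im) / np.sqrt(2.0)
    v[n + 1 :] = np.conj(v[1:n][::-1])
    y = np.fft.fft(np.sqrt(lam) * v) / np.sqrt(m)
    return y[:n].real


# --------------------------------------------------------------------------
# state maps
# --------------------------------------------------------------------------


def make_state_maps(
    k: int,
    n_parcels: int,
    max_abs_corr: float = 0.5,
    seed: int | np.random.Generator = 0,
    max_tries_per_map: int = 5000,
) -> StateMapSet:
    """Rejection-sample k unit-norm maps with capped pairwise |similarity|.

    Similarity is the cosine between map vectors. ``max_abs_corr=0`` returns
    rows of a random orthogonal matrix (requires k <= n_parcels).
    """
    if k < 2:
        raise ValueError("need k >= 2 states")
    if k > n_parcels:
        raise ValueError(f"cannot place {k} identifiable maps in {n_parcels} parcels")
    if not (0.0 <= max_abs_corr <= 1.0):
        raise ValueError("max_abs_corr must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if max_abs_corr < 1e-12:
        q, _ = np.linalg.qr(rng.standard_normal((n_parcels, k)))
        return StateMapSet(maps=q.T[:k])
    accepted: list[np.ndarray] = []
    for _ in range(k):
        for attempt in range(max_tries_per_map):
            cand = rng.standard_normal(n_parcels)
            cand /= np.linalg.norm(cand)
            if all(abs(float(cand @ m)) <= max_abs_corr for m in accepted):
                accepted.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not satisfy |corr| <= {max_abs_corr} for map "
                f"{len(accepted) + 1}/{k} after {max_tries_per_map} tries"
            )
    return StateMapSet(maps=np.vstack(accepted))


# --------------------------------------------------------------------------
# semi-Markov state sequences
# --------------------------------------------------------------------------


def sample_state_sequence(
    params: SequenceParams, seed: int | np.random.Generator = 0
) -> StateSequence:
    """Draw one semi-Markov label sequence.

    Run labels follow the embedded chain (initial state from its
    stationary distribution); each run's dwell is a gamma draw with the
    state's mean/dispersion, rounded to samples and truncated at 1. When
    ``target_hurst`` is set, the gamma dwell draws are reordered by
    rank-mapping onto a fractional-Gaussian-noise series, which preserves
    the dwell marginals while planting long-range dependence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samples = int(round(params.duration_s * params.fs))
    mean_samples = params.dwell_mean / 1000.0 * params.fs  # per state
    expected_dwell = float(np.mean(mean_samples))
    n_runs = max(16, int(math.ceil(n_samples / expected_dwell * 1.4)) + 16)

    labels_runs = _sample_run_labels(params, n_runs, rng)
    dwells = _sample_dwells(params, labels_runs, rng)
    while dwells.sum() < n_samples:  # rare; extend and redraw dwell modulation
        n_runs = int(n_runs * 1.5) + 16
        labels_runs = _sample_run_labels(params, n_runs, rng)
        dwells = _sample_dwells(params, labels_runs, rng)

    labels = np.repeat(labels_runs, dwells)[:n_samples]
    return StateSequence(labels=labels, fs=params.fs, source="ground_truth")


def _sample_run_labels(
    params: SequenceParams, n_runs: int, rng: np.random.Generator
) -> np.ndarray:
    T = params.transition_matrix
    k = params.k
    cum = np.cumsum(T, axis=1)
    pi = params.stationary_run_distribution()
    labels = np.empty(n_runs, dtype=int)
    labels[0] = rng.choice(k, p=pi)
    u = rng.random(n_runs - 1)
    for r in range(1, n_runs):
        labels[r] = int(np.searchsorted(cum[labels[r - 1]], u[r - 1], side="right"))
    return labels


def _sample_dwells(
    params: SequenceParams, labels_runs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    mean_samples = params.dwell_mean / 1000.0 * params.fs
    shape = params.dwell_dispersion
    draws = rng.gamma(
        shape[labels_runs], mean_samples[labels_runs] / shape[labels_runs]
    )
    if params.target_hurst is not None:
        # Rank-map each state's dwell draws onto its own fGn series: dwell
        # *values* keep their gamma marginal while their temporal order
        # inherits the fGn's long-range autocorrelation. Per-state (rather
        # than shared) modulation is essential — a common slow scaling of
        # all dwells cancels out of state occupancy and leaves the label
        # walk memoryless, whereas independent per-state modulation makes
        # occupancy shares drift slowly, which is what the bipartition
        # random-walk picks up as H > 0.5.
        for c in range(params.k):
            idx = np.flatnonzero(labels_runs == c)
            if idx.size < 2:
                continue
            fgn = fractional_gaussian_noise(idx.size, params.target_hurst, rng)
            order = np.argsort(np.argsort(fgn))
            draws[idx] = np.sort(draws[idx])[order]
    dwells = np.maximum(1, np.rint(draws).astype(int))
    return dwells


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

# Coupling oscillation amplitude relative to the per-parcel RMS of the map
# signal; chosen so a strength-1 pair dominates the (zero-lag) map component
# on its two parcels and yields wPLI near 1 at moderate noise.
_COUPLING_GAIN = 3.0


def render_timeseries(
    seq: StateSequence,
    maps: StateMapSet,
    coupling: list[Coupling] | None = None,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
    band: tuple[float, float] = _BROADBAND,
    scan_id: str = "",
    group: str = "NA",
) -> ParcelTimeSeries:
    """Render a labelled sequence into parcel time courses.

    signal(t) = envelope(t) * map[label(t)]
              + state-conditional phase-lagged narrowband pairs
              + white noise,   then band-limited to ``band`` (1-30 Hz).

    The envelope is rectified band-limited noise normalised to unit RMS,
    so the global field power fluctuates and has natural peaks. With
    unit-norm maps the per-parcel map-signal RMS is about
    ``1/sqrt(n_parcels)``; ``noise_sd`` is on the same amplitude scale.
    """
    if coupling is None:
        coupling = []
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if seq.labels.max() >= maps.k:
        raise ValueError(
            f"sequence uses label {int(seq.labels.max())} but maps define only {maps.k} states"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = seq.fs
    n = seq.n_samples
    p = maps.n_parcels

    sos = _signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    envelope = np.abs(_signal.sosfiltfilt(sos, rng.standard_normal(n)))
    envelope /= np.sqrt(np.mean(envelope**2))

    data = maps.maps[seq.labels].T * envelope  # (p, n)

    if coupling:
        t = np.arange(n) / fs
        parcel_rms = 1.0 / np.sqrt(p)
        for c in coupling:
            lo, hi = BAND_EDGES[c.band]
            f0 = 0.5 * (lo + hi)
            phase0 = rng.uniform(0.0, 2.0 * math.pi)
            amp = _COUPLING_GAIN * c.strength * parcel_rms
            mask = seq.labels == c.state
            if not mask.any():
                continue
            ph = 2.0 * math.pi * f0 * t + phase0
            data[c.parcel_i, mask] += amp * np.cos(ph[mask])
            data[c.parcel_j, mask] += amp * np.cos(ph[mask] - c.phase_lag_rad)

    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal((p, n))

    data = _signal.sosfiltfilt(sos, data, axis=-1)
    return ParcelTimeSeries(
        data=data,
        fs=fs,
        parcel_labels=list(maps.parcel_labels),
        scan_id=scan_id,
        group=group,
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


def _scan_seed_sequences(spec: GroupSpec) -> list[tuple[str, str, np.random.SeedSequence]]:
    """Deterministic (scan_id, group, seed) triples for every scan."""
    total = sum(spec.n_scans)
    children = np.random.SeedSequence(spec.seed).spawn(total)
    out = []
    idx = 0
    for g, n in zip(spec.group_names, spec.n_scans):
        for i in range(n):
            out.append((f"{g}_{i:03d}", g, children[idx]))
            idx += 1
    return out


def cohort_manifest(spec: GroupSpec) -> dict:
    """Scan bookkeeping (ids, groups, per-scan seeds) without rendering."""
    entries = [
        {"scan_id": sid, "group": g, "seed_entropy": int(ss.entropy)}
        for sid, g, ss in _scan_seed_sequences(spec)
    ]
    return {
        "n_scans": list(spec.n_scans),
        "group_names": list(spec.group_names),
        "fs": spec.params.fs,
        "duration_s": spec.params.duration_s,
        "k": spec.maps.k,
        "n_parcels": spec.maps.n_parcels,
        "noise_sd": spec.noise_sd,
        "dwell_multipliers": list(spec.dwell_multipliers),
        "seed": spec.seed,
        "scans": entries,
    }


def iter_cohort_scans(spec: GroupSpec, render: bool = True):
    """Yield (scan, sequence) pairs one at a time (memory-bounded).

    With ``render=False`` the scan slot is ``None`` and only label
    sequences are produced — enough for sequence-statistics work at a
    fraction of the cost.
    """
    for sid, g, ss in _scan_seed_sequences(spec):
        which = spec.group_names.index(g)
        gp = spec.group_params(which)
        rng = np.random.default_rng(ss)
        seq = sample_state_sequence(gp, rng)
        seq.scan_id, seq.group = sid, g
        scan = None
        if render:
            scan = render_timeseries(
                seq,
                spec.maps,
                coupling=spec.coupling,
                noise_sd=spec.noise_sd,
                seed=rng,
                scan_id=sid,
                group=g,
            )
        yield scan, seq


def generate_cohort(spec: GroupSpec, out_dir=None, render: bool = True) -> Cohort:
    """Materialise a full cohort; optionally write scans + manifest to disk.

    Returns the scans in memory — for long recordings prefer
    :func:`iter_cohort_scans`. The manifest and ground-truth bundle
    (maps, per-scan generative parameters) are returned and, when
    ``out_dir`` is given, written alongside the data.
    """
    from . import io as _io  # local import to keep module load light

    manifest = cohort_manifest(spec)
    scans: list[ParcelTimeSeries] = []
    seqs: list[StateSequence] = []
    for scan, seq in iter_cohort_scans(spec, render=render):
        if scan is not None:
            scans.append(scan)
        seqs.append(seq)

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for scan in scans:
            _io.write_scan(scan, out / f"{scan.scan_id}.tsv")
        _io.write_json(manifest, out / "manifest.json")
        truth = {
            "maps": spec.maps.maps,
            "parcel_labels": spec.maps.parcel_labels,
            "transition_matrix": spec.params.transition_matrix,
            "dwell_mean_ms": spec.params.dwell_mean,
            "dwell_dispersion": spec.params.dwell_dispersion,
            "target_hurst": spec.params.target_hurst,
            "dwell_multipliers": list(spec.dwell_multipliers),
            "sequences": {s.scan_id: s.labels for s in seqs},
        }
        _io.write_json(truth, out / "ground_truth.json")
    return Cohort(scans=scans, sequences=seqs, maps=spec.maps, manifest=manifest)
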