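"""Temporal and syntactic statistics of microstate label sequences.

Covers the per-class indicators (mean duration, coverage, occurrence),
the run-transition ("syntax") matrix, the Hurst exponent of the label
sequence (random-walk embedding + detrended fluctuation analysis), and
a surrogate test for non-random syntax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .core import StateSequence

__all__ = [
    "SequenceStats",
    "SyntaxMatrix",
    "run_length_encode",
    "run_length_decode",
    "class_stats",
    "transition_matrix",
    "group_syntax",
    "hurst_exponent",
    "dfa",
    "syntax_surrogate_test",
    "SyntaxTestResult",
]


@dataclass
class SequenceStats:
    """Per-class and global sequence indicators.

    duration_ms[c] is the mean uninterrupted dwell of class c (NaN when
    the class never occurs; ``present`` flags it); coverage is the
    fraction of samples, occurrence the number of class onsets per
    second.
    """

    duration_ms: np.ndarray
    coverage: np.ndarray
    occurrence: np.ndarray
    present: np.ndarray
    global_mean_duration_ms: float
    n_runs: int
    fs: float

    @property
    def k(self) -> int:
        return self.duration_ms.size


@dataclass
class SyntaxMatrix:
    """Run-transition counts and row-normalised probabilities (zero diagonal)."""

    probs: np.ndarray
    counts: np.ndarray
    n_transitions: int
    empty_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.counts = np.asarray(self.counts)
        k = self.probs.shape[0]
        if self.probs.shape != (k, k) or self.counts.shape != (k, k):
            raise ValueError("probs and counts must be square and matched")
        if np.any(np.abs(np.diag(self.probs)) > 0):
            raise ValueError("diagonal must be zero (self-transitions impossible)")
        if self.empty_rows.size == 0:
            self.empty_rows = self.counts.sum(axis=1) == 0
        rs = self.probs.sum(axis=1)
        if np.any(np.abs(rs[~self.empty_rows] - 1.0) > 1e-9):
            raise ValueError("non-empty rows must sum to 1")

    @property
    def k(self) -> int:
        return self.probs.shape[0]


def _labels_of(seq: StateSequence | np.ndarray) -> np.ndarray:
    return seq.labels if isinstance(seq, StateSequence) else np.asarray(seq, dtype=int)


def run_length_encode(seq: StateSequence | np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (label, start, length) triples."""
    labels = _labels_of(seq)
    if labels.size == 0:
        raise ValueError("empty sequence")
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(labels[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def run_length_decode(runs: list[tuple[int, int, int]]) -> np.ndarray:
    return np.concatenate([np.full(length, label, dtype=int) for label, _, length in runs])


def class_stats(
    seq: StateSequence, k: int | None = None, include_boundary_runs: bool = True
) -> SequenceStats:
    """Duration / coverage / occurrence per class plus the global mean dwell.

    duration_c = mean run length of class c * 1000 / fs (ms)
    coverage_c = samples in class c / total samples
    occurrence_c = runs of class c / scan length in seconds

    Boundary runs (truncated by the scan edges) are included by default;
    ``include_boundary_runs=False`` drops the first and last run from the
    duration and occurrence tallies (coverage always uses all samples).
    """
    labels = seq.labels
    if k is None:
        k = int(labels.max()) + 1
    if labels.max() >= k:
        raise ValueError(f"label {int(labels.max())} out of range for k={k}")
    runs = run_length_encode(seq)
    n_samples = labels.size
    dur_runs = runs if include_boundary_runs or len(runs) <= 2 else runs[1:-1]

    counts = np.bincount(labels, minlength=k)
    coverage = counts / n_samples

    run_labels = np.array([r[0] for r in dur_runs], dtype=int)
    run_lengths = np.array([r[2] for r in dur_runs], dtype=float)
    n_runs_c = np.bincount(run_labels, minlength=k).astype(float)
    sum_len_c = np.bincount(run_labels, weights=run_lengths, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        duration_ms = sum_len_c / n_runs_c * 1000.0 / seq.fs
    present = counts > 0
    duration_ms[n_runs_c == 0] = np.nan

    scan_seconds = n_samples / seq.fs
    occurrence = n_runs_c / scan_seconds
    global_mean = float(run_lengths.mean() * 1000.0 / seq.fs)
    return SequenceStats(
        duration_ms=duration_ms,
        coverage=coverage,
        occurrence=occurrence,
        present=present,
        global_mean_duration_ms=global_mean,
        n_runs=len(dur_runs),
        fs=seq.fs,
    )


def transition_matrix(seq: StateSequence | np.ndarray, k: int | None = None) -> SyntaxMatrix:
    """Run-label transition counts and probabilities (self-transitions impossible)."""
    runs = run_length_encode(seq)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to count transitions")
    run_labels = np.array([r[0] for r in runs], dtype=int)
    if k is None:
        k = int(run_labels.max()) + 1
    return _matrix_from_run_labels(run_labels, k)


def _matrix_from_run_labels(run_labels: np.ndarray, k: int) -> SyntaxMatrix:
    src, dst = run_labels[:-1], run_labels[1:]
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (src, dst), 1)
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(rowsum > 0, counts / np.maximum(rowsum, 1), 0.0)
    return SyntaxMatrix(probs=probs, counts=counts, n_transitions=int(src.size))


def group_syntax(matrices: list[SyntaxMatrix]) -> SyntaxMatrix:
    """Group-level syntax: unweighted mean of per-scan probability matrices."""
    if not matrices:
        raise ValueError("no matrices")
    k = matrices[0].k
    if any(m.k != k for m in matrices):
        raise ValueError("all syntax matrices must share k")
    probs = np.mean([m.probs for m in matrices], axis=0)
    counts = np.sum([m.counts for m in matrices], axis=0)
    empty = np.any([m.empty_rows for m in matrices], axis=0)
    # rows touched by an empty constituent matrix do not average to 1
    rowsum = probs.sum(axis=1)
    probs[~empty] /= rowsum[~empty, None]
    out = SyntaxMatrix(
        probs=probs,
        counts=counts,
        n_transitions=int(sum(m.n_transitions for m in matrices)),
        empty_rows=empty,
    )
    return out


# --------------------------------------------------------------------------
# Hurst exponent via bipartition random-walk embedding + DFA
# --------------------------------------------------------------------------


DEFAULT_SCALE_RANGE = (500, 40000)
"""Default DFA window range in samples (2-160 s at 250 Hz).

Microstate label walks are ballistic within a dwell and for a long
crossover beyond it; windows must sit well above the mean dwell
(~10-100 ms, i.e. tens of samples) for the fitted exponent to reflect
long-range dependence rather than the dwell itself. The upper end is
clamped to a quarter of the sequence length.
"""


def dfa(
    x: np.ndarray,
    scale_range: tuple[int, int] = DEFAULT_SCALE_RANGE,
    n_scales: int = 12,
) -> float:
    """Detrended fluctuation analysis (order-1) scaling exponent.

    The profile (cumulative sum of the mean-removed series) is divided
    into non-overlapping windows at each of ``n_scales`` log-spaced
    scales; a linear trend is removed per window and the RMS fluctuation
    F(s) recorded. The exponent is the slope of log F against log s.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = scale_range
    hi = min(hi, x.size // 4)
    if hi <= lo:
        raise ValueError("series too short for the requested scales")
    if np.ptp(x) == 0:
        raise ValueError("constant series: fluctuation undefined")
    profile = np.cumsum(x - x.mean())
    scales = np.unique(
        np.round(np.exp(np.linspace(np.log(lo), np.log(hi), n_scales))).astype(int)
    )
    flucts = np.empty(scales.size)
    for si, s in enumerate(scales):
        m = profile.size // s
        seg = profile[: m * s].reshape(m, s)
        t = np.arange(s, dtype=float)
        t = t - t.mean()
        denom = float(t @ t)
        seg_mean = seg.mean(axis=1, keepdims=True)
        slope = (seg @ t)[:, None] / denom
        resid = seg - seg_mean - slope * t
        flucts[si] = np.sqrt(np.mean(resid**2))
    valid = flucts > 0
    if valid.sum() < 3:
        raise ValueError("not enough valid scales for a log-log fit")
    h, _ = np.polyfit(np.log(scales[valid]), np.log(flucts[valid]), 1)
    return float(h)


def _bipartitions(k: int, max_full_k: int, n_sample: int, rng: np.random.Generator):
    """Nonempty proper subsets containing label 0 (one per complement pair)."""
    all_parts = []
    for size in range(1, k):
        for rest in combinations(range(1, k), size - 1):
            all_parts.append(frozenset((0, *rest)))
    if k <= max_full_k or len(all_parts) <= n_sample:
        return all_parts
    idx = rng.choice(len(all_parts), size=n_sample, replace=False)
    return [all_parts[i] for i in idx]


def hurst_exponent(
    seq: StateSequence | np.ndarray,
    k: int | None = None,
    scale_range: tuple[int, int] = DEFAULT_SCALE_RANGE,
    n_scales: int = 12,
    n_bipartitions: int = 63,
    max_full_k: int = 8,
    seed: int = 0,
) -> float:
    """Hurst exponent of a label sequence.

    Each bipartition of the label alphabet maps the sequence to a +/-1
    series whose DFA exponent is computed; the estimate is the mean over
    all 2^(k-1)-1 bipartitions (k <= ``max_full_k``) or a seeded sample
    of ``n_bipartitions`` of them. 0.5 indicates a memoryless sequence,
    values above 0.5 long-range temporal dependence.
    """
    labels = _labels_of(seq)
    if k is None:
        k = int(labels.max()) + 1
    if k < 2:
        raise ValueError("Hurst exponent undefined for a single-state sequence")
    if labels.size < 10 * scale_range[0]:
        raise ValueError("sequence too short for the requested scale range")
    rng = np.random.default_rng(seed)
    parts = _bipartitions(k, max_full_k, n_bipartitions, rng)
    estimates = []
    for part in parts:
        mask = np.isin(labels, list(part))
        x = np.where(mask, 1.0, -1.0)
        if np.ptp(x) == 0:
            continue  # bipartition never visited on one side
        estimates.append(dfa(x, scale_range=scale_range, n_scales=n_scales))
    if not estimates:
        raise ValueError("constant sequence: Hurst exponent undefined")
    return float(np.mean(estimates))


# --------------------------------------------------------------------------
# non-random syntax surrogate test
# --------------------------------------------------------------------------


@dataclass
class SyntaxTestResult:
    """Per-cell surrogate p-values for the observed transition probabilities."""

    observed: SyntaxMatrix
    p_greater: np.ndarray  # upper tail: observed prob unusually high
    p_two_sided: np.ndarray
    n_surrogates: int


def _shuffle_no_adjacent(
    run_labels: np.ndarray, rng: np.random.Generator, max_tries: int
) -> np.ndarray:
    """Uniform-ish shuffle of the run-label multiset with no adjacent equals.

    Plain rejection sampling is infeasible here — for R runs over k
    roughly balanced labels a uniform permutation is adjacency-valid with
    probability ~exp(-R/k), astronomically small at realistic R. Instead
    each attempt shuffles uniformly and then repairs the few collisions
    by swapping a colliding run with a randomly chosen position where the
    swap removes the collision without creating new ones; attempts whose
    repair stalls are rejected wholesale. The repair step perturbs exact
    uniformity only slightly (collisions are O(R/k) and the repair target
    is chosen uniformly among valid positions); the surrogate null stays
    calibrated (see the type-I tests).
    """
    n = run_labels.size

    def locally_valid(arr, pos):
        if pos > 0 and arr[pos] == arr[pos - 1]:
            return False
        if pos + 1 < n and arr[pos] == arr[pos + 1]:
            return False
        return True

    for _ in range(max_tries):
        out = rng.permutation(run_labels)
        ok = True
        for _repair in range(4 * n):
            bad = np.flatnonzero(out[1:] == out[:-1])
            if bad.size == 0:
                break
            i = int(bad[0]) + 1  # out[i] collides with out[i-1]
            for j in rng.permutation(n):
                if out[j] == out[i]:
                    continue
                out[i], out[j] = out[j], out[i]
                if locally_valid(out, i) and locally_valid(out, j):
                    break
                out[i], out[j] = out[j], out[i]
            else:
                ok = False
                break
        else:
            ok = False
        if ok and np.all(out[1:] != out[:-1]):
            return out
    raise RuntimeError(
        "could not draw an adjacent-distinct shuffle of the run labels; "
        "the label multiset is too degenerate for the surrogate null"
    )


def syntax_surrogate_test(
    seq: StateSequence | np.ndarray,
    n_surrogates: int = 1000,
    seed: int = 0,
    k: int | None = None,
    max_tries: int = 500,
) -> SyntaxTestResult:
    """Surrogate test of non-random syntax.

    The null preserves the multiset of run labels but shuffles their
    order among arrangements with no two adjacent runs equal (shuffle
    plus collision repair; see :func:`_shuffle_no_adjacent`). For each
    off-diagonal cell,
    p = (1 + #{surrogate prob >= observed prob}) / (1 + n_surrogates);
    the two-sided value doubles the smaller tail, capped at 1.

    With only two distinct labels every arrangement alternates, the null
    coincides with the data, and all p-values are 1.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    runs = run_length_encode(seq)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    run_labels = np.array([r[0] for r in runs], dtype=int)
    if k is None:
        k = int(run_labels.max()) + 1
    observed = _matrix_from_run_labels(run_labels, k)

    if np.unique(run_labels).size <= 2:
        ones = np.ones((k, k))
        np.fill_diagonal(ones, 0.0)
        return SyntaxTestResult(
            observed=observed,
            p_greater=ones.copy(),
            p_two_sided=ones.copy(),
            n_surrogates=n_surrogates,
        )

    rng = np.random.default_rng(seed)
    ge = np.zeros((k, k), dtype=int)
    le = np.zeros((k, k), dtype=int)
    for _ in range(n_surrogates):
        surr = _shuffle_no_adjacent(run_labels, rng, max_tries)
        sp = _matrix_from_run_labels(surr, k).probs
        ge += sp >= observed.probs
        le += sp <= observed.probs
    p_hi = (1.0 + ge) / (1.0 + n_surrogates)
    p_lo = (1.0 + le) / (1.0 + n_surrogates)
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    off = ~np.eye(k, dtype=bool)
    p_hi[~off] = 1.0
    p_two[~off] = 1.0
    return SyntaxTestResult(
        observed=observed, p_greater=p_hi, p_two_sided=p_two, n_surrogates=n_surrogates
    )
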