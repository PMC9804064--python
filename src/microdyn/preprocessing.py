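"""Conditioning of parcel time courses and GFP-peak extraction.

The clustering stage does not see whole recordings: it sees the spatial
patterns at peaks of the global field power (GFP), the moments of
maximal topographic signal-to-noise. This module provides the 1-30 Hz
band-pass, the GFP trace, strict local-maximum peak detection, and the
seeded random subsampling of peaks used to build the pooled clustering
set (5000 peaks per scan by default).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .core import GfpTrace, ParcelTimeSeries

__all__ = ["bandpass", "compute_gfp", "detect_peaks", "sample_peaks", "gfp_trace"]


def bandpass(
    ts: ParcelTimeSeries, lo: float, hi: float, order: int = 4
) -> ParcelTimeSeries:
    """Zero-phase Butterworth band-pass of every parcel time course.

    A 4th-order Butterworth is applied forward and backward
    (``sosfiltfilt``), doubling the effective order and cancelling phase
    distortion. ``hi`` must stay below the Nyquist frequency.
    """
    nyq = ts.fs / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=ts.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=-1)
    return ParcelTimeSeries(
        data=filtered,
        fs=ts.fs,
        parcel_labels=list(ts.parcel_labels),
        scan_id=ts.scan_id,
        group=ts.group,
    )


def compute_gfp(ts: ParcelTimeSeries | np.ndarray, demean: bool = True) -> np.ndarray:
    """Global field power: per-sample spatial standard deviation.

    With ``demean=True`` (default) the spatial mean is removed at each
    sample before taking the RMS, i.e. GFP(t) = population SD over
    parcels — the sensor-space convention carried over to parcel space.
    ``demean=False`` gives the plain spatial RMS.
    """
    data = ts.data if isinstance(ts, ParcelTimeSeries) else np.asarray(ts, dtype=float)
    if demean:
        return data.std(axis=0, ddof=0)
    return np.sqrt(np.mean(data**2, axis=0))


def detect_peaks(gfp_values: np.ndarray) -> np.ndarray:
    """Strict local maxima of a 1-D trace.

    A sample i is a peak when values[i-1] < values[i] > values[i+1].
    Plateaus (runs of equal values higher than both neighbours) count as
    one peak at the leftmost plateau sample. Endpoints are never peaks.
    """
    v = np.asarray(gfp_values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a 1-D trace of length >= 3")
    # A (plateau) peak is a rise immediately followed — across any run of
    # equal values — by a fall. Consecutive nonzero slope signs with the
    # pattern (+, -) bracket exactly one peak, at the first plateau sample.
    sign = np.sign(np.diff(v))
    nz = np.flatnonzero(sign)
    if nz.size < 2:
        return np.array([], dtype=int)
    a, b = nz[:-1], nz[1:]
    starts = a[(sign[a] > 0) & (sign[b] < 0)] + 1
    return starts.astype(int)


def gfp_trace(ts: ParcelTimeSeries, demean: bool = True) -> GfpTrace:
    """GFP values plus detected peaks in one container."""
    values = compute_gfp(ts, demean=demean)
    return GfpTrace(values=values, peak_indices=detect_peaks(values))


def sample_peaks(
    peak_indices: np.ndarray, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Uniform sample without replacement of ``min(n, available)`` peaks.

    Returned sorted ascending. A scan with fewer than ``n`` peaks
    contributes all of them (with a warning) so cohort totals stay
    well-defined.
    """
    peaks = np.asarray(peak_indices, dtype=int)
    if n < 1:
        raise ValueError("n must be >= 1")
    if peaks.size == 0:
        raise ValueError("no peaks to sample from")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if peaks.size <= n:
        if peaks.size < n:
            warnings.warn(
                f"requested {n} peaks but only {peaks.size} available; using all",
                stacklevel=2,
            )
        return np.sort(peaks)
    chosen = rng.choice(peaks, size=n, replace=False)
    return np.sort(chosen)
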