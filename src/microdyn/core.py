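"""Shared containers for parcel-space microstate analysis.

The pipeline operates on region-of-interest ("parcel") time courses —
one broadband source-reconstructed signal per cortical region — rather
than on sensor-space EEG. All containers are thin dataclasses around
numpy arrays; shapes are validated at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParcelTimeSeries", "GfpTrace", "StateSequence", "default_parcel_labels"]


def default_parcel_labels(n_parcels: int) -> list[str]:
    """Placeholder region names (``ROI_00`` ...) when none are supplied."""
    width = max(2, len(str(n_parcels - 1)))
    return [f"ROI_{i:0{width}d}" for i in range(n_parcels)]


@dataclass
class ParcelTimeSeries:
    """Parcel-space recording: ``data`` is (n_parcels, n_samples).

    Parameters
    ----------
    data : ndarray
        Real matrix of shape (n_parcels, n_samples), arbitrary amplitude
        units. No missing values allowed.
    fs : float
        Sampling rate in Hz.
    parcel_labels : list of str
        One name per parcel (e.g. cortical AAL region names).
    scan_id : str
        Identifier of the recording.
    group : str
        Cohort label; one of ``{"MCS", "VS", "NA"}`` by convention, but any
        string is accepted so the pipeline generalises to other designs.
    """

    data: np.ndarray
    fs: float
    parcel_labels: list[str] = field(default_factory=list)
    scan_id: str = ""
    group: str = "NA"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (parcels x samples), got ndim={self.data.ndim}")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 parcels")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.parcel_labels:
            self.parcel_labels = default_parcel_labels(self.data.shape[0])
        if len(self.parcel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.parcel_labels)} parcel labels for {self.data.shape[0]} parcels"
            )

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GfpTrace:
    """Global field power trace with detected peak locations.

    ``values[t]`` is the spatial standard deviation across parcels at
    sample ``t``; ``peak_indices`` are strict local maxima of the trace
    (endpoints excluded, plateaus resolved to their leftmost sample).
    """

    values: np.ndarray
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.values.ndim != 1:
            raise ValueError("GFP values must be 1-D")
        if np.any(self.values < -1e-12):
            raise ValueError("GFP values must be nonnegative")
        if self.peak_indices.size:
            if np.any(np.diff(self.peak_indices) <= 0):
                raise ValueError("peak indices must be strictly increasing")
            if self.peak_indices[0] < 0 or self.peak_indices[-1] >= self.values.size:
                raise ValueError("peak indices out of range")


@dataclass
class StateSequence:
    """Per-sample microstate labels for one scan.

    ``labels`` holds an integer state in ``[0, k)`` for every sample.
    ``source`` records whether the labels are generator ground truth or
    the result of backfitting a clustering model.
    """

    labels: np.ndarray
    fs: float
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    source: str = "ground_truth"
    scan_id: str = ""
    group: str = "NA"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D integer array")
        if np.any(self.labels < 0):
            raise ValueError("labels must be nonnegative")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if self.source not in ("ground_truth", "backfit"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_states_seen(self) -> int:
        return int(self.labels.max()) + 1
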