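"""Polarity-invariant modified k-means microstate clustering.

Spatial patterns at GFP peaks are clustered into k centroid maps with
the modified (topographic) k-means of the microstate literature:
assignment maximises squared spatial correlation between a sample map
and a centroid (so a map and its sign-flip are the same state), and the
centroid update is the first principal direction of the member maps.
Model order is chosen by scanning k and locating the knee of the global
explained variance (GEV) curve with the kneedle algorithm; the chosen
model is then backfitted to whole scans via their GFP peaks.

Spatial correlation is the Pearson correlation across parcels (spatial
mean removed), matching the GFP convention; centroids are stored as
zero-mean, unit-norm map vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import GfpTrace, ParcelTimeSeries, StateSequence

__all__ = [
    "MicrostateModel",
    "GevCurve",
    "fit_kmeans",
    "compute_gev",
    "scan_k",
    "kneedle",
    "backfit",
    "match_maps",
]

log = logging.getLogger(__name__)


@dataclass
class MicrostateModel:
    """Fitted microstate centroids plus diagnostics."""

    maps: np.ndarray  # (k, n_parcels), zero-mean unit-norm rows
    k: int
    polarity_invariant: bool = True
    gev: float = float("nan")
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] != self.k:
            raise ValueError("maps must be (k, n_parcels)")
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("centroid rows must be unit-norm")
        if not (np.isnan(self.gev) or 0.0 <= self.gev <= 1.0 + 1e-12):
            raise ValueError("gev must lie in [0, 1]")


@dataclass
class GevCurve:
    """GEV as a function of model order k, with the selected knee."""

    k_values: np.ndarray
    gev_values: np.ndarray
    knee: int | None = None

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.gev_values = np.asarray(self.gev_values, dtype=float)
        if self.k_values.size != self.gev_values.size:
            raise ValueError("k and GEV arrays must align")
        if np.any(np.diff(self.k_values) <= 0):
            raise ValueError("k values must be increasing")
        if np.any((self.gev_values < -1e-12) | (self.gev_values > 1 + 1e-12)):
            raise ValueError("GEV values must lie in [0, 1]")


# --------------------------------------------------------------------------
# internals
# --------------------------------------------------------------------------


def _demean_rows(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def _principal_direction(scatter: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector/eigenvalue of a symmetric scatter matrix."""
    vals, vecs = np.linalg.eigh(scatter)
    return vecs[:, -1], float(vals[-1])


def _plusplus_init(
    Xn: np.ndarray, k: int, rng: np.random.Generator, polarity_invariant: bool
) -> np.ndarray:
    """k-means++-style seeding on correlation distance.

    The first centroid is a random sample; each further centroid is a
    sample drawn with probability proportional to its distance
    (1 - corr^2 under polarity invariance) from the nearest centroid so
    far. Greatly reduces merged/split-state local optima compared with
    uniform seeding on large peak pools.
    """
    m = Xn.shape[0]
    idx = [int(rng.integers(m))]
    dist = np.full(m, np.inf)
    for _ in range(1, k):
        proj = Xn @ Xn[idx[-1]]
        d = 1.0 - proj**2 if polarity_invariant else 1.0 - proj
        np.minimum(dist, d, out=dist)
        w = np.clip(dist, 0.0, None)
        total = float(w.sum())
        if total <= 0:
            idx.append(int(rng.integers(m)))
            continue
        idx.append(int(rng.choice(m, p=w / total)))
    return Xn[idx].copy()


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def fit_kmeans(
    peak_maps: np.ndarray,
    k: int,
    restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | np.random.Generator = 0,
    polarity_invariant: bool = True,
) -> MicrostateModel:
    """Modified k-means on peak maps; best of ``restarts`` runs by GEV.

    The objective is the global explained variance
    GEV = sum_t (GFP_t * corr(x_t, a_{L_t}))^2 / sum_t GFP_t^2
    with Pearson spatial correlation; under polarity invariance the
    assignment maximises corr^2. Because GFP_t is the spatial SD of x_t,
    the per-cluster optimal centroid is the first principal direction of
    the member maps (spatially demeaned), and the cluster's GEV
    contribution is the corresponding leading eigenvalue.
    """
    X = np.asarray(peak_maps, dtype=float)
    if X.ndim != 2:
        raise ValueError("peak_maps must be (m, n_parcels)")
    m, p = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if m < k:
        raise ValueError(f"cannot fit {k} states to {m} samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Xd = _demean_rows(X)
    sqnorm = np.einsum("ij,ij->i", Xd, Xd)  # = p * GFP_t^2
    denom = float(sqnorm.sum())
    if denom <= 0:
        raise ValueError("all peak maps are spatially constant")
    Xn = _normalize_rows(Xd).astype(X.dtype, copy=False)

    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for restart in range(restarts):
        C = _plusplus_init(Xn, k, rng, polarity_invariant)
        prev_gev = -np.inf
        labels = np.zeros(m, dtype=int)
        for it in range(max_iter):
            proj = C @ Xn.T  # (k, m) correlations
            if polarity_invariant:
                labels = np.argmax(proj**2, axis=0)
            else:
                labels = np.argmax(proj, axis=0)
            gev_sum = 0.0
            fit_per_sample = proj[labels, np.arange(m)] ** 2 * sqnorm
            for c in range(k):
                mask = labels == c
                if not mask.any():
                    # dead centroid: reseed from the worst-fit sample
                    worst = int(np.argmin(fit_per_sample))
                    log.debug("restart %d iter %d: reseeding empty cluster %d", restart, it, worst)
                    C[c] = Xn[worst]
                    labels[worst] = c
                    mask = labels == c
                Xc = Xd[mask]
                scatter = Xc.T @ Xc
                if polarity_invariant:
                    direction, lam = _principal_direction(scatter)
                else:
                    mean_map = Xc.sum(axis=0)
                    nrm = np.linalg.norm(mean_map)
                    direction = mean_map / nrm if nrm > 0 else C[c]
                    lam = float(direction @ scatter @ direction)
                C[c] = direction
                gev_sum += lam
            gev = gev_sum / denom
            if gev - prev_gev < tol:
                prev_gev = gev
                break
            prev_gev = gev
        if best is None or prev_gev > best[0]:
            best = (prev_gev, C.copy(), labels.copy(), it)

    gev, C, labels, iters = best
    C = _normalize_rows(_demean_rows(C))
    return MicrostateModel(
        maps=C,
        k=k,
        polarity_invariant=polarity_invariant,
        gev=float(min(gev, 1.0)),
        fit_meta={"restarts": restarts, "iterations": int(iters), "tol": tol},
    )


def compute_gev(
    data_maps: np.ndarray,
    gfp_values: np.ndarray,
    labels: np.ndarray,
    model: MicrostateModel,
) -> float:
    """GEV of a labelling: sum_t (GFP_t corr_t)^2 / sum_t GFP_t^2."""
    X = np.asarray(data_maps, dtype=float)
    g = np.asarray(gfp_values, dtype=float)
    L = np.asarray(labels, dtype=int)
    if not (X.shape[0] == g.size == L.size):
        raise ValueError("data, GFP and labels must align")
    total = float(np.sum(g**2))
    if total <= 0:
        raise ValueError("total GFP is zero; GEV undefined")
    Xn = _normalize_rows(_demean_rows(X))
    corr = np.einsum("ij,ij->i", Xn, model.maps[L])
    return float(np.sum((g * corr) ** 2) / total)


def scan_k(
    peak_maps: np.ndarray,
    k_range: tuple[int, int] = (2, 20),
    restarts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    polarity_invariant: bool = True,
) -> GevCurve:
    """Independent fits over k = kmin..kmax; returns the GEV curve."""
    kmin, kmax = k_range
    if kmin < 2:
        raise ValueError("kmin must be >= 2")
    if kmax < kmin:
        raise ValueError("empty k range")
    ss = np.random.SeedSequence(seed).spawn(kmax - kmin + 1)
    ks, gevs = [], []
    for i, k in enumerate(range(kmin, kmax + 1)):
        model = fit_kmeans(
            peak_maps,
            k,
            restarts=restarts,
            tol=tol,
            max_iter=max_iter,
            seed=np.random.default_rng(ss[i]),
            polarity_invariant=polarity_invariant,
        )
        ks.append(k)
        gevs.append(model.gev)
    gevs = np.asarray(gevs)
    drops = np.diff(gevs) < -0.01
    if drops.any():
        warnings.warn(
            "GEV decreased by more than 0.01 between consecutive k; "
            "consider more restarts",
            stacklevel=2,
        )
    return GevCurve(k_values=np.asarray(ks), gev_values=gevs)


# --------------------------------------------------------------------------
# model order selection
# --------------------------------------------------------------------------


def kneedle(curve: GevCurve, sensitivity: float = 1.0) -> int | None:
    """Knee of a concave increasing curve (kneedle algorithm).

    x and y are min-max normalised, the difference curve d = y_n - x_n is
    formed, and a local maximum of d is declared the knee once d drops
    below (d_lmx - sensitivity * mean x-spacing) before any higher local
    maximum appears. Returns None when no local maximum clears its
    threshold (e.g. a perfectly linear curve).
    """
    x = curve.k_values.astype(float)
    y = curve.gev_values.astype(float)
    if x.size < 3:
        raise ValueError("need at least 3 curve points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    xn = (x - x.min()) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    d = yn - xn
    spacing = sensitivity * np.mean(np.diff(xn))

    # local maxima of the difference curve (plateau-left, endpoints excluded)
    lmx = [
        i
        for i in range(1, d.size - 1)
        if d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    if not lmx:
        return None
    knee = None
    current = None  # (index, threshold)
    for i in range(1, d.size):
        if i in lmx:
            if current is None or d[i] > d[current[0]]:
                current = (i, d[i] - spacing)
        if current is not None and i > current[0] and d[i] < current[1]:
            knee = current[0]
            break
    return int(curve.k_values[knee]) if knee is not None else None


def select_k(curve: GevCurve, sensitivity: float = 1.0, increment_floor: float = 0.01) -> int:
    """Kneedle with fallback: smallest k whose GEV increment drops below 1%."""
    knee = kneedle(curve, sensitivity=sensitivity)
    if knee is not None:
        return knee
    inc = np.diff(curve.gev_values)
    small = np.flatnonzero(inc < increment_floor)
    fallback = int(curve.k_values[small[0] + 1]) if small.size else int(curve.k_values[-1])
    log.warning("kneedle found no knee; falling back to k=%d", fallback)
    return fallback


# --------------------------------------------------------------------------
# backfitting
# --------------------------------------------------------------------------


def backfit(
    ts: ParcelTimeSeries, model: MicrostateModel, gfp: GfpTrace
) -> StateSequence:
    """Label every sample of a scan from its GFP peaks.

    Peak samples get the centroid with minimum distance
    (1 - corr^2 under polarity invariance, 1 - corr otherwise); all
    other samples inherit the label of the temporally nearest peak, the
    earlier peak winning ties. Samples before the first / after the last
    peak take that terminal peak's label.
    """
    peaks = np.asarray(gfp.peak_indices, dtype=int)
    if peaks.size == 0:
        raise ValueError("cannot backfit a scan with no GFP peaks")
    X = ts.data[:, peaks].T  # (n_peaks, n_parcels)
    Xn = _normalize_rows(_demean_rows(X))
    proj = Xn @ model.maps.T  # (n_peaks, k)
    if model.polarity_invariant:
        peak_labels = np.argmax(proj**2, axis=1)
    else:
        peak_labels = np.argmax(proj, axis=1)

    n = ts.n_samples
    idx = np.arange(n)
    right = np.searchsorted(peaks, idx, side="left")  # first peak >= t
    right_c = np.clip(right, 0, peaks.size - 1)
    left_c = np.clip(right - 1, 0, peaks.size - 1)
    dist_right = np.abs(peaks[right_c] - idx)
    dist_left = np.abs(idx - peaks[left_c])
    # earlier peak wins ties -> strict inequality required to pick the right one
    use_right = (right < peaks.size) & ((right - 1 < 0) | (dist_right < dist_left))
    nearest = np.where(use_right, right_c, left_c)
    labels = peak_labels[nearest]
    return StateSequence(
        labels=labels,
        fs=ts.fs,
        peak_indices=peaks,
        source="backfit",
        scan_id=ts.scan_id,
        group=ts.group,
    )


# --------------------------------------------------------------------------
# evaluation helpers
# --------------------------------------------------------------------------


def match_maps(fitted: np.ndarray, planted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal 1-1 matching of fitted to planted maps on |spatial corr|.

    Returns (permutation, |corr| per matched pair): ``permutation[i]`` is
    the planted map assigned to fitted map i (Hungarian assignment
    maximising total |Pearson correlation|).
    """
    from scipy.optimize import linear_sum_assignment

    F = _normalize_rows(_demean_rows(np.asarray(fitted, dtype=float)))
    P = _normalize_rows(_demean_rows(np.asarray(planted, dtype=float)))
    C = np.abs(F @ P.T)
    row, col = linear_sum_assignment(-C)
    return col, C[row, col]
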