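"""Microstate-segmented wPLI connectivity and MVPA decoding.

For each narrow band (delta 1-4, theta 4-8, alpha 8-13, beta 13-30 Hz)
the analytic signal of every parcel is computed; samples carrying a
given microstate label are concatenated and chopped into non-overlapping
5-s windows; each window yields a weighted-phase-lag-index (wPLI) matrix
whose weighted-degree vector serves as one MVPA feature sample. A
cross-validated multiclass linear model decoding the microstate label
from those features, with a label-permutation null, tests whether the
states carry distinct connectivity patterns. Edges whose state-resolved
wPLI deviates most from the static (all-window) background are ranked
for reporting.

wPLI_ij = |mean_t Im S_ij(t)| / mean_t |Im S_ij(t)|, with
S_ij = z_i conj(z_j) the instantaneous cross-spectrum; the index is
insensitive to zero-lag coupling (volume-conduction-like leakage).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .core import ParcelTimeSeries, StateSequence
from .synthetic import BAND_EDGES

__all__ = [
    "BAND_EDGES",
    "StateConnectivity",
    "MvpaResult",
    "narrowband_analytic",
    "segment_windows",
    "wpli",
    "wpli_components",
    "weighted_degree",
    "mvpa_classify",
    "permutation_test",
    "edge_deviation",
    "compute_state_connectivity",
]

log = logging.getLogger(__name__)


@dataclass
class MvpaResult:
    """Cross-validated decoding accuracy with its permutation null."""

    accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_classes: int
    n_windows_per_class: dict[int, int]
    n_folds: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class StateConnectivity:
    """Per-(band, state) wPLI matrices, window features and static background."""

    state_wpli: dict[tuple[str, int], np.ndarray]
    static_wpli: dict[str, np.ndarray]
    features: dict[str, tuple[np.ndarray, np.ndarray]]  # band -> (X, y)
    window_s: float
    mvpa: dict[str, MvpaResult] = field(default_factory=dict)


# --------------------------------------------------------------------------
# analytic signal and windowing
# --------------------------------------------------------------------------


def narrowband_analytic(
    ts: ParcelTimeSeries, band: str | tuple[float, float], order: int = 4
) -> np.ndarray:
    """Complex analytic signal per parcel in one narrow band.

    Zero-phase Butterworth band-pass followed by the Hilbert analytic
    extension; returns a complex (n_parcels, n_samples) array.
    """
    lo, hi = BAND_EDGES[band] if isinstance(band, str) else band
    nyq = ts.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) Hz must lie inside (0, {nyq}) Hz")
    sos = _signal.butter(order, [lo, hi], btype="bandpass", fs=ts.fs, output="sos")
    filtered = _signal.sosfiltfilt(sos, ts.data, axis=-1)
    return _signal.hilbert(filtered, axis=-1)


def segment_windows(
    analytic: np.ndarray, seq: StateSequence, window_s: float = 5.0
) -> tuple[list[np.ndarray], np.ndarray]:
    """Concatenate each state's samples and epoch into disjoint windows.

    Returns (windows, labels): windows are complex (n_parcels, win_len)
    arrays, labels the state each window came from. The residual tail of
    each state's concatenation (shorter than one window) is dropped; a
    state with fewer samples than one window contributes no windows.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if analytic.shape[-1] != seq.n_samples:
        raise ValueError("analytic signal and sequence lengths differ")
    win_len = int(round(window_s * seq.fs))
    windows: list[np.ndarray] = []
    labels: list[int] = []
    for state in range(int(seq.labels.max()) + 1):
        cols = np.flatnonzero(seq.labels == state)
        n_win = cols.size // win_len
        if n_win == 0:
            if cols.size:
                log.debug("state %d has %d samples < one window; skipped", state, cols.size)
            continue
        Z = analytic[:, cols[: n_win * win_len]]
        for w in range(n_win):
            windows.append(Z[:, w * win_len : (w + 1) * win_len])
            labels.append(state)
    return windows, np.asarray(labels, dtype=int)


# --------------------------------------------------------------------------
# wPLI
# --------------------------------------------------------------------------


def wpli_components(window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Numerator |mean Im S| and denominator mean |Im S| of the wPLI ratio.

    Keeping the two components separate lets windows be aggregated
    exactly: a pooled wPLI over any window set is sum(num)/sum(den).
    """
    Z = np.asarray(window)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("window must be (n_parcels, n_samples>=2) and complex")
    x, y = Z.real, Z.imag
    t = Z.shape[1]
    # Im(z_i conj z_j) = y_i x_j - x_i y_j
    mean_im = (y @ x.T - x @ y.T) / t
    num = np.abs(mean_im)
    # |Im| needs the per-sample tensor; chunk over time to bound memory
    p = Z.shape[0]
    den = np.zeros((p, p))
    step = max(1, int(2e6 // (p * p)))
    for a in range(0, t, step):
        b = min(t, a + step)
        im = np.einsum("it,jt->ijt", y[:, a:b], x[:, a:b]) - np.einsum(
            "it,jt->ijt", x[:, a:b], y[:, a:b]
        )
        den += np.abs(im).sum(axis=-1)
    den /= t
    np.fill_diagonal(num, 0.0)
    np.fill_diagonal(den, 0.0)
    return num, den


def wpli(window: np.ndarray) -> np.ndarray:
    """Weighted phase lag index matrix of one window; 0 where Im S vanishes."""
    num, den = wpli_components(window)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-15, num / np.maximum(den, 1e-300), 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def weighted_degree(matrix: np.ndarray) -> np.ndarray:
    """Row sums excluding the diagonal of a symmetric connectivity matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    return m.sum(axis=1) - np.diag(m)


# --------------------------------------------------------------------------
# MVPA
# --------------------------------------------------------------------------


def _make_classifier(kind: str, seed: int | None):
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    if kind == "logistic":
        clf = LogisticRegression(max_iter=2000, C=1.0)
    else:
        raise ValueError(f"unknown classifier {kind!r}")
    return make_pipeline(StandardScaler(), clf)


def _lda_fold_accuracy(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, yte: np.ndarray
) -> float:
    """Shrinkage LDA (Ledoit-Wolf) fold accuracy, train-fold standardised.

    Same model as scikit-learn's ``LinearDiscriminantAnalysis(solver="lsqr",
    shrinkage="auto")`` behind a ``StandardScaler``, implemented directly in
    NumPy so the permutation null (hundreds of full cross-validations) stays
    cheap.
    """
    from sklearn.covariance import ledoit_wolf

    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (Xtr - mu) / sd
    Xte = (Xte - mu) / sd
    classes = np.unique(ytr)
    means = np.vstack([Xtr[ytr == c].mean(axis=0) for c in classes])
    priors = np.array([(ytr == c).mean() for c in classes])
    centered = Xtr - means[np.searchsorted(classes, ytr)]
    cov, _ = ledoit_wolf(centered, assume_centered=True)
    coef = np.linalg.solve(cov, means.T).T  # (n_classes, p)
    intercept = -0.5 * np.einsum("ij,ij->i", means, coef) + np.log(priors)
    scores = Xte @ coef.T + intercept
    pred = classes[np.argmax(scores, axis=1)]
    return float(np.mean(pred == yte))


def _check_classes(y: np.ndarray, n_folds: int) -> dict[int, int]:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < n_folds:
        bad = classes[counts < n_folds].tolist()
        raise ValueError(
            f"classes {bad} have fewer than {n_folds} windows; "
            "generate longer recordings rather than merging classes"
        )
    return dict(zip(classes.tolist(), counts.tolist()))


def mvpa_classify(
    features: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    classifier: str = "lda",
) -> float:
    """Stratified k-fold cross-validated accuracy of a linear decoder.

    Features are standardised inside each training fold. Deterministic
    given ``seed`` (fold shuffling only; the decoders are deterministic).
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValueError("features and labels must align")
    _check_classes(y, n_folds)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    if classifier == "lda":
        scores = [
            _lda_fold_accuracy(X[tr], y[tr], X[te], y[te]) for tr, te in cv.split(X, y)
        ]
        return float(np.mean(scores))
    scores = cross_val_score(_make_classifier(classifier, seed), X, y, cv=cv)
    return float(scores.mean())


def permutation_test(
    features: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    n_folds: int = 5,
    seed: int = 0,
    classifier: str = "lda",
) -> MvpaResult:
    """Label-permutation null for the cross-validated accuracy.

    p = (1 + #{null >= observed}) / (1 + n_perm); the +1 correction keeps
    p strictly positive, so 1000 permutations bottom out at ~0.001
    (reported in tables as p < 0.001).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    y = np.asarray(labels)
    counts = _check_classes(y, n_folds)
    rng = np.random.default_rng(seed)
    observed = mvpa_classify(features, y, n_folds=n_folds, seed=seed, classifier=classifier)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(y)
        nulls[i] = mvpa_classify(
            features, perm, n_folds=n_folds, seed=seed, classifier=classifier
        )
    p = (1.0 + np.sum(nulls >= observed)) / (1.0 + n_perm)
    return MvpaResult(
        accuracy=observed,
        null_accuracies=nulls,
        p_value=float(p),
        n_classes=len(counts),
        n_windows_per_class=counts,
        n_folds=n_folds,
        seed=seed,
    )


# --------------------------------------------------------------------------
# deviation edges and the full per-scan computation
# --------------------------------------------------------------------------


def edge_deviation(
    state_wpli: dict[int, np.ndarray],
    static_wpli: np.ndarray,
    top_frac: float = 0.01,
):
    """Top (state, edge) pairs by |state wPLI - static wPLI|.

    All k * C(p, 2) pairs are ranked by absolute deviation (descending);
    the top ceil(top_frac * total) are returned as a DataFrame with
    signed deviations. Ties are broken by (state, i, j) lexicographic
    order.
    """
    import pandas as pd

    if not (0.0 < top_frac <= 1.0):
        raise ValueError("top_frac must lie in (0, 1]")
    rows = []
    for state in sorted(state_wpli):
        dev = state_wpli[state] - static_wpli
        if dev.shape != static_wpli.shape:
            raise ValueError("state and static matrices must share shape")
        p = dev.shape[0]
        iu, ju = np.triu_indices(p, k=1)
        for i, j, d in zip(iu, ju, dev[iu, ju]):
            rows.append((state, int(i), int(j), float(d)))
    df = pd.DataFrame(rows, columns=["state", "parcel_i", "parcel_j", "deviation"])
    df["absdev"] = df["deviation"].abs()
    df = df.sort_values(
        ["absdev", "state", "parcel_i", "parcel_j"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).drop(columns="absdev")
    n_top = math.ceil(top_frac * len(df))
    return df.head(n_top).reset_index(drop=True)


def compute_state_connectivity(
    ts: ParcelTimeSeries,
    seq: StateSequence,
    bands: list[str] | None = None,
    window_s: float = 5.0,
) -> StateConnectivity:
    """wPLI matrices, degree features and static background for one scan."""
    if bands is None:
        bands = list(BAND_EDGES)
    state_mats: dict[tuple[str, int], np.ndarray] = {}
    static: dict[str, np.ndarray] = {}
    feats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for band in bands:
        analytic = narrowband_analytic(ts, band)
        windows, labels = segment_windows(analytic, seq, window_s=window_s)
        p = ts.n_parcels
        num_tot = np.zeros((p, p))
        den_tot = np.zeros((p, p))
        per_state_num: dict[int, np.ndarray] = {}
        per_state_den: dict[int, np.ndarray] = {}
        X = np.empty((len(windows), p))
        for w, (win, lab) in enumerate(zip(windows, labels)):
            num, den = wpli_components(win)
            with np.errstate(invalid="ignore", divide="ignore"):
                wmat = np.where(den > 1e-15, num / np.maximum(den, 1e-300), 0.0)
            X[w] = weighted_degree(wmat)
            num_tot += num
            den_tot += den
            s = int(lab)
            per_state_num[s] = per_state_num.get(s, 0) + num
            per_state_den[s] = per_state_den.get(s, 0) + den
        for s in per_state_num:
            with np.errstate(invalid="ignore", divide="ignore"):
                state_mats[(band, s)] = np.where(
                    per_state_den[s] > 1e-15,
                    per_state_num[s] / np.maximum(per_state_den[s], 1e-300),
                    0.0,
                )
        with np.errstate(invalid="ignore", divide="ignore"):
            static[band] = np.where(
                den_tot > 1e-15, num_tot / np.maximum(den_tot, 1e-300), 0.0
            )
        feats[band] = (X, labels)
    return StateConnectivity(
        state_wpli=state_mats, static_wpli=static, features=feats, window_s=window_s
    )
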