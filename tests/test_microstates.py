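"""Clustering, GEV, kneedle and backfitting against independent oracles."""

import numpy as np
import pytest

from microdyn.core import GfpTrace, ParcelTimeSeries
from microdyn.microstates import (
    GevCurve,
    MicrostateModel,
    backfit,
    compute_gev,
    fit_kmeans,
    kneedle,
    match_maps,
    scan_k,
    select_k,
)


def orthogonal_zero_mean_maps(k, p, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((p, k + 1))
    X[:, 0] = 1.0  # force the constant direction into the basis, then drop it
    q, _ = np.linalg.qr(X)
    return q[:, 1 : k + 1].T  # orthonormal and orthogonal to the constant


class TestFitKmeans:
    def test_perfect_recovery_of_planted_orthogonal_maps(self):
        maps = orthogonal_zero_mean_maps(3, 12)
        X = np.vstack([maps[i] * s for i in range(3) for s in (1.0, -2.0, 0.5)] * 4)
        model = fit_kmeans(X, 3, restarts=5, seed=1)
        _, corrs = match_maps(model.maps, maps)
        assert np.all(corrs > 1 - 1e-9)
        assert model.gev == pytest.approx(1.0)

    def test_k1_equals_principal_direction(self, rng):
        X = rng.standard_normal((60, 9))
        model = fit_kmeans(X, 1, restarts=1, seed=0)
        Xd = X - X.mean(axis=1, keepdims=True)
        # power-iteration oracle
        v = np.ones(9) / 3.0
        S = Xd.T @ Xd
        for _ in range(500):
            v = S @ v
            v /= np.linalg.norm(v)
        assert abs(float(model.maps[0] @ v)) == pytest.approx(1.0, abs=1e-6)

    def test_partition_matches_exhaustive_bipartition(self, rng):
        # small instance: the k-means optimum must equal the best of all
        # bipartitions by GEV (centroid = principal direction per side)
        m, p = 12, 5
        X = rng.standard_normal((m, p))
        Xd = X - X.mean(axis=1, keepdims=True)
        denom = np.sum(Xd**2)
        best = -1.0
        for mask_bits in range(1, 2 ** (m - 1)):
            mask = np.array([(mask_bits >> i) & 1 for i in range(m)], dtype=bool)
            if mask.all() or not mask.any():
                continue
            gev = sum(
                np.linalg.eigvalsh(Xd[side].T @ Xd[side])[-1]
                for side in (mask, ~mask)
            ) / denom
            best = max(best, gev)
        model = fit_kmeans(X, 2, restarts=30, seed=3)
        assert model.gev == pytest.approx(best, abs=1e-9)

    def test_more_clusters_than_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_kmeans(rng.standard_normal((3, 5)), 4)

    def test_polarity_invariance_of_fit(self, rng):
        X = rng.standard_normal((80, 10))
        flip = rng.choice([-1.0, 1.0], size=(80, 1))
        a = fit_kmeans(X, 3, restarts=10, seed=5)
        b = fit_kmeans(X * flip, 3, restarts=10, seed=5)
        assert a.gev == pytest.approx(b.gev, abs=1e-9)
        _, corrs = match_maps(a.maps, b.maps)
        assert np.all(corrs > 1 - 1e-9)


class TestComputeGev:
    def test_exact_fit_gives_one(self):
        maps = orthogonal_zero_mean_maps(3, 8)
        model = MicrostateModel(maps=maps, k=3)
        X = np.vstack([maps[i] * a for i, a in [(0, 2.0), (1, -1.5), (2, 0.3)]])
        gfp = X.std(axis=1)
        assert compute_gev(X, gfp, [0, 1, 2], model) == pytest.approx(1.0)

    def test_orthogonal_mismatch_gives_zero(self):
        maps = orthogonal_zero_mean_maps(2, 8)
        model = MicrostateModel(maps=maps, k=2)
        X = np.vstack([maps[0], maps[1]])
        gfp = X.std(axis=1)
        assert compute_gev(X, gfp, [1, 0], model) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        maps = orthogonal_zero_mean_maps(3, 7)
        model = MicrostateModel(maps=maps, k=3)
        X = rng.standard_normal((40, 7))
        labels = rng.integers(0, 3, 40)
        gfp = X.std(axis=1)
        got = compute_gev(X, gfp, labels, model)
        num = 0.0
        for t in range(40):
            x = X[t] - X[t].mean()
            corr = (x / np.linalg.norm(x)) @ maps[labels[t]]
            num += (gfp[t] * corr) ** 2
        assert got == pytest.approx(num / np.sum(gfp**2))

    def test_zero_gfp_rejected(self):
        maps = orthogonal_zero_mean_maps(2, 6)
        model = MicrostateModel(maps=maps, k=2)
        with pytest.raises(ValueError):
            compute_gev(np.ones((5, 6)), np.zeros(5), np.zeros(5, dtype=int), model)

    def test_label_permutation_leaves_gev_unchanged(self, rng):
        maps = orthogonal_zero_mean_maps(3, 7)
        X = rng.standard_normal((30, 7))
        gfp = X.std(axis=1)
        labels = rng.integers(0, 3, 30)
        perm = np.array([2, 0, 1])
        a = compute_gev(X, gfp, labels, MicrostateModel(maps=maps, k=3))
        b = compute_gev(X, gfp, perm[labels], MicrostateModel(maps=maps[np.argsort(perm)], k=3))
        assert a == pytest.approx(b)


class TestScanK:
    def test_duplicate_maps_give_unit_gev_everywhere(self):
        one = orthogonal_zero_mean_maps(1, 9)[0]
        X = np.vstack([one * s for s in np.linspace(0.5, 2.0, 30)])
        curve = scan_k(X, (2, 5), restarts=2, seed=0)
        assert curve.k_values.tolist() == [2, 3, 4, 5]
        assert np.allclose(curve.gev_values, 1.0)

    def test_curve_near_monotone_with_planted_structure(self, rng):
        maps = orthogonal_zero_mean_maps(4, 15)
        X = maps[rng.integers(0, 4, 400)] + 0.1 * rng.standard_normal((400, 15))
        curve = scan_k(X, (2, 8), restarts=20, seed=1)
        assert np.all(np.diff(curve.gev_values) > -0.01)
        # large increments up to the planted order, small after
        inc = np.diff(curve.gev_values)
        assert inc[:2].min() > 5 * max(inc[3:].max(), 1e-4)


class TestKneedle:
    def test_formula_oracle(self):
        curve = GevCurve(k_values=np.arange(2, 7), gev_values=[0.2, 0.8, 0.9, 0.95, 0.97])
        # normalized difference curve maximum: d = y_norm - x_norm
        y = np.array([0.2, 0.8, 0.9, 0.95, 0.97])
        d = (y - y.min()) / np.ptp(y) - np.linspace(0, 1, 5)
        assert kneedle(curve) == int(np.arange(2, 7)[np.argmax(d)])

    def test_linear_curve_has_no_knee(self):
        curve = GevCurve(k_values=np.arange(2, 9), gev_values=np.linspace(0.1, 0.7, 7))
        assert kneedle(curve) is None

    def test_select_k_falls_back_to_increment_rule(self):
        curve = GevCurve(k_values=np.arange(2, 9), gev_values=np.linspace(0.1, 0.7, 7))
        assert select_k(curve) == 8  # increments all 0.1 > 1% -> last k

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kneedle(GevCurve(k_values=[2, 3], gev_values=[0.1, 0.2]))


class TestBackfit:
    def _setup(self, peak_labels, peaks, n=30, p=8):
        maps = orthogonal_zero_mean_maps(2, p)
        data = np.zeros((p, n))
        for idx, lab in zip(peaks, peak_labels):
            data[:, idx] = maps[lab] * 5.0
        data += 0.01 * np.random.default_rng(0).standard_normal((p, n))
        ts = ParcelTimeSeries(data=data, fs=100.0)
        model = MicrostateModel(maps=maps, k=2)
        gfp = GfpTrace(values=np.abs(data).std(axis=0), peak_indices=np.array(peaks))
        return ts, model, gfp

    def test_nearest_and_tie_rules(self):
        ts, model, gfp = self._setup([0, 1], [10, 20])
        seq = backfit(ts, model, gfp)
        assert seq.labels[14] == 0  # nearer to peak 10
        assert seq.labels[15] == 0  # equidistant -> earlier peak
        assert seq.labels[16] == 1
        assert seq.labels[0] == 0 and seq.labels[29] == 1  # terminal inheritance

    def test_matches_brute_force_nearest_peak(self, rng):
        n, p = 200, 6
        maps = orthogonal_zero_mean_maps(3, p)
        model = MicrostateModel(maps=maps, k=3)
        data = rng.standard_normal((p, n))
        ts = ParcelTimeSeries(data=data, fs=100.0)
        peaks = np.sort(rng.choice(n, size=20, replace=False))
        gfp = GfpTrace(values=np.abs(data).std(axis=0), peak_indices=peaks)
        seq = backfit(ts, model, gfp)
        # oracle: label peaks by max corr^2, then exhaustive nearest search
        def peak_label(idx):
            x = data[:, idx] - data[:, idx].mean()
            x = x / np.linalg.norm(x)
            return int(np.argmax((maps @ x) ** 2))
        for t in range(n):
            dists = np.abs(peaks - t)
            best = peaks[np.flatnonzero(dists == dists.min())[0]]  # earlier wins
            assert seq.labels[t] == peak_label(best)

    def test_no_peaks_rejected(self, small_scan):
        model = MicrostateModel(maps=orthogonal_zero_mean_maps(2, 8), k=2)
        with pytest.raises(ValueError):
            backfit(small_scan, model, GfpTrace(values=np.ones(small_scan.n_samples)))

    def test_backfit_polarity_invariance(self, rng):
        n, p = 300, 8
        data = rng.standard_normal((p, n))
        flip = rng.choice([-1.0, 1.0], size=n)
        maps = orthogonal_zero_mean_maps(3, p)
        model = MicrostateModel(maps=maps, k=3)
        peaks = np.sort(rng.choice(n, 25, replace=False))
        gfp = GfpTrace(values=np.abs(data).std(axis=0), peak_indices=peaks)
        a = backfit(ParcelTimeSeries(data=data, fs=100.0), model, gfp)
        b = backfit(ParcelTimeSeries(data=data * flip, fs=100.0), model, gfp)
        assert np.array_equal(a.labels, b.labels)
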