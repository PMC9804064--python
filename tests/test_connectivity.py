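"""wPLI, windowing, MVPA and edge ranking against direct-formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdyn.core import ParcelTimeSeries, StateSequence
from microdyn.connectivity import (
    compute_state_connectivity,
    edge_deviation,
    mvpa_classify,
    narrowband_analytic,
    permutation_test,
    segment_windows,
    weighted_degree,
    wpli,
    wpli_components,
)


def tone_pair(lag, n=2500, fs=250.0, f=10.0):
    t = np.arange(n) / fs
    z1 = np.exp(1j * 2 * np.pi * f * t)
    return np.vstack([z1, z1 * np.exp(-1j * lag)])


class TestAnalyticSignal:
    def test_pure_tone_amplitude_and_phase_rate(self):
        fs, f = 250.0, 10.0
        t = np.arange(int(8 * fs)) / fs
        ts = ParcelTimeSeries(data=np.vstack([np.cos(2 * np.pi * f * t)] * 2), fs=fs)
        z = narrowband_analytic(ts, "alpha")
        mid = slice(500, -500)
        assert np.abs(z[0, mid]) == pytest.approx(1.0, rel=0.05)
        dphi = np.diff(np.unwrap(np.angle(z[0, mid])))
        assert np.mean(dphi) * fs == pytest.approx(2 * np.pi * f, rel=0.05)

    def test_zero_signal_maps_to_zero(self):
        ts = ParcelTimeSeries(data=np.zeros((2, 1000)), fs=250.0)
        assert np.allclose(narrowband_analytic(ts, "beta"), 0.0)

    def test_band_outside_nyquist_rejected(self):
        ts = ParcelTimeSeries(data=np.zeros((2, 1000)), fs=50.0)
        with pytest.raises(ValueError):
            narrowband_analytic(ts, (13.0, 30.0))


class TestWpli:
    def test_quarter_cycle_lag_gives_one(self):
        assert wpli(tone_pair(np.pi / 2))[0, 1] == pytest.approx(1.0)

    def test_zero_lag_gives_zero(self):
        assert wpli(tone_pair(0.0))[0, 1] == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        Z = rng.standard_normal((4, 300)) + 1j * rng.standard_normal((4, 300))
        got = wpli(Z)
        for i in range(4):
            for j in range(i + 1, 4):
                im = np.imag(Z[i] * np.conj(Z[j]))
                expected = abs(np.mean(im)) / np.mean(np.abs(im))
                assert got[i, j] == pytest.approx(expected)
                assert got[j, i] == pytest.approx(expected)

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(0.1, 50.0), rot=st.floats(0, 2 * np.pi))
    def test_invariant_to_rescaling_and_common_rotation(self, scale, rot):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((3, 200)) + 1j * rng.standard_normal((3, 200))
        base = wpli(Z)
        assert np.allclose(wpli(Z * scale * np.exp(1j * rot)), base, atol=1e-10)

    def test_entries_bounded_and_symmetric(self, rng):
        Z = rng.standard_normal((5, 400)) + 1j * rng.standard_normal((5, 400))
        W = wpli(Z)
        assert np.all((W >= 0) & (W <= 1 + 1e-12))
        assert np.allclose(W, W.T)
        assert np.allclose(np.diag(W), 0.0)


class TestSegmentWindows:
    def test_floor_arithmetic(self):
        fs = 250.0
        labels = np.zeros(5000, dtype=int)
        labels[:3125] = 1  # 12.5 s of state 1
        seq = StateSequence(labels=labels, fs=fs)
        z = np.arange(2 * 5000, dtype=complex).reshape(2, 5000)
        wins, labs = segment_windows(z, seq, window_s=5.0)
        assert np.sum(labs == 1) == 2  # 3125 // 1250
        assert np.sum(labs == 0) == 1  # 1875 // 1250

    def test_absent_state_contributes_nothing(self):
        seq = StateSequence(labels=np.zeros(3000, dtype=int), fs=250.0)
        z = np.zeros((2, 3000), dtype=complex)
        wins, labs = segment_windows(z, seq, window_s=5.0)
        assert set(labs.tolist()) == {0}

    def test_per_state_sample_counts_match_coverage(self, rng):
        labels = rng.integers(0, 3, 20000)
        seq = StateSequence(labels=labels, fs=250.0)
        z = rng.standard_normal((2, 20000)) * (1 + 0j)
        wins, labs = segment_windows(z, seq, window_s=1.0)
        for s in range(3):
            assert np.sum(labs == s) == np.sum(labels == s) // 250


class TestWeightedDegree:
    def test_all_ones_off_diagonal(self):
        m = np.ones((78, 78)) - np.eye(78)
        assert np.allclose(weighted_degree(m), 77.0)

    def test_zero_matrix(self):
        assert np.allclose(weighted_degree(np.zeros((5, 5))), 0.0)

    def test_matches_brute_force_row_sum(self, rng):
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        got = weighted_degree(m)
        for i in range(6):
            assert got[i] == pytest.approx(sum(m[i, j] for j in range(6) if j != i))


class TestMvpa:
    def test_linearly_separable_classes_reach_unit_accuracy(self, rng):
        mu = rng.standard_normal((7, 10)) * 5
        y = np.repeat(np.arange(7), 20)
        X = mu[y] + 0.01 * rng.standard_normal((140, 10))
        assert mvpa_classify(X, y, seed=0) == pytest.approx(1.0)

    def test_identical_distributions_stay_near_chance(self, rng):
        accs = []
        for r in range(10):
            X = rng.standard_normal((140, 12))
            y = np.repeat(np.arange(7), 20)
            accs.append(mvpa_classify(X, y, seed=r))
        assert np.mean(accs) == pytest.approx(1 / 7, abs=0.03)

    def test_known_bayes_rate_recovered(self, rng):
        # two 1-D Gaussian classes at +/- mu with sigma 1:
        # Bayes error = Phi(-mu) = 0.2 at mu = 0.8416
        mu = 0.8416
        n = 1000
        X = np.concatenate([rng.normal(-mu, 1, n), rng.normal(mu, 1, n)])[:, None]
        y = np.repeat([0, 1], n)
        acc = mvpa_classify(X, y, seed=0)
        assert acc == pytest.approx(0.80, abs=0.03)

    def test_small_class_rejected(self):
        X = np.zeros((8, 3))
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="fewer than"):
            mvpa_classify(X, y, n_folds=5)

    def test_matches_sklearn_lda_closely(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        diffs = []
        for trial in range(5):
            X = rng.standard_normal((90, 12)) + np.repeat(
                rng.standard_normal((3, 12)) * 0.8, 30, axis=0
            )
            y = np.repeat(np.arange(3), 30)
            cv = StratifiedKFold(5, shuffle=True, random_state=trial)
            sk = cross_val_score(
                make_pipeline(
                    StandardScaler(),
                    LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
                ),
                X, y, cv=cv,
            ).mean()
            diffs.append(abs(sk - mvpa_classify(X, y, seed=trial)))
        assert np.mean(diffs) < 0.03


class TestPermutationTest:
    def test_p_value_floor(self, rng):
        mu = rng.standard_normal((3, 8)) * 5
        y = np.repeat(np.arange(3), 15)
        X = mu[y] + 0.01 * rng.standard_normal((45, 8))
        res = permutation_test(X, y, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_zero_permutations_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError):
            permutation_test(X, y, n_perm=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((40, 5))
        y = np.repeat([0, 1], 20)
        a = permutation_test(X, y, n_perm=20, seed=3)
        b = permutation_test(X, y, n_perm=20, seed=3)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_accuracies, b.null_accuracies)


class TestEdgeDeviation:
    def test_ceiling_arithmetic_78_parcels(self):
        sw = {s: np.zeros((78, 78)) for s in range(7)}
        df = edge_deviation(sw, np.zeros((78, 78)), top_frac=0.01)
        assert len(df) == 211  # ceil(0.01 * 7 * C(78,2)) = ceil(210.21)

    def test_all_zero_ties_resolve_lexicographically(self):
        sw = {s: np.zeros((4, 4)) for s in range(2)}
        df = edge_deviation(sw, np.zeros((4, 4)), top_frac=1.0)
        first = df.iloc[0]
        assert (first.state, first.parcel_i, first.parcel_j) == (0, 0, 1)
        assert df[["state", "parcel_i", "parcel_j"]].apply(tuple, axis=1).is_monotonic_increasing

    def test_planted_deviation_ranks_first(self):
        static = np.zeros((5, 5))
        sw = {0: np.zeros((5, 5)), 1: np.zeros((5, 5))}
        sw[1][2, 4] = sw[1][4, 2] = 0.7
        df = edge_deviation(sw, static, top_frac=0.1)
        assert tuple(df.iloc[0][["state", "parcel_i", "parcel_j"]]) == (1, 2, 4)
        assert df.iloc[0].deviation == pytest.approx(0.7)


class TestStaticAggregationIdentity:
    def test_static_equals_pooled_state_components(self, rng):
        labels = np.repeat(rng.integers(0, 2, 40), 250)  # 40 s at 250 Hz
        seq = StateSequence(labels=labels, fs=250.0)
        ts = ParcelTimeSeries(data=rng.standard_normal((4, labels.size)), fs=250.0)
        conn = compute_state_connectivity(ts, seq, bands=["alpha"], window_s=5.0)
        z = narrowband_analytic(ts, "alpha")
        wins, wlabs = segment_windows(z, seq, 5.0)
        num = sum(wpli_components(w)[0] for w in wins)
        den = sum(wpli_components(w)[1] for w in wins)
        expected = np.where(den > 1e-15, num / np.maximum(den, 1e-300), 0.0)
        assert np.allclose(conn.static_wpli["alpha"], expected, atol=1e-12)
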