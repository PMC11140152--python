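import numpy as np
import pytest

from ddadecode import (
    DelayPair,
    WindowSpec,
    build_design,
    ergodicity_score,
    estimate_derivative,
    extract_features,
    fit_ct,
    fit_st,
    gen_sinusoid,
)
from ddadecode.windowing import standardize_window


class TestDerivative:
    def test_ramp_gives_unit_slope(self):
        du = estimate_derivative(np.arange(50, dtype=float))
        np.testing.assert_allclose(du, 1.0)

    def test_constant_gives_zero(self):
        assert not estimate_derivative(np.full(10, 3.3)).any()

    def test_sinusoid_trig_identity(self):
        # (sin(w(n+1)) - sin(w(n-1)))/2 = sin(w)*cos(w*n), exactly
        w = 0.31
        n = np.arange(200)
        du = estimate_derivative(np.sin(w * n))
        np.testing.assert_allclose(du, np.sin(w) * np.cos(w * n[1:-1]), atol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            estimate_derivative(np.array([1.0, 2.0]))


class TestBuildDesign:
    def test_row_count_and_indexing(self):
        u = np.random.default_rng(0).normal(size=10)
        X, y = build_design(u, DelayPair(2, 5))
        assert X.shape == (4, 3)  # rows n = 5..8
        assert y.shape == (4,)
        np.testing.assert_allclose(X[:, 0], u[[3, 4, 5, 6]])
        np.testing.assert_allclose(X[:, 1], u[[0, 1, 2, 3]])
        np.testing.assert_allclose(X[:, 2], X[:, 0] ** 2)
        np.testing.assert_allclose(y, (u[6:10] - u[4:8]) / 2)

    def test_column_difference_identity(self):
        u = np.random.default_rng(1).normal(size=40)
        d = DelayPair(1, 2)
        X, _ = build_design(u, d)
        n = np.arange(d.tmax, len(u) - 1)
        np.testing.assert_allclose(X[:, 0] - X[:, 1], u[n - 1] - u[n - 2])

    def test_insufficient_length_raises(self):
        with pytest.raises(ValueError):
            build_design(np.ones(8), DelayPair(3, 7))


class TestFitST:
    def test_matches_normal_equations_oracle(self):
        """QR least-squares fitter vs brute-force normal equations, 100
        random 200-sample windows, agreement to 1e-8."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            u = standardize_window(rng.normal(size=200))
            d = DelayPair(int(rng.integers(1, 12)), int(rng.integers(12, 25)))
            X, y = build_design(u, d)
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            f = fit_st(u, d)
            np.testing.assert_allclose(f.coef, oracle, atol=1e-8)
            rho_oracle = np.sqrt(np.mean((X @ oracle - y) ** 2))
            assert abs(f.rho - rho_oracle) < 1e-8

    def test_sinusoid_closed_form(self):
        """Noise-free sinusoid: (a1, a2) solve the 2x2 trig matching system
        a1*cos(w*t1)+a2*cos(w*t2)=0, a1*sin(w*t1)+a2*sin(w*t2)=-sin(w)."""
        u = standardize_window(gen_sinusoid(10.0, 1000.0, 4000))
        w = 2 * np.pi * 10.0 / 1000.0
        for t1, t2 in [(4, 9), (3, 11), (6, 13)]:
            f = fit_st(u, DelayPair(t1, t2))
            A = np.array([[np.cos(w * t1), np.cos(w * t2)],
                          [np.sin(w * t1), np.sin(w * t2)]])
            a12 = np.linalg.solve(A, [0.0, -np.sin(w)])
            np.testing.assert_allclose([f.a1, f.a2], a12, atol=1e-6)
            assert abs(f.a3) < 1e-3
            assert f.rho < 1e-3

    def test_constant_window_flagged(self):
        f = fit_st(np.full(100, 2.0), DelayPair(3, 7))
        assert f.is_degenerate

    def test_scale_invariance_of_standardized_fit(self):
        u = np.random.default_rng(3).normal(size=300).cumsum()
        d = DelayPair(2, 6)
        f1 = fit_st(standardize_window(u), d)
        f2 = fit_st(standardize_window(5.0 * u + 3.0), d)
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-10)
        assert abs(f1.rho - f2.rho) < 1e-10


class TestFitCT:
    def test_identical_windows_equal_st(self):
        u = standardize_window(np.random.default_rng(0).normal(size=150).cumsum())
        d = DelayPair(2, 5)
        st = fit_st(u, d)
        ct = fit_ct([u, u], d)
        np.testing.assert_allclose(ct.coef, st.coef, atol=1e-10)
        assert abs(ct.rho - st.rho) < 1e-10

    def test_single_window_equals_st(self):
        u = standardize_window(np.random.default_rng(1).normal(size=150).cumsum())
        d = DelayPair(3, 4)
        np.testing.assert_allclose(fit_ct([u], d).coef, fit_st(u, d).coef, atol=1e-12)

    def test_pooled_residual_dominates_mean_st(self):
        """rho_CT^2 >= mean(rho_ST^2): one shared coefficient set cannot
        beat per-window fits."""
        rng = np.random.default_rng(2)
        d = DelayPair(3, 7)
        for _ in range(20):
            group = [standardize_window(rng.normal(size=160).cumsum()) for _ in range(3)]
            ct = fit_ct(group, d)
            st_sq = np.mean([fit_st(u, d).rho ** 2 for u in group])
            assert ct.rho ** 2 >= st_sq - 1e-12


class TestErgodicity:
    def test_identical_channels_zero(self):
        u = standardize_window(np.random.default_rng(0).normal(size=150).cumsum())
        d = DelayPair(2, 5)
        st = [fit_st(u, d)] * 3
        assert abs(ergodicity_score(st, fit_ct([u] * 3, d))) < 1e-10

    def test_different_dynamics_positive(self):
        rng = np.random.default_rng(4)
        d = DelayPair(3, 7)
        smooth = standardize_window(rng.normal(size=200).cumsum())
        rough = standardize_window(np.sign(rng.normal(size=200)))
        st = [fit_st(smooth, d), fit_st(rough, d)]
        e = ergodicity_score(st, fit_ct([smooth, rough], d))
        assert e > 0

    def test_nan_propagates(self):
        u = standardize_window(np.random.default_rng(0).normal(size=150))
        d = DelayPair(2, 5)
        bad = fit_st(np.full(150, 1.0), d)
        assert np.isnan(ergodicity_score([fit_st(u, d), bad], fit_ct([u, u], d)))


class TestExtractFeatures:
    def test_sliding_feature_count_34_per_triple(self, tiny_trialset, wspec):
        fm = extract_features(tiny_trialset, [(0, 1, 2)], DelayPair(3, 7), wspec)
        # 3 channels x 8 (mean/std of a1,a2,a3,rho) + 8 CT + 2 E
        assert fm.values.shape == (tiny_trialset.n_trials, 34)
        assert len(fm.feature_names) == 34
        assert sum(".CT." in n for n in fm.feature_names) == 8
        assert sum(".E." in n for n in fm.feature_names) == 2
        assert np.isfinite(fm.values).all()

    def test_single_window_feature_count_17_per_triple(self, tiny_trialset):
        fm = extract_features(
            tiny_trialset, [(0, 1, 2)], DelayPair(3, 7), WindowSpec(mode="single")
        )
        assert fm.values.shape[1] == 3 * 4 + 4 + 1
        assert all(n.endswith(".val") for n in fm.feature_names)

    def test_identical_trials_identical_rows(self, tiny_trialset, wspec):
        ts = tiny_trialset
        data = np.concatenate([ts.data[:1], ts.data[:1]])
        from ddadecode import TrialSet

        dup = TrialSet(data, ts.fs, ts.labels[:2], ts.subjects[:2], ts.channel_names)
        fm = extract_features(dup, [(0, 1, 2)], DelayPair(2, 5), wspec)
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_scale_invariance(self, tiny_trialset, wspec):
        from ddadecode import TrialSet

        ts = tiny_trialset
        scaled = TrialSet(7.5 * ts.data, ts.fs, ts.labels, ts.subjects, ts.channel_names)
        a = extract_features(ts, [(0, 1, 2)], DelayPair(3, 7), wspec)
        b = extract_features(scaled, [(0, 1, 2)], DelayPair(3, 7), wspec)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_degenerate_channel_yields_nan_features(self, wspec):
        from ddadecode import TrialSet

        rng = np.random.default_rng(0)
        data = rng.normal(size=(2, 3, 128))
        data[0, 1] = 4.2  # constant channel in trial 0
        ts = TrialSet(data, 64.0, ["a", "b"], [0, 0], ["c0", "c1", "c2"])
        fm = extract_features(ts, [(0, 1, 2)], DelayPair(2, 5), wspec)
        ch1 = [i for i, n in enumerate(fm.feature_names) if ".c1." in n]
        assert np.isnan(fm.values[0, ch1]).all()
        assert np.isfinite(fm.values[1, ch1]).all()
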