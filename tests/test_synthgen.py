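import numpy as np
import pytest

from ddadecode import (
    ClassDynamics,
    DelayPair,
    GeneratorSpec,
    fit_st,
    gen_null_trialset,
    gen_signal,
    gen_sinusoid,
    gen_trialset,
    null_spec,
    two_class_spec,
)
from ddadecode.synthgen import AMPLITUDE_GUARD, DivergenceError


class TestGenSignal:
    def test_degenerate_dynamics_is_random_walk(self):
        # b = 0: u[n] = u[n-1] + eps, so the differenced series is white noise
        spec = two_class_spec(ClassDynamics(3, 7, 0, 0, 0, 1.0), ClassDynamics(3, 7, 0, 0, 0, 1.0))
        u = gen_signal(spec, "a", 4000, 0)
        d = np.diff(u)
        for lag in (1, 2, 3, 7):
            assert abs(np.corrcoef(d[:-lag], d[lag:])[0, 1]) < 0.05

    def test_roundtrip_recovery_linear(self):
        """Fitting at the generating delays recovers (b1, b2) within 0.02."""
        spec = two_class_spec(
            ClassDynamics(3, 7, -0.1, 0.05, 0.0, 1e-3),
            ClassDynamics(3, 7, -0.1, 0.05, 0.0, 1e-3),
        )
        errs = []
        for seed in range(20):
            u = gen_signal(spec, "a", 3000, seed)
            f = fit_st(u, DelayPair(3, 7))
            errs.append([abs(f.a1 + 0.1), abs(f.a2 - 0.05)])
        med = np.median(errs, axis=0)
        assert (med < 0.02).all()

    def test_roundtrip_recovery_with_quadratic_term(self):
        """All three coefficients recover at a noise level where the
        quadratic regressor has usable signal."""
        spec = two_class_spec(
            ClassDynamics(3, 7, -0.1, 0.05, 0.02, 0.1),
            ClassDynamics(3, 7, -0.1, 0.05, 0.02, 0.1),
        )
        errs = []
        for seed in range(20):
            u = gen_signal(spec, "a", 3000, seed)
            f = fit_st(u, DelayPair(3, 7))
            errs.append(np.abs(f.coef - [-0.1, 0.05, 0.02]))
        assert (np.median(errs, axis=0) < 0.02).all()

    def test_distinct_seeds_decorrelated(self):
        spec = null_spec(n_subjects=1)
        for seed in range(20):
            u1 = gen_signal(spec, "c0", 2000, seed)
            u2 = gen_signal(spec, "c0", 2000, 10_000 + seed)
            assert abs(np.corrcoef(u1, u2)[0, 1]) < 0.3

    def test_bounded_finite_nonzero_variance(self):
        spec = null_spec(n_subjects=1)
        u = gen_signal(spec, "c0", 1000, 3)
        assert len(u) == 1000
        assert np.isfinite(u).all()
        assert np.abs(u).max() <= AMPLITUDE_GUARD
        assert u.std() > 0

    def test_divergent_map_raises_after_retries(self):
        spec = two_class_spec(
            ClassDynamics(3, 7, 1.0, 1.0, 0.5, 1.0),
            ClassDynamics(3, 7, 1.0, 1.0, 0.5, 1.0),
        )
        with pytest.raises(DivergenceError):
            gen_signal(spec, "a", 500, 0)


class TestGenSinusoid:
    def test_exact_cycles_zero_mean(self):
        u = gen_sinusoid(10.0, 1000.0, 4000)  # 40 full cycles
        assert abs(u.mean()) < 1e-10
        np.testing.assert_allclose(u[:100], u[100:200], atol=1e-9)

    def test_zero_amplitude(self):
        assert not gen_sinusoid(10.0, 1000.0, 100, amplitude=0.0).any()

    def test_quarter_nyquist_period_four(self):
        u = gen_sinusoid(250.0, 1000.0, 16)
        np.testing.assert_allclose(u, np.tile([0, 1, 0, -1], 4), atol=1e-12)

    @pytest.mark.parametrize("freq", [500.0, 600.0, 0.0, -1.0])
    def test_aliasing_raises(self, freq):
        with pytest.raises(ValueError):
            gen_sinusoid(freq, 1000.0, 100)


class TestTrialSets:
    def test_counts(self):
        spec = null_spec(n_classes=2, n_subjects=2, n_trials_per_class=5,
                         fs=64.0, trial_len=2.0)
        ts = gen_trialset(spec)
        assert ts.n_trials == 2 * 2 * 5
        assert ts.n_channels == 3
        assert len(np.unique(ts.subjects)) == 2

    def test_reproducible_bit_identical(self):
        spec = null_spec(n_classes=2, n_subjects=1, n_trials_per_class=3,
                         fs=64.0, seed=42)
        a, b = gen_trialset(spec), gen_trialset(spec)
        assert (a.data == b.data).all()
        assert (a.labels == b.labels).all()

    def test_identity_mixing_channels_independent(self):
        spec = null_spec(n_classes=2, n_subjects=1, n_trials_per_class=4, fs=64.0)
        ts = gen_trialset(spec)
        r = np.corrcoef(ts.data[0, 0], ts.data[0, 1])[0, 1]
        assert abs(r) < 0.5  # independent realizations, not copies

    def test_null_set_shares_dynamics_and_balances_labels(self):
        spec = null_spec(n_classes=3, n_subjects=1, n_trials_per_class=4, fs=64.0)
        ts = gen_null_trialset(spec)
        _, counts = np.unique(ts.labels, return_counts=True)
        assert (counts == 4).all()

    def test_null_label_exchangeability(self):
        """Per-class mean signal power of a null set is class-independent
        (coarse): labels carry no signal by construction."""
        spec = null_spec(n_classes=2, n_subjects=1, n_trials_per_class=15, fs=64.0, seed=9)
        ts = gen_null_trialset(spec)
        power = ts.data.var(axis=(1, 2))
        g0 = power[ts.labels == "c0"]
        g1 = power[ts.labels == "c1"]
        pooled = power.std()
        assert abs(g0.mean() - g1.mean()) < pooled

    def test_zero_trials_raises(self):
        with pytest.raises(ValueError):
            null_spec(n_trials_per_class=0)

    def test_invalid_mixing_raises(self):
        with pytest.raises(ValueError, match="mixing"):
            GeneratorSpec(
                n_subjects=1, n_trials_per_class=2, classes=("a",),
                fs=64.0, trial_len=2.0, n_channels=3,
                dynamics={"a": ClassDynamics(3, 7, -0.1, 0.05)},
                mixing=np.ones((2, 2)),
            )

    def test_equal_delays_raise(self):
        with pytest.raises(ValueError):
            ClassDynamics(5, 5, -0.1, 0.05)

    def test_dense_mixing_applied(self):
        mix = np.array([[1.0, 0.5], [0.0, 1.0], [0.3, 0.3]])
        spec = GeneratorSpec(
            n_subjects=1, n_trials_per_class=2, classes=("a",),
            fs=64.0, trial_len=2.0, n_channels=3,
            dynamics={"a": ClassDynamics(3, 7, -0.1, 0.05)},
            mixing=mix,
        )
        ts = gen_trialset(spec)
        assert ts.data.shape == (2, 3, 128)
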