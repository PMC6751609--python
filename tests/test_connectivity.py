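import numpy as np
import pytest
from scipy import signal as sps

import myonet as mn
from myonet.connectivity import BIN_CENTERS_HZ, mvar_coherence
from myonet.preprocess import EnvelopeSet


def _env(x, fs=200.0, labels=None):
    x = np.asarray(x, float)
    labels = labels or tuple(f"ch{i}" for i in range(x.shape[0]))
    return EnvelopeSet(sample_rate_hz=fs, channel_labels=tuple(labels),
                       envelopes=x)


def _band_noise(rng, n, lo, hi, fs=200.0):
    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(n))


class TestNormalizedPsd:
    def test_rows_sum_to_one_and_shape(self, hc_envelopes):
        spec = mn.normalized_psd(hc_envelopes)
        assert spec.psd.shape == (8, 35)
        assert np.allclose(spec.psd.sum(axis=1), 1.0, atol=1e-9)
        assert (spec.psd >= 0).all()

    def test_pure_tone_peaks_in_containing_bin(self):
        t = np.arange(12_000) / 200.0
        x = np.tile(1.0 + 0.5 * np.sin(2 * np.pi * 10.0 * t), (8, 1))
        spec = mn.normalized_psd(_env(x))
        assert (spec.bin_centers_hz[spec.psd.argmax(axis=1)] == 11.0).all()

    def test_white_noise_spectrum_is_flat(self):
        """Seed-averaged normalized PSD of white noise: max/min bin < 1.5."""
        acc = np.zeros(35)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            spec = mn.normalized_psd(_env(rng.standard_normal((8, 24_000))))
            acc += spec.psd.mean(axis=0)
        acc /= 10
        assert acc.max() / acc.min() < 1.5

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            mn.normalized_psd(_env(np.ones((8, 150))))


class TestImcoh:
    def test_identical_channels_fully_coherent(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        env = _env(np.stack([x, x]))
        conn = mn.imcoh([env])
        assert np.allclose(conn.values, 1.0, atol=1e-9)

    def test_symmetric_lookup(self, hc_envelopes):
        conn = mn.imcoh([hc_envelopes])
        assert np.array_equal(conn.value("TA_l", "G_r"),
                              conn.value("G_r", "TA_l"))
        assert conn.values.shape == (28, 35)
        assert (conn.values >= 0).all() and (conn.values <= 1).all()

    def test_independent_noise_has_low_coherence(self):
        rng = np.random.default_rng(1)
        env = _env(rng.standard_normal((4, 24_000)))
        conn = mn.imcoh([env])
        assert conn.values.mean() < 0.1

    def test_planted_common_drive_peaks_in_its_bin(self):
        rng = np.random.default_rng(2)
        n = 24_000
        drive = _band_noise(rng, n, 10.0, 12.0)
        drive /= drive.std()
        x = np.stack([drive + 0.8 * rng.standard_normal(n),
                      drive + 0.8 * rng.standard_normal(n)])
        conn = mn.imcoh([_env(x)])
        assert conn.bin_centers_hz[conn.values[0].argmax()] == 11.0

    def test_matches_scipy_coherence(self):
        """Pooled single-trial estimate equals scipy's Welch coherence."""
        rng = np.random.default_rng(3)
        common = _band_noise(rng, 8000, 8.0, 14.0)
        x = np.stack([common + rng.standard_normal(8000),
                      common + rng.standard_normal(8000)])
        conn = mn.imcoh([_env(x)])
        f, cxy = sps.coherence(x[0], x[1], fs=200.0, window="hann",
                               nperseg=200, noverlap=150, detrend="constant")
        keep = (f > 0) & (f < 70.0)  # DC excluded, as in the implementation
        binned = np.zeros(35)
        which = np.digitize(f[keep], np.arange(0, 72, 2)) - 1
        for b in range(35):
            binned[b] = cxy[keep][which == b].mean()
        assert np.allclose(conn.values[0], binned, atol=1e-10)

    def test_trial_modes_and_errors(self, hc_envelopes):
        pooled = mn.imcoh([hc_envelopes], trial_mode="pooled")
        per = mn.imcoh([hc_envelopes], trial_mode="per_trial")
        assert np.allclose(pooled.values, per.values)  # single trial: equal
        other = _env(np.ones((3, 1000)))
        with pytest.raises(ValueError):
            mn.imcoh([hc_envelopes, other])
        with pytest.raises(ValueError):
            mn.imcoh([hc_envelopes], trial_mode="bogus")


def _simulate_var(coefs, n, sd=1.0, seed=0, burn=200):
    rng = np.random.default_rng(seed)
    p, c, _ = coefs.shape
    x = np.zeros((n + burn, c))
    e = sd * rng.standard_normal((n + burn, c))
    for t in range(p, n + burn):
        x[t] = e[t]
        for lag in range(p):
            x[t] += coefs[lag] @ x[t - lag - 1]
    return x[burn:]


VAR3 = np.zeros((3, 3, 3))
VAR3[0] = np.diag([0.5, 0.4, 0.3])
VAR3[2] = np.array([[0.0, 0.3, 0.0], [0.0, 0.0, -0.25], [0.3, 0.0, 0.0]])


class TestFitMvar:
    def test_var3_order_recovered(self):
        x = _simulate_var(VAR3, 10_000, seed=5)
        model = mn.fit_mvar(_env(x.T), max_order=8)
        assert model.order_p == 3
        assert model.stable
        assert min(model.aic_trace, key=model.aic_trace.get) == 3

    def test_var1_coefficients_consistent(self):
        a = np.array([[[0.5, 0.2, 0.0], [0.0, 0.4, -0.2], [0.1, 0.0, 0.3]]])
        x = _simulate_var(a, 100_000, seed=6)
        model = mn.fit_mvar(_env(x.T), max_order=3)
        assert np.abs(model.coefficients[0] - a[0]).max() < 0.05

    def test_white_noise_selects_low_order(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            m = mn.fit_mvar(_env(rng.standard_normal((3, 8000))), max_order=6)
            hits += m.order_p <= 2
        assert hits == 3

    def test_record_too_short(self):
        with pytest.raises(ValueError):
            mn.fit_mvar(_env(np.random.default_rng(0).standard_normal(
                (8, 100))), max_order=20)


class TestPdc:
    def test_diagonal_var_has_zero_cross_pdc(self):
        model = mn.MvarModel(
            order_p=1, coefficients=np.diag([0.5, 0.6, 0.4])[None],
            noise_covariance=np.eye(3), aic_trace={1: 0.0}, stable=True,
            sample_rate_hz=200.0, channel_labels=("a", "b", "c"))
        conn = mn.pdc(model)
        assert np.allclose(conn.values, 0.0, atol=1e-12)

    def test_unidirectional_coupling_recovered(self):
        coefs = np.array([[[0.5, 0.0], [0.7, 0.4]]])  # 1 -> 2 only
        model = mn.MvarModel(
            order_p=1, coefficients=coefs, noise_covariance=np.eye(2),
            aic_trace={1: 0.0}, stable=True, sample_rate_hz=200.0,
            channel_labels=("a", "b"))
        conn = mn.pdc(model)
        fwd = conn.value("a", "b")
        rev = conn.value("b", "a")
        assert fwd.max() > 0.5
        assert np.allclose(rev, 0.0, atol=1e-12)

    def test_column_normalization_identity(self, hc_envelopes):
        model = mn.fit_mvar(hc_envelopes, max_order=6)
        from myonet.connectivity import _a_bar
        a = _a_bar(model, BIN_CENTERS_HZ)
        sums = (np.abs(a) ** 2 / (np.abs(a) ** 2).sum(axis=1,
                                                      keepdims=True)).sum(1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_unstable_model_rejected(self):
        model = mn.MvarModel(
            order_p=1, coefficients=np.array([[[1.2]]]),
            noise_covariance=np.eye(1), aic_trace={1: 0.0}, stable=False,
            sample_rate_hz=200.0, channel_labels=("a",))
        with pytest.raises(ValueError):
            mn.pdc(model)


class TestValidateMvar:
    def test_parametric_bootstrap_self_consistency(self):
        """Data simulated from the fitted model itself: model-implied and
        Welch coherence agree to < 0.1 mean absolute difference."""
        x = _simulate_var(VAR3, 40_000, seed=7)
        env = _env(x.T)
        model = mn.fit_mvar(env, max_order=5)
        welch = mn.imcoh([env])
        report = mn.validate_mvar(model, welch)
        assert report.mean_abs_diff.mean() < 0.1
        assert report.passed

    def test_white_noise_passes(self):
        rng = np.random.default_rng(8)
        env = _env(rng.standard_normal((4, 20_000)))
        model = mn.fit_mvar(env, max_order=4)
        report = mn.validate_mvar(model, mn.imcoh([env]))
        assert report.passed

    def test_mismatched_inputs_rejected(self, hc_envelopes):
        model = mn.fit_mvar(hc_envelopes, max_order=4)
        rng = np.random.default_rng(9)
        other = _env(rng.standard_normal((3, 4000)))
        with pytest.raises(ValueError):
            mn.validate_mvar(model, mn.imcoh([other]))
        with pytest.raises(ValueError):
            mn.validate_mvar(model, mn.pdc(model))


class TestModelCoherence:
    def test_model_coherence_in_unit_interval(self, hc_envelopes):
        model = mn.fit_mvar(hc_envelopes, max_order=6)
        conn = mvar_coherence(model)
        assert (conn.values >= 0).all() and (conn.values <= 1).all()
        assert conn.values.shape == (28, 35)
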