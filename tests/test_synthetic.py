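import dataclasses

import numpy as np
import pytest

import myonet as mn
from myonet.synthetic import DirectedCoupling, DriveBand, with_subject


def _one_synergy_config(**kw):
    base = dict(
        preset_name="custom", n_synergies_true=1,
        synergy_matrix_true=np.array([[1.0, 0.5, 0.2, 0.8, 1.0, 0.5, 0.2,
                                       0.8]]).T,
        recruitment_profiles=np.ones((1, 200)),
        cycle_duration_s=1.0, n_cycles=4, noise_sd=0.0,
        recruitment_jitter=0.0, carrier=False, baseline_level=0.0,
    )
    base.update(kw)
    return mn.GeneratorConfig(**base)


class TestGenerateEmg:
    def test_determinism_bit_identical(self):
        cfg = mn.preset("HC")
        cfg.n_cycles = 6
        cfg.seed = 42
        a = mn.generate_emg(cfg)
        b = mn.generate_emg(cfg)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.heel_strikes["right"], b.heel_strikes["right"])

    def test_constant_recruitment_gives_constant_proportional_envelopes(self):
        rec = mn.generate_emg(_one_synergy_config())
        env = rec.true_envelopes
        assert np.allclose(env, env[:, :1])  # constant in time
        w = np.array([1.0, 0.5, 0.2, 0.8, 1.0, 0.5, 0.2, 0.8])
        ratio = env[:, 0] / w
        assert np.allclose(ratio, ratio[0])

    def test_envelope_structure_is_synergy_product(self):
        cfg = dataclasses.replace(mn.preset("HC"), n_cycles=5, noise_sd=0.0,
                                  recruitment_jitter=0.0, drive_bands=(),
                                  directed_couplings=(), carrier=False,
                                  baseline_level=0.0)
        rec = mn.generate_emg(cfg)
        # rank of the noise-free envelope matrix equals the planted k
        s = np.linalg.svd(rec.true_envelopes, compute_uv=False)
        assert s[1] / s[0] > 1e-3
        assert s[2] / s[0] < 1e-10

    def test_gait_events_consistent_with_cycle_duration(self):
        cfg = dataclasses.replace(mn.preset("HC"), n_cycles=8)
        rec = mn.generate_emg(cfg)
        assert np.allclose(np.diff(rec.heel_strikes["right"]),
                           cfg.cycle_duration_s)
        # toe-offs at the stance fraction inside each cycle
        to = rec.toe_offs["right"][0]
        hs = rec.heel_strikes["right"]
        assert hs[0] < to < hs[1]
        assert to == pytest.approx(hs[0] + 0.6 * cfg.cycle_duration_s)

    def test_directed_coupling_adds_lagged_source_copy(self):
        profile = 0.5 + 0.5 * np.abs(np.sin(np.linspace(0, 2 * np.pi, 200)))
        cfg = _one_synergy_config(
            recruitment_profiles=profile[None, :],
            directed_couplings=(DirectedCoupling("RF_l", "G_r", 30, 0.8),),
        )
        rec = mn.generate_emg(cfg)
        env = rec.true_envelopes
        src = env[mn.MUSCLES.index("RF_l")]
        tgt = env[mn.MUSCLES.index("G_r")]
        # target minus its own synergy part == lagged scaled source fluct.
        own = 0.8 * src  # W ratio G_r/RF_l = 0.8/1.0
        resid = tgt - own
        lagged = 0.8 * (src - src.mean())
        assert np.allclose(resid[30:], lagged[:-30], atol=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(n_synergies_true=0),
        dict(drive_bands=(DriveBand(80.0, 2.0, ("TA_l",), 1.0),)),
        dict(drive_bands=(DriveBand(-1.0, 2.0, ("TA_l",), 1.0),)),
        dict(drive_bands=(DriveBand(10.0, 0.0, ("TA_l",), 1.0),)),
    ])
    def test_invalid_configs_rejected(self, bad):
        cfg = _one_synergy_config()
        for k, v in bad.items():
            setattr(cfg, k, v)
        with pytest.raises(ValueError):
            mn.generate_emg(cfg)

    def test_negative_synergy_matrix_rejected(self):
        cfg = _one_synergy_config()
        cfg.synergy_matrix_true = -cfg.synergy_matrix_true
        with pytest.raises(ValueError):
            mn.generate_emg(cfg)


class TestPresets:
    def test_planted_synergy_counts(self):
        assert mn.preset("HC").n_synergies_true == 2
        assert mn.preset("DM1").n_synergies_true == 5

    def test_preset_is_reproducible(self):
        a, b = mn.preset("HC"), mn.preset("HC")
        assert np.array_equal(a.synergy_matrix_true, b.synergy_matrix_true)
        assert a.drive_bands == b.drive_bands
        assert a.cycle_duration_s == b.cycle_duration_s

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            mn.preset("XYZ")

    def test_hc_synergies_concentrated_on_distal_muscles(self):
        w = mn.preset("HC").synergy_matrix_true
        distal = [mn.MUSCLES.index(m) for m in ("TA_l", "G_l", "TA_r", "G_r")]
        proximal = [i for i in range(8) if i not in distal]
        assert w[distal].sum() > 2 * w[proximal].sum()

    def test_planted_band_recovery_single_drive(self):
        """A strong single drive band dominates the group-mean envelope PSD
        in the 2 Hz bin containing its center frequency."""
        hits = 0
        for seed in range(1, 6):
            cfg = _one_synergy_config(
                recruitment_profiles=0.5 + 0.5 * np.abs(
                    np.sin(np.linspace(0, np.pi, 200)))[None, :],
                n_cycles=30, carrier=True, noise_sd=0.02, seed=seed,
                baseline_level=0.3,
                drive_bands=tuple(DriveBand(21.0, 2.0, (m,), 2.5)
                                  for m in mn.MUSCLES))
            env = mn.make_envelopes(mn.generate_emg(cfg))
            spec = mn.normalized_psd(env)
            mean = spec.psd.mean(axis=0)
            hits += spec.bin_centers_hz[mean.argmax()] == 21.0
        assert hits == 5


class TestCop:
    def test_determinism(self):
        a = mn.generate_cop(3.0, 2.0, seed=5)
        b = mn.generate_cop(3.0, 2.0, seed=5)
        assert np.array_equal(a.xy, b.xy)

    def test_near_zero_sigma_limit_has_vanishing_path(self):
        t = mn.generate_cop(1e-9, 1e-9, duration_s=10, seed=0)
        assert mn.cop_path_length(t) < 1e-5

    def test_stationary_sd_matches_target_on_long_record(self):
        t = mn.generate_cop(4.0, 2.5, duration_s=600, rate_hz=50, seed=3)
        sd = t.xy.std(axis=0)
        assert sd[1] == pytest.approx(4.0, rel=0.10)  # AP = y
        assert sd[0] == pytest.approx(2.5, rel=0.10)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            mn.generate_cop(-1.0, 1.0)
        with pytest.raises(ValueError):
            mn.generate_cop(1.0, 1.0, rate_hz=0.0)


class TestSyntheticConnectivity:
    def test_planted_factors_and_shape(self):
        conn = mn.synthetic_connectivity(seed=0)
        assert conn.values.shape == (28, 35)
        assert (conn.values >= 0).all()
        # planted signatures peak in the bins containing the band centers
        peaks = conn.true_signatures.argmax(axis=1)
        assert [conn.bin_centers_hz[p] for p in peaks] == [5.0, 9.0, 19.0, 35.0]

    def test_noise_free_matrix_has_planted_rank(self):
        conn = mn.synthetic_connectivity(noise_sd=0.0, seed=1)
        s = np.linalg.svd(conn.values, compute_uv=False)
        assert s[3] / s[0] > 1e-3
        assert s[4] / s[0] < 1e-10


class TestIO:
    def test_emg_roundtrip(self, tmp_path):
        cfg = dataclasses.replace(mn.preset("HC"), n_cycles=3, seed=1)
        rec = mn.generate_emg(cfg)
        mn.write_emg_recording(rec, tmp_path / "subj")
        back = mn.read_emg_recording(tmp_path / "subj")
        assert back.channel_labels == rec.channel_labels
        assert np.allclose(back.signal, rec.signal, atol=1e-4)
        assert np.allclose(back.heel_strikes["right"],
                           rec.heel_strikes["right"])

    def test_cop_roundtrip(self, tmp_path):
        t = mn.generate_cop(3.0, 2.0, duration_s=5, seed=2)
        mn.write_cop_trace(t, tmp_path / "cop.tsv")
        back = mn.read_cop_trace(tmp_path / "cop.tsv")
        assert back.sample_rate_hz == t.sample_rate_hz
        assert np.allclose(back.xy, t.xy, atol=1e-4)

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = mn.preset("DM1")
        mn.config_to_yaml(cfg, tmp_path / "cfg.yaml")
        back = mn.config_from_yaml(tmp_path / "cfg.yaml")
        assert back.n_synergies_true == 5
        assert back.drive_bands == cfg.drive_bands
        assert np.allclose(back.synergy_matrix_true, cfg.synergy_matrix_true)

    def test_with_subject_reidentifies(self):
        cfg = mn.preset("HC")
        sub = with_subject(cfg, "HC03", 77)
        assert sub.subject_id == "HC03" and sub.seed == 77
        assert cfg.subject_id != "HC03"


class TestRecordingInvariants:
    def test_heel_strikes_must_increase(self):
        with pytest.raises(ValueError):
            mn.EmgRecording(
                subject_id="x", group="HC", sample_rate_hz=1000,
                channel_labels=mn.MUSCLES, signal=np.zeros((8, 100)),
                heel_strikes={"right": np.array([0.0, 2.0, 1.0])},
                toe_offs={"right": np.array([])})

    def test_channel_labels_unique(self):
        with pytest.raises(ValueError):
            mn.EmgRecording(
                subject_id="x", group="HC", sample_rate_hz=1000,
                channel_labels=("a",) * 8, signal=np.zeros((8, 10)),
                heel_strikes={}, toe_offs={})

    def test_toe_off_must_lie_inside_cycle(self):
        with pytest.raises(ValueError):
            mn.EmgRecording(
                subject_id="x", group="HC", sample_rate_hz=1000,
                channel_labels=mn.MUSCLES, signal=np.zeros((8, 3000)),
                heel_strikes={"right": np.array([0.0, 1.0, 2.0])},
                toe_offs={"right": np.array([1.0])})
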