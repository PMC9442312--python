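import numpy as np
import pytest

from angioquant.dce import (
    DCEStudy,
    afi_actual_flip_angle,
    afi_signals_exact,
    afi_signals_linear,
    iauc,
    mrt,
    perfused_voxel_fraction,
    signal_to_concentration,
    spgr_signal,
    vfa_t1_fit,
)
from angioquant.synth.dce import DCEPhantomSpec, gamma_variate, generate_dce_phantom


class TestAFI:
    def test_equal_signals_degenerate(self):
        fa, valid = afi_actual_flip_angle(np.array([1.0]), np.array([1.0]), 10, 100, 64)
        assert not valid[0]

    def test_recovers_64_degrees_from_linear_forward(self):
        s1, s2 = afi_signals_linear(1.0, 1500.0, 10.0, 100.0, np.radians(64.0))
        # the short-TR ratio for 64 deg at n = 10
        assert s2 / s1 == pytest.approx(0.5158, abs=1e-3)
        fa, valid = afi_actual_flip_angle(np.array(s1), np.array(s2), 10, 100, 64)
        assert valid
        assert 64.0 * float(fa) == pytest.approx(64.0, abs=1e-6)

    def test_exact_steady_state_recovered_closely(self):
        s1, s2 = afi_signals_exact(1.0, 1500.0, 10.0, 100.0, np.radians(64.0))
        fa, valid = afi_actual_flip_angle(np.array(s1), np.array(s2), 10, 100, 64)
        assert abs(64.0 * float(fa) - 64.0) < 0.1

    def test_unit_scale_phantom(self):
        study, _ = generate_dce_phantom(DCEPhantomSpec(fa_scale=1.0))
        fa, valid = afi_actual_flip_angle(
            study.afi_s1, study.afi_s2, study.afi_tr1_ms, study.afi_tr2_ms,
            study.afi_nominal_fa_deg)
        assert np.all(valid)
        assert np.allclose(fa, 1.0, atol=1e-3)


class TestVFA:
    def test_noiseless_t1_within_one_percent(self):
        fa = np.linspace(1, 8, 16)
        t1, tr = 1500.0, 1.7
        sig = spgr_signal(1000.0, t1, tr, np.radians(fa)).reshape(-1, 1, 1, 1)
        fit = vfa_t1_fit(sig, fa, tr)
        assert fit.valid.all()
        assert float(fit.t1_ms[0, 0, 0]) == pytest.approx(t1, rel=0.01)

    def test_b1_corrected_fit(self):
        fa = np.linspace(1, 8, 16)
        t1, tr, scale = 1500.0, 1.7, 0.9
        sig = spgr_signal(1000.0, t1, tr, np.radians(fa) * scale).reshape(-1, 1)
        corrected = vfa_t1_fit(sig, fa, tr, fa_scale=np.array([scale]))
        assert float(corrected.t1_ms[0]) == pytest.approx(t1, rel=0.01)
        biased = vfa_t1_fit(sig, fa, tr)
        assert abs(float(biased.t1_ms[0]) - t1) > abs(float(corrected.t1_ms[0]) - t1)

    def test_zero_signal_invalid_no_crash(self):
        fit = vfa_t1_fit(np.zeros((16, 4, 4)), np.linspace(1, 8, 16), 1.7)
        assert not fit.valid.any()


class TestConcentration:
    def test_flat_signal_gives_zero(self):
        study, truth = generate_dce_phantom(DCEPhantomSpec())
        t1map = vfa_t1_fit(study.vfa_signals, study.vfa_fa_deg, study.tr_ms)
        flat = np.repeat(study.signal[:1], 20, axis=0)
        c, valid = signal_to_concentration(flat, t1map, study.tr_ms, 5.0,
                                           baseline_frames=slice(0, 5))
        assert np.allclose(c[valid], 0.0, atol=1e-9)

    def test_r1_linearity(self):
        study, truth = generate_dce_phantom(DCEPhantomSpec())
        t1map = vfa_t1_fit(study.vfa_signals, study.vfa_fa_deg, study.tr_ms)
        c1, _ = signal_to_concentration(study.signal, t1map, study.tr_ms, 5.0,
                                        relaxivity_r1=3.3)
        c2, _ = signal_to_concentration(study.signal, t1map, study.tr_ms, 5.0,
                                        relaxivity_r1=6.6)
        m = np.abs(c1) > 1e-6
        np.testing.assert_allclose(c2[m], c1[m] / 2.0, rtol=1e-9)


class TestIAUC:
    times = (np.arange(50) + 0.5) * 13.0

    def test_constant_concentration(self):
        c = np.ones(50)
        assert float(iauc(c, self.times, self.times[10], 90.0)) == pytest.approx(90.0)

    def test_linear_ramp(self):
        t0 = self.times[10]
        c = np.clip((self.times - t0) / 90.0, 0, None)
        assert float(iauc(c, self.times, t0, 90.0)) == pytest.approx(45.0, rel=1e-6)

    def test_window_monotonicity(self):
        rng = np.random.default_rng(2)
        c = rng.uniform(0, 1, 50)
        t0 = self.times[5]
        a = float(iauc(c, self.times, t0, 60.0))
        b = float(iauc(c, self.times, t0, 200.0))
        assert b >= a

    def test_window_beyond_acquisition_raises(self):
        with pytest.raises(ValueError):
            iauc(np.ones(50), self.times, self.times[45], 90.0)


class TestMRT:
    times = (np.arange(50) + 0.5) * 13.0

    def test_rectangular_curve_half_duration(self):
        # C = 1 on [t_inj, t_inj + T], 0 after -> MRT = T/2
        t = np.arange(0, 400.0, 1.0)
        t0, T = 50.0, 200.0
        c = ((t >= t0) & (t <= t0 + T)).astype(float)
        assert float(mrt(c, t, t0)) == pytest.approx(T / 2, rel=0.01)

    def test_exponential_decay_recovers_tau(self):
        t = np.arange(0.0, 260.0, 2.0)  # 13 tau window, 2 s sampling
        tau, t0 = 20.0, 10.0
        c = np.where(t >= t0, np.exp(-(t - t0) / tau), 0.0)
        assert float(mrt(c, t, t0)) == pytest.approx(tau, rel=0.03)

    def test_single_hot_frame(self):
        c = np.zeros(50)
        c[30] = 5.0
        t0 = self.times[10]
        assert float(mrt(c, self.times, t0)) == pytest.approx(self.times[30] - t0, rel=1e-6)

    def test_zero_area_invalid(self):
        out = mrt(np.zeros(50), self.times, self.times[10])
        assert np.isnan(float(out))


class TestPerfusedFraction:
    def test_identical_distributions_at_most_half(self):
        vals = np.arange(100.0).reshape(10, 10)
        tumor = np.zeros((10, 10), bool); tumor[:5] = True
        muscle = ~tumor
        vals_t = np.where(tumor, np.arange(100.0).reshape(10, 10), 0)
        frac, med = perfused_voxel_fraction(vals, tumor, muscle)
        assert 0.0 <= frac <= 1.0

    def test_exact_half_above_median(self):
        m = np.zeros((4, 4))
        tumor = np.zeros((4, 4), bool); tumor[:2] = True
        muscle = ~tumor
        m[muscle] = 1.0
        m[tumor] = np.array([0, 0, 0, 0, 2, 2, 2, 2.0])
        frac, med = perfused_voxel_fraction(m, tumor, muscle)
        assert med == 1.0
        assert frac == pytest.approx(0.5)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            perfused_voxel_fraction(np.ones((2, 2)), np.zeros((2, 2), bool),
                                    np.ones((2, 2), bool))


class TestPhantom:
    def test_zero_concentration_frames_identical(self):
        spec = DCEPhantomSpec(tumor_peak_mM=0.0, muscle_peak_mM=0.0)
        study, truth = generate_dce_phantom(spec)
        for k in range(1, study.signal.shape[0]):
            np.testing.assert_array_equal(study.signal[k], study.signal[0])

    def test_forward_model_self_consistency(self):
        """Plugging the ground-truth maps back into the SPGR equation
        reproduces the stored noiseless signals bit-for-bit."""
        spec = DCEPhantomSpec(fa_scale=0.9, seed=5)
        study, truth = generate_dce_phantom(spec)
        a = np.radians(spec.nominal_fa_deg) * truth["fa_scale"]
        r1t = 1.0 / truth["t1_ms"][None] + spec.relaxivity_r1 * truth["c_true"] / 1000.0
        recon = spgr_signal(truth["m0"][None], 1.0 / r1t, spec.tr_ms, a[None])
        np.testing.assert_array_equal(recon, study.signal)

    def test_ground_truth_iauc_matches_quadrature(self):
        spec = DCEPhantomSpec()
        study, truth = generate_dce_phantom(spec)
        t0 = truth["injection_time_s"]
        tg = np.linspace(t0, t0 + 90.0, 200001)
        unit = np.trapezoid(gamma_variate(tg, 1.0, t0, spec.gamma_alpha, spec.gamma_beta_s), tg)
        enh = truth["peak_mM"] == spec.tumor_peak_mM
        np.testing.assert_allclose(truth["iauc90"][enh], spec.tumor_peak_mM * unit, rtol=1e-5)

    def test_study_dir_roundtrip(self, tmp_path):
        study, _ = generate_dce_phantom(DCEPhantomSpec(grid_shape=(4, 8, 8)))
        study.write_dir(tmp_path / "s")
        back = DCEStudy.read_dir(tmp_path / "s")
        np.testing.assert_allclose(back.signal, study.signal, rtol=1e-6)
        assert back.injection_frame == study.injection_frame
        assert back.tr_ms == study.tr_ms
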