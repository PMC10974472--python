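"""Tests of filtering, COP/COM kinematics, event detection and feature
extraction."""

import numpy as np
import pytest

from gipca.kinetics import (
    G,
    GaitEventError,
    GIEvents,
    GIFeatures,
    TrialRecording,
    com_kinematics,
    compute_cop,
    detect_events,
    extract_features,
    lowpass_filter,
)
from gipca.registry import FEATURES
from gipca.synthetic import TrialSpec, simulate_trial

FS = 500.0


def _quiet_standing(mass=70.0, duration=3.0, noise=0.0, seed=0):
    n = int(duration * FS)
    t = np.arange(n) / FS
    F = np.zeros((n, 3))
    F[:, 2] = mass * G
    M = np.zeros((n, 3))
    if noise:
        r = np.random.default_rng(seed)
        F += r.normal(0, noise, F.shape)
        M += r.normal(0, noise * 0.3, M.shape)
    return TrialRecording(t=t, F=F, M=M, fs=FS, mass=mass)


class TestLowpass:
    def test_dc_gain_is_unity(self):
        x = np.full(2000, 3.7)
        assert np.allclose(lowpass_filter(x, FS), 3.7)

    def test_single_pass_half_power_at_cutoff(self):
        """A pure sinusoid at the cut-off comes through a single-pass
        2nd-order Butterworth at 1/sqrt(2) amplitude; the zero-phase
        (two-pass) application squares that to 1/2."""
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y1 = lowpass_filter(x, FS, fc=10.0, zero_phase=False)
        steady = slice(int(5 * FS), int(18 * FS))
        amp1 = np.sqrt(2) * y1[steady].std()
        assert amp1 == pytest.approx(1 / np.sqrt(2), rel=1e-3)
        y2 = lowpass_filter(x, FS, fc=10.0, zero_phase=True)
        amp2 = np.sqrt(2) * y2[steady].std()
        assert amp2 == pytest.approx(0.5, rel=1e-3)

    def test_high_frequency_attenuated_40x(self):
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 100.0 * t)
        y = lowpass_filter(x, FS)
        # residual at 100 Hz after removing the (preserved) 1 Hz component
        resid = y - lowpass_filter(np.sin(2 * np.pi * 1.0 * t), FS)
        inner = slice(int(FS), int(7 * FS))
        atten = np.sqrt(0.5) / resid[inner].std()
        assert atten > 40

    def test_passband_idempotence(self):
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 1.5 * t) + 0.5 * np.cos(2 * np.pi * 0.7 * t)
        y = lowpass_filter(x, FS)
        inner = slice(int(FS), int(7 * FS))
        rms = np.sqrt(np.mean((y[inner] - x[inner]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(x[inner] ** 2))

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(np.zeros(100), FS, fc=300.0)


class TestCop:
    def test_point_load_at_origin(self):
        rec = _quiet_standing()
        assert np.allclose(compute_cop(rec), 0.0)

    def test_direct_moment_ratio(self):
        rec = _quiet_standing(mass=700 / G)
        rec.M[:, 0] = 21.0  # Mx -> COP_y = 21/700
        cop = compute_cop(rec)
        assert np.allclose(cop[:, 1], 0.03)
        assert np.allclose(cop[:, 0], 0.0)

    def test_low_load_samples_flagged_invalid(self):
        rec = _quiet_standing()
        rec.F[100:110, 2] = 5.0  # below the 10 N threshold
        cop = compute_cop(rec)
        assert np.isnan(cop[100:110]).all()
        assert np.isfinite(cop[:100]).all()


class TestComKinematics:
    def test_quiet_standing_velocity_zero(self):
        rec = _quiet_standing()
        kin = com_kinematics(rec, t0=1.0)
        assert np.allclose(kin["vel_ap"], 0.0, atol=1e-12)
        assert np.allclose(kin["vel_ml"], 0.0, atol=1e-12)

    def test_constant_force_linear_velocity(self):
        rec = _quiet_standing(mass=70.0)
        c = 0.8  # m/s^2
        t0 = 1.0
        rec.F[:, 1] = np.where(rec.t >= t0, 70.0 * c, 0.0)
        kin = com_kinematics(rec, t0=t0, baseline_s=0.5)
        late = rec.t > t0 + 0.3  # past the filter edge of the step
        expect = c * (rec.t[late] - t0)
        assert np.allclose(kin["vel_ap"][late], expect, atol=5e-3)

    def test_sinusoidal_force_matches_analytic_integral(self):
        rec = _quiet_standing(mass=70.0)
        f0 = 1.0  # Hz, well inside the passband
        rec.F[:, 1] = 70.0 * np.sin(2 * np.pi * f0 * rec.t)
        # t0 at one full period: v(t0) = 0 matches the analytic integral
        kin = com_kinematics(rec, t0=1.0, baseline_s=1.0)
        # v(t) = (1 - cos(2 pi f t)) / (2 pi f), from a(t) = sin(2 pi f t)
        expect = (1 - np.cos(2 * np.pi * f0 * rec.t)) / (2 * np.pi * f0)
        # baseline correction subtracts the near-zero early mean; compare
        # shapes after aligning the integration constant
        err = kin["vel_ap"] - expect
        assert np.std(err[200:-200]) < 2e-3

    def test_mass_validated(self):
        with pytest.raises(ValueError, match="mass"):
            _quiet_standing(mass=-1.0)


class TestEvents:
    def test_noiseless_recovery_within_one_sample(self, noiseless_trial):
        ev = detect_events(noiseless_trial)
        gt = noiseless_trial.ground_truth["events"]
        dt = 1.0 / noiseless_trial.fs
        for name in ("t0", "HO", "TO", "HC"):
            assert abs(getattr(ev, name) - getattr(gt, name)) <= dt + 1e-12

    def test_quiet_standing_raises_no_gait_initiation(self):
        with pytest.raises(GaitEventError, match="no gait initiation"):
            detect_events(_quiet_standing(noise=0.3))

    def test_noisy_median_error_below_10ms(self):
        errs = []
        for seed in range(20):
            rec = simulate_trial(
                TrialSpec(noise_sd=0.3, seed=seed, ml_onset_delay=0.05))
            ev = detect_events(rec)
            gt = rec.ground_truth["events"]
            errs += [abs(getattr(ev, k) - getattr(gt, k))
                     for k in ("t0", "HO", "TO", "HC")]
        assert np.median(errs) <= 0.010

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            GIEvents(t0=1.0, HO=1.3, TO=1.2, HC=1.8)


class TestFeatures:
    TOL = {  # noiseless recovery tolerances: discretization + filter edge
        "apa_ml": 0.004, "apa_ap": 0.004, "foot_lift": 0.002,
        "cop_shift_ap": None, "cop_shift_ml": None,
        "vcom_ap_ho": None, "vcom_ap_to": None, "vcom_ap_hc": None,
        "vcom_ml_ho": None, "vcom_ml_to": None, "fz_peak": None,
    }

    def test_noiseless_features_match_ground_truth(self, noiseless_trial):
        feats = extract_features(noiseless_trial)
        gt = noiseless_trial.ground_truth["features"].as_dict()
        for name, val in feats.as_dict().items():
            tol = self.TOL[name]
            if tol is not None:
                assert val == pytest.approx(gt[name], abs=tol), name
            else:
                assert val == pytest.approx(gt[name], rel=0.01), name

    def test_footlift_positive_invariant(self):
        kwargs = dict(apa_ml=0.3, apa_ap=0.3, cop_shift_ap=0.03,
                      cop_shift_ml=0.04, vcom_ap_ho=0.1, vcom_ap_to=0.4,
                      vcom_ap_hc=0.9, vcom_ml_ho=0.1, vcom_ml_to=0.15,
                      fz_peak=800.0)
        with pytest.raises(ValueError, match="foot_lift"):
            GIFeatures(foot_lift=0.0, **kwargs)

    def test_doubling_peak_only_scales_fz_peak(self):
        base = simulate_trial(TrialSpec(noise_sd=0.0, fz_peak=824.0))
        tall = simulate_trial(TrialSpec(noise_sd=0.0, fz_peak=1648.0))
        fb = extract_features(base).as_dict()
        ft = extract_features(tall).as_dict()
        assert ft["fz_peak"] / fb["fz_peak"] == pytest.approx(2.0, rel=0.01)
        for name in FEATURES:
            if name != "fz_peak":
                assert ft[name] == pytest.approx(fb[name], rel=1e-6), name

    def test_time_shift_invariance(self):
        """Shifting every event by a constant leaves all durations and
        amplitudes unchanged."""
        a = simulate_trial(TrialSpec(noise_sd=0.0))
        shift = 0.4
        ev = {k: v + shift for k, v in
              TrialSpec().event_times.items()}
        b = simulate_trial(TrialSpec(noise_sd=0.0, duration=3.0 + shift,
                                     event_times=ev))
        fa, fb = extract_features(a).as_dict(), extract_features(b).as_dict()
        for name in FEATURES:
            assert fb[name] == pytest.approx(fa[name], rel=1e-6, abs=1e-9), name

    def test_events_outside_recording_rejected(self, noiseless_trial):
        bad = GIEvents(t0=1.0, HO=1.3, TO=1.45, HC=5.0)
        with pytest.raises(ValueError, match="span"):
            extract_features(noiseless_trial, bad)
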