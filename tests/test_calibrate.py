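"""Fringe calibration: profiles, high-pass, peak tracking, phase fit, round trip."""

import math

import numpy as np
import pandas as pd
import pytest

import fringeflow as ff
from fringeflow import calibrate as cal
from fringeflow.stackio import META_COLUMNS, FrameStack

PERIOD_PX = 7.3015  # 791 nm carrier at the 108.33 nm object pixel


def _sinusoid(n=700, period=PERIOD_PX, phase=0.0, amp=1.0):
    x = np.arange(n, dtype=float)
    return amp * np.cos(2 * np.pi * x / period + phase)


def _stack_from_frames(frames, voltages):
    rows = [
        (i, 0.0, v, np.nan, 0.0, 0.0) for i, v in enumerate(voltages)
    ]
    return FrameStack(np.stack(frames).astype(np.float32), pd.DataFrame(rows, columns=META_COLUMNS))


class TestAverageRepetitions:
    def test_identical_frames_pass_through(self):
        f = np.random.default_rng(0).normal(100, 1, (8, 8)).astype(np.float32)
        stack = _stack_from_frames([f] * 8, [3.0] * 8)
        avg = cal.average_repetitions(stack)
        assert len(avg) == 1
        assert np.allclose(avg.frames[0], f)

    def test_noise_reduced_by_sqrt_n(self):
        rng = np.random.default_rng(1)
        frames = [rng.normal(0, 1, (64, 64)) for _ in range(8)]
        stack = _stack_from_frames(frames, [2.0] * 8)
        avg = cal.average_repetitions(stack)
        assert avg.frames[0].std() == pytest.approx(1 / math.sqrt(8), rel=0.1)

    def test_grouping_by_voltage(self):
        rng = np.random.default_rng(2)
        frames = [rng.normal(0, 1, (8, 8)) for _ in range(6)]
        stack = _stack_from_frames(frames, [2.0, 3.0] * 3)
        avg = cal.average_repetitions(stack)
        assert len(avg) == 2
        assert avg.meta["voltage_v"].to_list() == [2.0, 3.0]

    def test_unequal_repetition_counts_rejected(self):
        frames = [np.zeros((4, 4))] * 5
        stack = _stack_from_frames(frames, [2.0, 2.0, 2.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            cal.average_repetitions(stack)


class TestExtractProfile:
    def test_constant_frame(self):
        assert np.allclose(cal.extract_profile(np.full((10, 20), 7.0), (2, 8)), 7.0)

    def test_single_row_band_is_verbatim(self):
        frame = np.arange(50, dtype=float).reshape(5, 10)
        assert np.array_equal(cal.extract_profile(frame, (2, 3)), frame[2])

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            cal.extract_profile(np.zeros((5, 10)), (3, 3))


class TestHighpass:
    def test_carrier_preserved_within_2pct(self):
        prof = 100.0 + _sinusoid(amp=10.0)
        hp = cal.highpass_profile(prof, PERIOD_PX)
        # compare amplitude in the central region (away from FFT edge effects)
        sl = slice(50, 650)
        assert hp[sl].max() == pytest.approx(10.0, rel=0.02)

    def test_smooth_envelope_rejected(self):
        x = np.arange(700, dtype=float)
        env = 50.0 * np.exp(-0.5 * ((x - 350) / (5 * PERIOD_PX)) ** 2)
        hp = cal.highpass_profile(env, PERIOD_PX)
        assert np.abs(hp).max() <= 0.05 * env.max()

    def test_constant_profile_maps_to_zero(self):
        hp = cal.highpass_profile(np.full(700, 42.0), PERIOD_PX)
        assert np.allclose(hp, 0.0, atol=1e-9)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            cal.highpass_profile(np.zeros(20), PERIOD_PX)


class TestDetectPeaks:
    def test_sinusoid_peak_count_and_spacing(self):
        peaks = cal.detect_peaks(_sinusoid(phase=0.5))
        assert len(peaks) in (95, 96)
        assert np.diff(peaks).mean() == pytest.approx(PERIOD_PX, abs=0.05)

    def test_symmetric_triangles_land_on_grid(self):
        prof = np.zeros(60)
        for k in (15, 30, 45):
            prof[k - 3 : k + 4] = [1, 2, 3, 4, 3, 2, 1]
        peaks = cal.detect_peaks(prof)
        assert np.allclose(peaks, [15, 30, 45], atol=1e-12)

    def test_subpixel_shift_recovered(self):
        a = cal.detect_peaks(_sinusoid(phase=0.3))
        b = cal.detect_peaks(_sinusoid(phase=0.3 - 2 * np.pi * 0.25 / PERIOD_PX))
        n = min(len(a), len(b))
        shifts = b[:n] - a[:n]
        # per-peak parabolic bias oscillates ~0.02 px on a 7.3 px carrier;
        # it averages out over the >20 peaks the pipeline uses
        assert np.allclose(shifts, 0.25, atol=0.03)
        assert shifts.mean() == pytest.approx(0.25, abs=0.005)

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            cal.detect_peaks(np.array([0.0, 1.0, 0.0, 0.0]))


class TestShiftAndPeriod:
    def test_identical_peak_sets_give_zero_shift(self):
        p = cal.detect_peaks(_sinusoid())
        core = cal.estimate_shift_and_period([p, p.copy()])
        assert core["shifts_px"] == [0.0]
        assert np.allclose(core["phases_rad"], 0.0)

    def test_third_period_translation(self):
        phase_step = 2 * np.pi / 3
        a = cal.detect_peaks(_sinusoid(phase=0.2))
        b = cal.detect_peaks(_sinusoid(phase=0.2 + phase_step))
        core = cal.estimate_shift_and_period([a, b])
        assert abs(core["phases_rad"][1]) == pytest.approx(phase_step, abs=0.02)

    def test_half_period_jump_rejected(self):
        a = cal.detect_peaks(_sinusoid(phase=0.0))
        b = cal.detect_peaks(_sinusoid(phase=np.pi))  # displacement exactly p/2
        with pytest.raises(ValueError):
            cal.estimate_shift_and_period([a, b])

    def test_quadratic_law_roundtrip_noise_free(self):
        a_true = (4 * math.pi / 3) / 5.86**2
        volts = np.arange(2.0, 7.6, 0.5)
        peaks = [
            cal.detect_peaks(_sinusoid(phase=0.1 + a_true * v**2)) for v in volts
        ]
        core = cal.estimate_shift_and_period(peaks, volts.tolist())
        fit = cal.fit_phase_vs_voltage(np.array(core["phases_rad"]), volts)
        phases = np.array(core["phases_rad"])
        model = fit["coeff_rad_per_v2"] * (volts**2 - volts[0] ** 2)
        ss_res = np.sum((phases - model) ** 2)
        ss_tot = np.sum((phases - phases.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999
        assert fit["coeff_rad_per_v2"] == pytest.approx(a_true, rel=0.01)


class TestPhaseFit:
    def test_closed_form_inversion(self):
        a = (4 * math.pi / 3) / 5.86**2
        v = np.arange(0.0, 6.1, 0.5)
        fit = cal.fit_phase_vs_voltage(a * v**2, v)
        assert fit["solved_voltages_v"]["2pi/3"] == pytest.approx(4.14, abs=0.005)
        assert fit["solved_voltages_v"]["4pi/3"] == pytest.approx(5.86, abs=0.005)
        assert fit["fit_residual_rms_rad"] == pytest.approx(0.0, abs=1e-12)

    def test_coefficient_scaling_law(self):
        a = (4 * math.pi / 3) / 5.86**2
        v = np.arange(0.0, 6.1, 0.5)
        f1 = cal.fit_phase_vs_voltage(a * v**2, v)
        f2 = cal.fit_phase_vs_voltage(2 * a * v**2, v)
        ratio = f2["solved_voltages_v"]["2pi/3"] / f1["solved_voltages_v"]["2pi/3"]
        assert ratio == pytest.approx(1 / math.sqrt(2), abs=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cal.fit_phase_vs_voltage(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestEndToEnd:
    def test_noise_free_recovery(self, cfg, psm, sheet):
        cam = ff.CameraModel(roi_px=(64, 700), frame_rate_hz=100.0)
        proto = ff.AcquisitionProtocol(mode="calibration_sweep", sweep_repetitions=1)
        extent = (700 * cfg.pixel_um, 64 * cfg.pixel_um, 8.0)
        dye = ff.make_dye_phantom(extent, 50.0, seed=21)
        stack = ff.run_calibration_sweep(dye, cfg, sheet, psm, cam, proto, seed=0, noise=False)
        res = cal.calibrate_sweep(stack, cfg, row_band=(8, 56))
        true_p = cfg.carrier_period_effective_nm() * 1e-3 / cfg.pixel_um
        a_true = psm.phi_ref_rad / psm.v_ref_v**2
        assert res.period_px == pytest.approx(true_p, rel=0.005)
        assert res.coeff_rad_per_v2 == pytest.approx(a_true, rel=0.01)
        assert not res.low_confidence and res.monotone
        assert all(n >= 21 for n in res.peaks_used)

    def test_envelope_invariance_of_phases(self, cfg, psm, sheet, dye_sweep):
        # multiplying profiles by a smooth Gaussian envelope must not move phases
        stack, _ = dye_sweep
        res_plain = cal.calibrate_sweep(stack, cfg, row_band=(8, 56))
        n = stack.shape[1]
        x = np.arange(n)
        env = np.exp(-0.5 * ((x - n / 2) / (4 * PERIOD_PX)) ** 2).astype(np.float32)
        mod_frames = stack.frames * env[None, None, :]
        mod = FrameStack(mod_frames, stack.meta.copy())
        res_env = cal.calibrate_sweep(mod, cfg, row_band=(8, 56))
        assert np.allclose(res_env.phases_rad, res_plain.phases_rad, atol=0.05)

    def test_recovery_with_default_noise(self, cfg, dye_sweep):
        stack, _ = dye_sweep
        res = cal.calibrate_sweep(stack, cfg, row_band=(8, 56))
        true_p = cfg.carrier_period_effective_nm() * 1e-3 / cfg.pixel_um
        assert res.period_px == pytest.approx(true_p, rel=0.01)
        assert res.period_nm == pytest.approx(791.0, rel=0.01)
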