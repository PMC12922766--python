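"""Fringe-phase estimation, phase-voltage curves, bead contrast, MZI extrema."""

import math

import numpy as np
import pytest

from chipsim.calibration import (
    CalibrationCurve,
    PatternNotDetectedError,
    bead_contrast,
    curve_variability,
    estimate_pattern_phase,
    find_contrast_extrema,
    phase_voltage_curve,
)
from chipsim.device import find_balance_voltage
from chipsim.optics import IlluminationPattern
from chipsim.phantoms import (
    ImageStack,
    NoiseModel,
    acquire_series,
    detection_psf,
    make_bead_phantom,
    make_sheet_phantom,
    render,
)


def cosine_frame(shape, freq, phase, amplitude=100.0, offset=500.0):
    x = np.arange(shape[1])
    return np.broadcast_to(
        offset + amplitude * np.cos(2 * math.pi * freq * x + phase), shape
    ).copy()


class TestEstimatePatternPhase:
    def test_recovers_phase_difference(self):
        f = 0.23
        a = estimate_pattern_phase(cosine_frame((64, 128), f, 0.0), f)
        b = estimate_pattern_phase(cosine_frame((64, 128), f, math.pi / 2), f)
        assert (b - a) % (2 * math.pi) == pytest.approx(math.pi / 2, abs=0.02)

    def test_invariant_to_intensity_scale(self):
        f = 0.19
        frame = cosine_frame((64, 128), f, 1.1)
        assert estimate_pattern_phase(frame, f) == pytest.approx(
            estimate_pattern_phase(3.0 * frame, f), abs=1e-12
        )

    def test_full_period_translation_wraps_to_zero(self):
        f = 0.25
        a = estimate_pattern_phase(cosine_frame((64, 128), f, 0.4), f)
        b = estimate_pattern_phase(cosine_frame((64, 128), f, 0.4 + 2 * math.pi), f)
        wrapped = (b - a + math.pi) % (2 * math.pi) - math.pi
        assert wrapped == pytest.approx(0.0, abs=1e-9)

    def test_no_pattern_raises(self):
        flat = np.full((64, 128), 100.0)
        with pytest.raises(PatternNotDetectedError):
            estimate_pattern_phase(flat, 0.2)


class TestPhaseVoltageCurve:
    def test_recovers_heater_law(self, sheet_calibration_stack, device_state):
        curve = phase_voltage_curve(sheet_calibration_stack)
        heater = device_state.output_heater
        truth = np.array([heater.phase(v, 638.0) for v in curve.voltages])
        assert np.abs(curve.phases_rad - truth).max() < 0.03

    def test_quadratic_ratio_property(self, sheet_calibration_stack):
        # thermal phase ~ V^2: phase(V) / phase(V/2) = 4
        curve = phase_voltage_curve(sheet_calibration_stack)
        v = curve.voltages
        p = dict(zip(v, curve.phases_rad))
        assert p[12.0] / p[6.0] == pytest.approx(4.0, rel=0.02)

    def test_identical_frames_give_zero_curve(self, device_state, train):
        sheet = make_sheet_phantom((64, 64), 65.0)
        stack = acquire_series(
            device_state, train, sheet, "calibration", voltages=[0.0, 0.0, 0.0]
        )
        curve = phase_voltage_curve(stack)
        assert curve.phases_rad == pytest.approx(np.zeros(3), abs=1e-9)

    def test_random_heater_parameter_recovery(self, device_state, train):
        # the estimator recovers 20 random quadratic phase laws
        from chipsim.device import HeaterModel

        rng = np.random.default_rng(21)
        sheet = make_sheet_phantom((64, 64), 65.0)
        voltages = list(np.linspace(0.0, 12.0, 9))
        for _ in range(20):
            kappa = rng.uniform(0.4, 1.4) * 50.635
            heater = HeaterModel(kappa_K_per_W=kappa)
            st = device_state.replace(output_heater=heater)
            stack = acquire_series(st, train, sheet, "calibration", voltages=voltages)
            curve = phase_voltage_curve(stack)
            truth = np.array([heater.phase(v, 638.0) for v in voltages])
            assert np.abs(curve.phases_rad - truth).max() < 0.05


class TestCurveVariability:
    def test_identical_curves_zero_spread(self):
        c = CalibrationCurve(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 4.0]))
        _, summary = curve_variability([c, c, c])
        assert summary == 0.0

    def test_hand_arithmetic(self):
        # two curves valued 1.0 and 1.2 at one voltage: sd/mean = 12.86 %
        a = CalibrationCurve(np.array([0.0, 5.0]), np.array([0.0, 1.0]))
        b = CalibrationCurve(np.array([0.0, 5.0]), np.array([0.0, 1.2]))
        rel_sd, summary = curve_variability([a, b])
        assert rel_sd[1] == pytest.approx(np.std([1.0, 1.2], ddof=1) / 1.1)
        assert summary == pytest.approx(12.86, abs=0.01)

    def test_recovers_injected_noise_level(self):
        rng = np.random.default_rng(17)
        v = np.linspace(0.0, 12.0, 13)
        truth = 2 * math.pi * (v / 12.0) ** 2
        curves = []
        for _ in range(10):
            noisy = truth * (1 + rng.normal(0, 0.02, size=truth.shape))
            noisy[0] = 0.0
            curves.append(CalibrationCurve(v, noisy))
        _, summary = curve_variability(curves)
        assert 1.5 < summary < 2.5  # injected 2 %, within Monte-Carlo error

    def test_mismatched_grids_rejected(self):
        a = CalibrationCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        b = CalibrationCurve(np.array([0.0, 2.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            curve_variability([a, b])


def synthetic_bead_stack(modulation, n_phases=24, b=100.0, field=(128, 128),
                         n_beads=30, seed=5, mean_intensity=1.0, gain=1.0):
    """Noise-free phase-stepped bead frames at a prescribed modulation."""
    beads = make_bead_phantom(n_beads, field, 65.0, min_spacing_px=10.0, seed=seed)
    psf = detection_psf(1.49, 638.0)
    frames, meta = [], []
    for k in range(n_phases):
        phase = 2 * math.pi * k / n_phases
        illum = IlluminationPattern(
            period_nm=283.6, modulation=modulation, phase_rad=phase,
            mean_intensity=mean_intensity,
        )
        frames.append(
            render(beads, illum, psf, NoiseModel(dark_offset=b, gain=gain))
        )
        meta.append({"mode": "structured", "phase_rad": phase, "period_nm": 283.6})
    return beads, ImageStack(
        frames=np.stack(frames), meta=meta, pixel_size_nm=65.0, camera_offset=b
    )


class TestBeadContrast:
    @pytest.mark.parametrize("m", [0.25, 0.5, 0.91, 1.0])
    def test_recovers_known_modulation(self, m):
        _, stack = synthetic_bead_stack(m)
        report = bead_contrast(stack, n_brightest=30)
        assert report.mean == pytest.approx(m, abs=0.01 * max(m, 0.1))

    def test_direct_formula(self):
        # one bead pixel cycling 110 <-> 30 with dark level 20: C = 80/100
        frames = np.full((5, 16, 16), 20.0)
        vals = [110.0, 70.0, 30.0, 70.0, 110.0]
        for f, v in zip(frames, vals):
            f[8, 8] = v
        stack = ImageStack(
            frames=frames,
            meta=[{"phase_rad": p} for p in np.linspace(0, 2 * math.pi, 5)],
            pixel_size_nm=65.0,
            camera_offset=20.0,
        )
        report = bead_contrast(stack, b=20.0, n_brightest=1,
                               positions=np.array([[8, 8]]))
        assert report.contrasts[0] == pytest.approx(0.8)

    def test_uniform_illumination_gives_zero(self):
        _, stack = synthetic_bead_stack(0.0)
        report = bead_contrast(stack, n_brightest=30)
        assert report.mean == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_dark_level_and_gain(self):
        _, a = synthetic_bead_stack(0.7, b=100.0)
        _, c = synthetic_bead_stack(0.7, b=400.0)
        _, g = synthetic_bead_stack(0.7, b=100.0, gain=3.0)
        ra = bead_contrast(a, n_brightest=30)
        rc = bead_contrast(c, n_brightest=30)
        rg = bead_contrast(g, n_brightest=30)
        assert rc.mean == pytest.approx(ra.mean, rel=0.01)
        assert rg.mean == pytest.approx(ra.mean, rel=0.01)

    def test_sheet_underestimates_by_mtf_factor(self):
        # extended sample: measured contrast = modulation x MTF(pattern freq);
        # beads escape the attenuation — the rationale for the bead slide
        m = 0.8
        psf = detection_psf(1.49, 638.0)
        sheet = make_sheet_phantom((128, 128), 65.0, 1000.0)
        frames, meta = [], []
        for k in range(24):
            phase = 2 * math.pi * k / 24
            illum = IlluminationPattern(
                period_nm=283.6, modulation=m, phase_rad=phase, mean_intensity=1.0
            )
            frames.append(render(sheet, illum, psf, NoiseModel()))
            meta.append({"phase_rad": phase, "period_nm": 283.6})
        stack = ImageStack(frames=np.stack(frames), meta=meta,
                           pixel_size_nm=65.0, camera_offset=100.0)
        grid = np.array([[r, c] for r in (40, 64, 88) for c in (40, 64, 88)])
        sheet_report = bead_contrast(stack, n_brightest=9, positions=grid)
        mtf = psf.mtf(1.0 / 283.6)
        assert sheet_report.mean == pytest.approx(m * mtf, rel=0.02)

        _, bstack = synthetic_bead_stack(m)
        bead_report = bead_contrast(bstack, n_brightest=30)
        assert bead_report.mean == pytest.approx(m, rel=0.01)

    def test_warns_when_fewer_beads_than_requested(self):
        _, stack = synthetic_bead_stack(0.9, n_beads=5, seed=8)
        with pytest.warns(UserWarning, match="beads available"):
            report = bead_contrast(stack, n_brightest=100)
        assert report.n_used <= 5

    def test_too_few_phase_steps_rejected(self):
        _, stack = synthetic_bead_stack(0.9, n_phases=24)
        short = ImageStack(frames=stack.frames[:3], meta=stack.meta[:3],
                           pixel_size_nm=65.0, camera_offset=100.0)
        with pytest.raises(ValueError, match="phase steps"):
            bead_contrast(short)


class TestFindContrastExtrema:
    def test_max_contrast_at_balance_voltage(self, device_state):
        grid = np.linspace(0.0, 12.0, 241)
        out = find_contrast_extrema(device_state, grid)
        v_balance = find_balance_voltage(device_state)
        step = grid[1] - grid[0]
        assert abs(out["v_max_contrast"] - v_balance) <= step
        assert out["max_modulation"] == pytest.approx(0.99, abs=1e-3)

    def test_unbalanced_coupler_extremes(self, device_state):
        # R = 0.819 at 561 nm: over a full MZI period the contrast minimum
        # is the single-beam state (device SR = 1, modulation ~ 0) and the
        # maximum is the balanced split (modulation 1); at zero voltage the
        # split is 0.407/0.593, a high but not extremal fringe
        st = device_state.replace(wavelength_nm=561.0, background_fraction=0.0)
        grid = np.linspace(0.0, 12.0, 241)
        out = find_contrast_extrema(st, grid)
        assert out["min_modulation"] == pytest.approx(0.0, abs=0.01)
        v_single = st.mzi_heater.voltage_for_phase(math.pi, 561.0)
        assert abs(out["v_min_contrast"] - v_single) <= grid[1] - grid[0]
        assert out["max_modulation"] == pytest.approx(1.0, abs=1e-6)
        r0 = 1.0 - 4 * 0.819 * 0.181
        zero_v_mod = out["modulations"][0]
        assert zero_v_mod == pytest.approx(2 * math.sqrt(r0 * (1 - r0)), abs=1e-3)

    def test_grid_refinement_halves_localization_error(self, device_state):
        v_balance = find_balance_voltage(device_state)
        coarse = find_contrast_extrema(device_state, np.linspace(0, 12, 25))
        fine = find_contrast_extrema(device_state, np.linspace(0, 12, 49))
        err_c = abs(coarse["v_max_contrast"] - v_balance)
        err_f = abs(fine["v_max_contrast"] - v_balance)
        assert err_f <= err_c + 1e-12
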