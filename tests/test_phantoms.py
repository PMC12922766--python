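"""Phantom generators, detection PSF, forward rendering, acquisition series."""

import math

import numpy as np
import pytest

from chipsim.optics import IlluminationPattern
from chipsim.phantoms import (
    ImageStack,
    NoiseModel,
    acquire_series,
    detection_psf,
    make_bead_phantom,
    make_sectioning_phantom,
    make_sheet_phantom,
    render,
)


class TestBeadPhantom:
    def test_count_spacing_and_determinism(self):
        ph = make_bead_phantom(100, (256, 256), 65.0, min_spacing_px=8.0, seed=7)
        assert len(ph.bead_centers) == 100
        # brute-force pairwise distances respect the minimum spacing
        d2 = ((ph.bead_centers[:, None] - ph.bead_centers[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= 8.0**2
        again = make_bead_phantom(100, (256, 256), 65.0, min_spacing_px=8.0, seed=7)
        assert np.array_equal(ph.planes, again.planes)
        assert np.array_equal(ph.bead_centers, again.bead_centers)

    def test_single_bead_is_an_impulse(self):
        ph = make_bead_phantom(1, (64, 64), 65.0, seed=0, brightness_range=(5.0, 5.0))
        assert np.count_nonzero(ph.planes) == 1
        (cy, cx) = ph.bead_centers[0]
        assert ph.planes[0, int(round(cy)), int(round(cx))] == 5.0

    def test_overcrowded_field_is_an_error(self):
        with pytest.raises(ValueError, match="could not place"):
            make_bead_phantom(500, (64, 64), 65.0, min_spacing_px=10.0, seed=0)


class TestSectioningPhantom:
    def test_planes_have_disjoint_structure(self):
        ph = make_sectioning_phantom((128, 128), 65.0, n_planes=2, seed=5)
        # each plane's fluorophores lie inside its own annotated region
        for k in range(2):
            assert ph.planes[k][~ph.plane_masks[k]].sum() == 0
            assert ph.planes[k][ph.plane_masks[k]].sum() > 0
        assert not np.any(ph.plane_masks[0] & ph.plane_masks[1])

    def test_mass_conservation_and_determinism(self):
        ph = make_sectioning_phantom((128, 128), 65.0, n_planes=3, seed=5)
        assert ph.planes.sum() == pytest.approx(
            sum(ph.planes[k].sum() for k in range(3))
        )
        again = make_sectioning_phantom((128, 128), 65.0, n_planes=3, seed=5)
        assert np.array_equal(ph.planes, again.planes)

    def test_single_plane_rejected(self):
        with pytest.raises(ValueError):
            make_sectioning_phantom((64, 64), 65.0, n_planes=1)


class TestDetectionPsf:
    @pytest.mark.parametrize("model", ["gaussian", "diffraction"])
    def test_normalized_with_central_maximum(self, model):
        psf = detection_psf(1.49, 638.0, model=model)
        ker = psf.kernel()
        assert ker.sum() == pytest.approx(1.0, abs=1e-9)
        center = np.unravel_index(np.argmax(ker), ker.shape)
        assert center == (ker.shape[0] // 2, ker.shape[1] // 2)

    def test_diffraction_otf_has_hard_cutoff(self):
        psf = detection_psf(1.49, 638.0, model="diffraction")
        otf = psf.transfer((256, 256))
        f = np.hypot(
            np.fft.fftfreq(256, d=65.0)[:, None], np.fft.fftfreq(256, d=65.0)[None, :]
        )
        assert np.all(otf[f > psf.cutoff_per_nm] == 0.0)
        assert otf[0, 0] == pytest.approx(1.0)

    def test_defocus_broadens_monotonically(self):
        # kernel second moment never decreases across a defocus grid
        moments = []
        for dz in (0.0, 1.0, 2.0, 4.0, 8.0):
            ker = detection_psf(1.49, 638.0, defocus_um=dz).kernel(size=401)
            idx = np.arange(401) - 200
            yy, xx = np.meshgrid(idx, idx, indexing="ij")
            moments.append((ker * (yy**2 + xx**2)).sum())
        assert all(b >= a for a, b in zip(moments, moments[1:]))

    def test_undersampling_warns(self):
        with pytest.warns(UserWarning, match="undersamples"):
            detection_psf(1.49, 638.0, pixel_size_nm=200.0)


class TestRender:
    def test_impulse_yields_scaled_psf_plus_offset(self):
        ph = make_bead_phantom(1, (65, 65), 65.0, seed=1, brightness_range=(100.0, 100.0))
        psf = detection_psf(1.0, 600.0, pixel_size_nm=65.0)
        illum = IlluminationPattern(period_nm=1e9, modulation=0.0, mean_intensity=1.0)
        frame = render(ph, illum, psf, NoiseModel(dark_offset=7.0))
        r, c = np.nonzero(ph.planes[0])
        ker = psf.kernel()
        peak_expected = 100.0 * ker.max() + 7.0
        assert frame[r[0], c[0]] == pytest.approx(peak_expected, rel=1e-6)
        assert frame.min() >= 7.0 - 1e-9

    def test_zero_modulation_equals_uniform_expectation(self):
        ph = make_bead_phantom(10, (64, 64), 65.0, seed=2)
        psf = detection_psf(1.49, 638.0)
        uni = IlluminationPattern(period_nm=300.0, modulation=0.0, mean_intensity=2.0)
        huge = IlluminationPattern(period_nm=1e6, modulation=0.0, mean_intensity=2.0)
        assert render(ph, uni, psf) == pytest.approx(render(ph, huge, psf))

    def test_noisy_mean_matches_expectation(self):
        # Monte-Carlo: mean over repeats of a noisy flat render hits b + signal
        ph = make_sheet_phantom((32, 32), 65.0, density=50.0)
        psf = detection_psf(1.49, 638.0)
        illum = IlluminationPattern(period_nm=300.0, modulation=0.5, mean_intensity=1.0)
        expectation = render(ph, illum, psf, NoiseModel())  # noise-free + b
        rng = np.random.default_rng(11)
        acc = np.zeros((32, 32))
        n = 500
        for _ in range(n):
            acc += render(ph, illum, psf, NoiseModel(), rng=rng)
        mean_frame = acc / n
        # 3 standard errors of the Poisson + read noise at each pixel mean
        sd = np.sqrt(expectation - 100.0 + 2.0**2)
        assert np.all(np.abs(mean_frame - expectation) < 3.5 * sd / math.sqrt(n) + 0.05)

    def test_photon_conservation_in_expectation(self):
        ph = make_bead_phantom(20, (64, 64), 65.0, min_spacing_px=6.0, seed=4)
        psf = detection_psf(1.49, 638.0)
        illum = IlluminationPattern(period_nm=300.0, modulation=0.9, mean_intensity=1.0)
        noise = NoiseModel(dark_offset=50.0)
        expected = render(ph, illum, psf, noise)
        rng = np.random.default_rng(12)
        means = [render(ph, illum, psf, noise, rng=rng).mean() for _ in range(200)]
        assert np.mean(means) - 50.0 == pytest.approx(
            expected.mean() - 50.0, rel=5e-3
        )

    def test_nyquist_violation_is_an_error(self):
        ph = make_sheet_phantom((32, 32), 65.0)
        psf = detection_psf(1.49, 638.0)
        illum = IlluminationPattern(period_nm=100.0, modulation=0.5, mean_intensity=1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            render(ph, illum, psf)


class TestAcquireSeries:
    def test_calibration_plan(self, device_state, train):
        sheet = make_sheet_phantom((64, 64), 65.0)
        voltages = [0.0, 2.0, 4.0, 6.0]
        stack = acquire_series(device_state, train, sheet, "calibration", voltages=voltages)
        assert len(stack) == 4
        assert [m["v_phase"] for m in stack.meta] == voltages
        assert all(m["mode"] == "structured" for m in stack.meta)

    def test_hilo_plan(self, device_state, train):
        ph = make_sectioning_phantom((64, 64), 65.0, n_planes=2, seed=1)
        stack = acquire_series(device_state, train, ph, "hilo")
        assert len(stack) == 4  # (uniform, structured) per z
        modes = [(m["z_index"], m["mode"]) for m in stack.meta]
        assert modes == [(0, "uniform"), (0, "structured"), (1, "uniform"), (1, "structured")]
        # uniform frames really are single-beam: zero modulation
        assert all(
            m["modulation"] == 0.0 for m in stack.meta if m["mode"] == "uniform"
        )

    def test_sim_metadata_phases_match_heater_model(self, device_state, train):
        sheet = make_sheet_phantom((64, 64), 65.0)
        stack = acquire_series(device_state, train, sheet, "sim")
        heater = device_state.output_heater
        for md in stack.meta:
            assert md["phase_rad"] == pytest.approx(
                heater.phase(md["v_phase"], md["wavelength_nm"]), rel=1e-12
            )
        steps = np.diff([m["phase_rad"] for m in stack.meta])
        assert steps == pytest.approx([2 * math.pi / 3] * 2, abs=1e-9)

    def test_sim_requires_three_phases(self, device_state, train):
        sheet = make_sheet_phantom((64, 64), 65.0)
        with pytest.raises(ValueError, match="three"):
            acquire_series(device_state, train, sheet, "sim", phases=(0.0, 1.0))

    def test_dual_wavelength_sequential(self, device_state, train):
        sheet = make_sheet_phantom((64, 64), 65.0)
        stack = acquire_series(
            device_state, train, sheet, "sim", wavelengths=[638.0, 561.0]
        )
        wls = [m["wavelength_nm"] for m in stack.meta]
        assert wls == [638.0] * 3 + [561.0] * 3
        # balanced at both colors: high modulation in every frame
        assert all(m["modulation"] >= 0.99 - 1e-12 for m in stack.meta)

    def test_seeded_reproducibility(self, device_state, train):
        beads = make_bead_phantom(10, (64, 64), 65.0, seed=3)
        a = acquire_series(device_state, train, beads, "sim", noisy=True, seed=9)
        b = acquire_series(device_state, train, beads, "sim", noisy=True, seed=9)
        assert np.array_equal(a.frames, b.frames)


class TestImageStackIO:
    def test_tiff_sidecar_round_trip(self, device_state, train, tmp_path):
        beads = make_bead_phantom(5, (64, 64), 65.0, min_spacing_px=6.0, seed=6)
        stack = acquire_series(device_state, train, beads, "sim", noisy=True, seed=2)
        path = tmp_path / "stack.tif"
        stack.save(path)
        loaded = ImageStack.load(path)
        assert np.array_equal(loaded.frames, stack.frames)
        assert loaded.pixel_size_nm == stack.pixel_size_nm
        assert loaded.camera_offset == stack.camera_offset
        assert loaded.meta == stack.meta

    def test_select_filters_by_metadata(self, device_state, train):
        ph = make_sectioning_phantom((64, 64), 65.0, n_planes=2, seed=1)
        stack = acquire_series(device_state, train, ph, "hilo")
        sub = stack.select(mode="uniform", z_index=1)
        assert len(sub) == 1
        assert sub.meta[0]["z_index"] == 1
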