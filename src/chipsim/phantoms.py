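"""Synthetic phantoms and the forward imaging model.

Everything downstream (phase calibration, bead contrast, HiLo, SIM) is
exercised on images produced here: ground-truth fluorophore maps are
multiplied by the sample-plane illumination, blurred by a per-plane
detection PSF, and read out with shot noise and camera dark offset.

Phantom types
-------------
* sparse sub-diffraction beads (near-point sources that sample the local
  excitation intensity without spatial averaging),
* a multi-plane filament phantom with disjoint per-plane structure, for
  optical-sectioning experiments,
* a uniform fluorescent sheet, for fringe-phase calibration.

The forward model for one frame is::

    detected = Poisson( gain * exposure * sum_z [object_z * I_illum] (*) PSF_z )
             + Normal(dark_offset, read_noise_sd)

with ``(*)`` a 2D convolution.  With no random generator supplied the
noise-free expectation plus the dark offset is returned.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.signal import fftconvolve

from .device import DeviceState, device_outputs, find_balance_voltage
from .optics import IlluminationPattern, OpticalTrain, fringe_field, pattern_period

__all__ = [
    "Phantom",
    "ImageStack",
    "DetectionPSF",
    "NoiseModel",
    "detection_psf",
    "make_bead_phantom",
    "make_sectioning_phantom",
    "make_sheet_phantom",
    "render",
    "acquire_series",
    "SIM_PHASES",
]

#: target pattern phases for 3-step 1D SIM
SIM_PHASES = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)


@dataclass
class Phantom:
    """Ground-truth fluorophore density map(s) with annotations.

    ``planes`` has shape (n_planes, H, W); densities are nonnegative.
    ``bead_centers`` records (row, col) subpixel coordinates per bead (bead
    phantoms only); ``plane_masks`` records, per plane, the boolean region
    that owns its structure (sectioning phantoms only).
    """

    planes: np.ndarray
    pixel_size_nm: float
    z_spacing_um: float = 0.0
    bead_centers: np.ndarray | None = None
    bead_brightness: np.ndarray | None = None
    plane_masks: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim == 2:
            self.planes = self.planes[None]
        if self.planes.ndim != 3:
            raise ValueError("planes must be (n_planes, H, W)")
        if np.any(self.planes < 0):
            raise ValueError("fluorophore densities must be nonnegative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


# --------------------------------------------------------------------------
# detection PSF


@dataclass(frozen=True)
class DetectionPSF:
    """Incoherent widefield detection PSF.

    ``model='gaussian'`` uses a Gaussian whose in-focus 1/e half-width is
    ``w0 = 0.21 lambda / NA`` (the standard approximation of the Airy core)
    and whose width grows with defocus as
    ``sqrt(w0^2 + (defocus * NA / n)^2)``.

    ``model='diffraction'`` uses the exact incoherent OTF of a circular
    pupil (the chat function) with hard frequency cutoff ``2 NA / lambda``;
    defocus is modelled as an additional Gaussian broadening with the same
    width law, which preserves the cutoff.
    """

    NA: float
    wavelength_nm: float
    immersion_index: float = 1.515
    pixel_size_nm: float = 65.0
    defocus_um: float = 0.0
    model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.NA > self.immersion_index:
            raise ValueError("NA cannot exceed the immersion index")
        if self.model not in ("gaussian", "diffraction"):
            raise ValueError(f"unknown PSF model {self.model!r}")
        if self.pixel_size_nm > 1.0 / (2.0 * self.cutoff_per_nm):
            warnings.warn(
                f"pixel size {self.pixel_size_nm} nm undersamples the "
                f"detection OTF (Nyquist "
                f"{1.0 / (2.0 * self.cutoff_per_nm):.1f} nm)",
                stacklevel=2,
            )

    @property
    def cutoff_per_nm(self) -> float:
        """Incoherent OTF support cutoff 2 NA / lambda, cycles/nm."""
        return 2.0 * self.NA / self.wavelength_nm

    @property
    def sigma_nm(self) -> float:
        """Gaussian width including defocus broadening, nm."""
        w0 = 0.21 * self.wavelength_nm / self.NA
        spread = abs(self.defocus_um) * 1e3 * self.NA / self.immersion_index
        return math.sqrt(w0**2 + spread**2)

    def transfer(
        self,
        shape: tuple[int, int],
        shift_cycles_per_nm: tuple[float, float] = (0.0, 0.0),
    ) -> np.ndarray:
        """OTF sampled on the FFT frequency grid of an image of this shape.

        ``shift_cycles_per_nm`` evaluates the OTF at displaced frequencies
        (fy + shift_y, fx + shift_x) — used for the shifted side bands in
        SIM recombination.
        """
        fy = np.fft.fftfreq(shape[0], d=self.pixel_size_nm)[:, None] + shift_cycles_per_nm[0]
        fx = np.fft.fftfreq(shape[1], d=self.pixel_size_nm)[None, :] + shift_cycles_per_nm[1]
        f = np.hypot(fy, fx)
        if self.model == "gaussian":
            otf = np.exp(-2.0 * math.pi**2 * self.sigma_nm**2 * f**2)
        else:
            rho = np.clip(f / self.cutoff_per_nm, 0.0, 1.0)
            otf = (2.0 / math.pi) * (
                np.arccos(rho) - rho * np.sqrt(1.0 - rho**2)
            )
            otf[f >= self.cutoff_per_nm] = 0.0
            if self.defocus_um != 0.0:
                spread = abs(self.defocus_um) * 1e3 * self.NA / self.immersion_index
                otf = otf * np.exp(-2.0 * math.pi**2 * spread**2 * f**2)
        return otf

    def mtf(self, freq_per_nm: float) -> float:
        """Modulation transfer at a single spatial frequency (cycles/nm)."""
        f = abs(freq_per_nm)
        if self.model == "gaussian":
            return float(np.exp(-2.0 * math.pi**2 * self.sigma_nm**2 * f**2))
        rho = f / self.cutoff_per_nm
        if rho >= 1.0:
            return 0.0
        val = (2.0 / math.pi) * (math.acos(rho) - rho * math.sqrt(1.0 - rho**2))
        if self.defocus_um != 0.0:
            spread = abs(self.defocus_um) * 1e3 * self.NA / self.immersion_index
            val *= math.exp(-2.0 * math.pi**2 * spread**2 * f**2)
        return val

    def kernel(self, size: int | None = None) -> np.ndarray:
        """Real-space kernel, normalized to unit sum, odd side length."""
        if size is None:
            half = max(8, int(math.ceil(4.0 * self.sigma_nm / self.pixel_size_nm)))
            size = 2 * half + 1
        if size % 2 == 0:
            raise ValueError("kernel size must be odd")
        otf = self.transfer((size, size))
        ker = np.fft.ifft2(otf).real
        ker = np.fft.fftshift(ker)
        ker = np.clip(ker, 0.0, None)
        return ker / ker.sum()

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Blur an image with this PSF, applied exactly in frequency domain."""
        return np.fft.ifft2(np.fft.fft2(image) * self.transfer(image.shape)).real


def detection_psf(
    NA: float,
    wavelength_em_nm: float,
    immersion_index: float = 1.515,
    pixel_size_nm: float = 65.0,
    defocus_um: float = 0.0,
    model: str = "gaussian",
) -> DetectionPSF:
    """Convenience constructor for :class:`DetectionPSF`."""
    return DetectionPSF(
        NA=NA,
        wavelength_nm=wavelength_em_nm,
        immersion_index=immersion_index,
        pixel_size_nm=pixel_size_nm,
        defocus_um=defocus_um,
        model=model,
    )


# --------------------------------------------------------------------------
# phantom generators


def make_bead_phantom(
    n_beads: int,
    field: tuple[int, int] = (256, 256),
    pixel_size_nm: float = 65.0,
    brightness_range: tuple[float, float] = (1000.0, 3000.0),
    min_spacing_px: float = 12.0,
    seed: int = 0,
    margin_px: int = 10,
) -> Phantom:
    """Sparse sub-diffraction beads: single-pixel impulses at random positions.

    Centers are drawn uniformly (subpixel, recorded in the annotations) with
    a minimum pairwise spacing; each bead deposits its whole brightness into
    the nearest pixel, emulating a point source well below the diffraction
    limit.
    """
    if n_beads < 1:
        raise ValueError("need at least one bead")
    H, W = field
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * n_beads
    while len(centers) < n_beads:
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n_beads} beads with spacing "
                f"{min_spacing_px} px in a {H}x{W} field"
            )
        attempts += 1
        y = rng.uniform(margin_px, H - 1 - margin_px)
        x = rng.uniform(margin_px, W - 1 - margin_px)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_spacing_px**2 for cy, cx in centers):
            centers.append((y, x))
    centers_arr = np.array(centers)
    brightness = rng.uniform(*brightness_range, size=n_beads)
    plane = np.zeros((H, W))
    for (y, x), a in zip(centers_arr, brightness):
        plane[int(round(y)), int(round(x))] += a
    return Phantom(
        planes=plane[None],
        pixel_size_nm=pixel_size_nm,
        bead_centers=centers_arr,
        bead_brightness=brightness,
        seed=seed,
    )


def make_sectioning_phantom(
    field: tuple[int, int] = (256, 256),
    pixel_size_nm: float = 65.0,
    n_planes: int = 2,
    z_spacing_um: float = 6.0,
    n_filaments_per_plane: int = 8,
    intensity: float = 1000.0,
    seed: int = 0,
) -> Phantom:
    """Multi-plane filament phantom for sectioning experiments.

    The field is split into ``n_planes`` vertical bands and the filament
    network of plane *k* is confined to band *k*, so in-focus and
    out-of-focus contributions occupy disjoint image regions and can be
    attributed unambiguously.  Filaments are smoothed random walks.
    """
    if n_planes < 2:
        raise ValueError("need at least two planes for a sectioning phantom")
    H, W = field
    rng = np.random.default_rng(seed)
    band_w = W // n_planes
    planes = np.zeros((n_planes, H, W))
    masks = np.zeros((n_planes, H, W), dtype=bool)
    for k in range(n_planes):
        x0, x1 = k * band_w, (k + 1) * band_w if k < n_planes - 1 else W
        pad = 6
        masks[k, :, x0:x1] = True
        for _ in range(n_filaments_per_plane):
            y = rng.uniform(5, H - 5)
            x = rng.uniform(x0 + pad, x1 - pad)
            theta = rng.uniform(0, 2 * math.pi)
            for _ in range(rng.integers(80, 200)):
                iy, ix = int(round(y)), int(round(x))
                if 0 <= iy < H and x0 + pad <= ix < x1 - pad:
                    planes[k, iy, ix] += intensity
                theta += rng.normal(0, 0.25)
                y += math.sin(theta)
                x += math.cos(theta)
                # keep the walk inside its band
                if x < x0 + pad or x > x1 - pad - 1:
                    theta = math.pi - theta
                    x = min(max(x, x0 + pad), x1 - pad - 1)
                if y < 5 or y > H - 6:
                    theta = -theta
                    y = min(max(y, 5), H - 6)
    return Phantom(
        planes=planes,
        pixel_size_nm=pixel_size_nm,
        z_spacing_um=z_spacing_um,
        plane_masks=masks,
        seed=seed,
    )


def make_sheet_phantom(
    field: tuple[int, int] = (256, 256),
    pixel_size_nm: float = 65.0,
    density: float = 1000.0,
) -> Phantom:
    """Uniform fluorescent sheet (dye layer), used for fringe calibration."""
    if density < 0:
        raise ValueError("density must be nonnegative")
    return Phantom(planes=np.full((1, *field), density), pixel_size_nm=pixel_size_nm)


# --------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class NoiseModel:
    """Camera model: photon gain, dark offset (counts) and read noise (sd)."""

    gain: float = 1.0
    dark_offset: float = 100.0
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.read_noise_sd < 0:
            raise ValueError("gain must be positive, read noise nonnegative")


def _illumination_image(
    illum: IlluminationPattern, shape: tuple[int, int], pixel_size_nm: float
) -> np.ndarray:
    x_nm = np.arange(shape[1]) * pixel_size_nm
    return np.broadcast_to(illum.intensity(x_nm)[None, :], shape)


def render(
    phantom: Phantom,
    illum: IlluminationPattern,
    psfs: DetectionPSF | list[DetectionPSF],
    noise: NoiseModel = NoiseModel(),
    exposure: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one detected frame from a phantom under the given illumination.

    ``psfs`` is one :class:`DetectionPSF` per phantom plane (or a single one
    for single-plane phantoms).  With ``rng=None`` the noise-free
    expectation plus the dark offset is returned; with a generator, Poisson
    shot noise and Gaussian dark noise are applied.
    """
    if illum.period_nm < 2.0 * phantom.pixel_size_nm:
        raise ValueError(
            f"illumination period {illum.period_nm:.1f} nm is below the "
            f"2-pixel Nyquist limit ({2 * phantom.pixel_size_nm:.1f} nm)"
        )
    if isinstance(psfs, DetectionPSF):
        psfs = [psfs] * phantom.n_planes
    if len(psfs) != phantom.n_planes:
        raise ValueError("need one PSF per phantom plane")
    illum_img = _illumination_image(illum, phantom.shape, phantom.pixel_size_nm)
    expected = np.zeros(phantom.shape)
    for plane, psf in zip(phantom.planes, psfs):
        if not np.any(plane):
            continue
        excited = plane * illum_img
        if psf.model == "diffraction" or psf.sigma_nm / phantom.pixel_size_nm > 12:
            # frequency-domain application: exact cutoff / large kernels
            expected += psf.apply(excited)
        else:
            expected += fftconvolve(excited, psf.kernel(), mode="same")
    expected = np.clip(expected * noise.gain * exposure, 0.0, None)
    if rng is None:
        return expected + noise.dark_offset
    frame = rng.poisson(expected).astype(float)
    frame += rng.normal(noise.dark_offset, noise.read_noise_sd, size=frame.shape)
    return frame


# --------------------------------------------------------------------------
# image stacks and acquisition series


@dataclass
class ImageStack:
    """A stack of frames with complete per-frame acquisition metadata."""

    frames: np.ndarray
    meta: list[dict]
    pixel_size_nm: float
    z_spacing_um: float = 0.0
    camera_offset: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, H, W)")
        if len(self.meta) != self.frames.shape[0]:
            raise ValueError("need one metadata record per frame")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def select(self, **criteria) -> "ImageStack":
        """Sub-stack of frames whose metadata match all given key=value pairs."""
        idx = [
            i
            for i, m in enumerate(self.meta)
            if all(m.get(k) == v for k, v in criteria.items())
        ]
        return ImageStack(
            frames=self.frames[idx],
            meta=[self.meta[i] for i in idx],
            pixel_size_nm=self.pixel_size_nm,
            z_spacing_um=self.z_spacing_um,
            camera_offset=self.camera_offset,
            seed=self.seed,
        )

    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF plus a JSON metadata sidecar (.json)."""
        path = Path(path)
        tifffile.imwrite(path, self.frames)  # float64: lossless round-trip
        sidecar = {
            "pixel_size_nm": self.pixel_size_nm,
            "z_spacing_um": self.z_spacing_um,
            "camera_offset": self.camera_offset,
            "seed": self.seed,
            "frames": self.meta,
        }

        def scalar(obj):
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            raise TypeError(f"not JSON serializable: {type(obj)}")

        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1, default=scalar)
        )

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            frames=frames,
            meta=sidecar["frames"],
            pixel_size_nm=sidecar["pixel_size_nm"],
            z_spacing_um=sidecar.get("z_spacing_um", 0.0),
            camera_offset=sidecar.get("camera_offset", 0.0),
            seed=sidecar.get("seed"),
        )


def _pattern_for(
    state: DeviceState,
    train: OpticalTrain,
    phase: float,
) -> IlluminationPattern:
    p1, p2, _ = device_outputs(state)
    period = pattern_period(train)
    return fringe_field(p1, p2, state.background_power, phase, period)


def acquire_series(
    state: DeviceState,
    train: OpticalTrain,
    phantom: Phantom,
    mode: str,
    voltages: list[float] | None = None,
    phases: tuple[float, ...] = SIM_PHASES,
    wavelengths: list[float] | None = None,
    noise: NoiseModel = NoiseModel(),
    exposure: float = 1.0,
    psf_model: str = "gaussian",
    noisy: bool = False,
    seed: int = 0,
) -> ImageStack:
    """Drive device -> optics -> render for a full acquisition series.

    Modes
    -----
    ``calibration``
        MZI held at its balance voltage; one structured frame per phase-
        shifter voltage in ``voltages``.
    ``hilo``
        For each phantom plane taken in turn as the focal plane: one
        uniform frame (MZI driven to a fully unbalanced single-beam state)
        and one structured frame (MZI balanced).
    ``sim``
        MZI balanced; >=3 phase-stepped structured frames (target phases
        ``phases``) for each wavelength in ``wavelengths``, acquired
        sequentially per wavelength — the thermo-optic phase law is
        wavelength dependent, so colors cannot share voltages.
    """
    rng = np.random.default_rng(seed)
    frame_rng = rng if noisy else None
    frames: list[np.ndarray] = []
    meta: list[dict] = []

    def psf_for(defocus_um: float, wavelength: float) -> DetectionPSF:
        return DetectionPSF(
            NA=train.NA,
            wavelength_nm=wavelength,  # emission approximated by excitation
            immersion_index=train.immersion_index,
            pixel_size_nm=phantom.pixel_size_nm,
            defocus_um=defocus_um,
            model=psf_model,
        )

    def in_focus_psfs(focus_index: int, wavelength: float) -> list[DetectionPSF]:
        return [
            psf_for(abs(k - focus_index) * phantom.z_spacing_um, wavelength)
            for k in range(phantom.n_planes)
        ]

    def record(frame: np.ndarray, **md) -> None:
        frames.append(frame)
        meta.append({"exposure": exposure, **md})

    if mode == "calibration":
        if not voltages:
            raise ValueError("calibration mode needs a voltage list")
        wl = state.wavelength_nm
        tr = train.replace(wavelength_nm=wl)
        v_bal = find_balance_voltage(state)
        st = state.replace(v_mzi=v_bal)
        psfs = in_focus_psfs(0, wl)
        for v in voltages:
            st_v = st.replace(v_phase=v)
            _, _, phase = device_outputs(st_v)
            illum = _pattern_for(st_v, tr, phase)
            record(
                render(phantom, illum, psfs, noise, exposure, frame_rng),
                mode="structured",
                v_mzi=v_bal,
                v_phase=v,
                phase_rad=phase,
                wavelength_nm=wl,
                period_nm=illum.period_nm,
                modulation=illum.modulation,
                z_index=0,
            )
    elif mode == "hilo":
        wl = state.wavelength_nm
        tr = train.replace(wavelength_nm=wl)
        v_bal = find_balance_voltage(state)
        # single-beam (whole-device SR = 1, phi = pi) => uniform illumination
        v_single = state.mzi_heater.voltage_for_phase(math.pi, wl)
        for z in range(phantom.n_planes):
            psfs = in_focus_psfs(z, wl)
            for label, v_mzi in (("uniform", v_single), ("structured", v_bal)):
                st = state.replace(v_mzi=v_mzi, v_phase=0.0)
                _, _, phase = device_outputs(st)
                illum = _pattern_for(st, tr, phase)
                record(
                    render(phantom, illum, psfs, noise, exposure, frame_rng),
                    mode=label,
                    v_mzi=v_mzi,
                    v_phase=0.0,
                    phase_rad=phase,
                    wavelength_nm=wl,
                    period_nm=illum.period_nm,
                    modulation=illum.modulation,
                    z_index=z,
                )
    elif mode == "sim":
        if len(phases) < 3:
            raise ValueError("SIM needs at least three pattern phases")
        if wavelengths is None:
            wavelengths = [state.wavelength_nm]
        for wl in wavelengths:  # sequential acquisition, one color at a time
            st_wl = state.replace(wavelength_nm=wl)
            tr = train.replace(wavelength_nm=wl)
            v_bal = find_balance_voltage(st_wl)
            psfs = in_focus_psfs(0, wl)
            for target_phase in phases:
                v = st_wl.output_heater.voltage_for_phase(target_phase, wl)
                st = st_wl.replace(v_mzi=v_bal, v_phase=v)
                _, _, phase = device_outputs(st)
                illum = _pattern_for(st, tr, phase)
                record(
                    render(phantom, illum, psfs, noise, exposure, frame_rng),
                    mode="structured",
                    v_mzi=v_bal,
                    v_phase=v,
                    phase_rad=phase,
                    wavelength_nm=wl,
                    period_nm=illum.period_nm,
                    modulation=illum.modulation,
                    z_index=0,
                )
    else:
        raise ValueError(f"unknown acquisition mode {mode!r}")

    return ImageStack(
        frames=np.stack(frames),
        meta=meta,
        pixel_size_nm=phantom.pixel_size_nm,
        z_spacing_um=phantom.z_spacing_um,
        camera_offset=noise.dark_offset,
        seed=seed,
    )
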