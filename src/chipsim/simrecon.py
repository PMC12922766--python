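"""Three-phase 1D structured-illumination reconstruction.

The chip produces a single fringe orientation (along the image x axis), so
three phase-stepped frames suffice to separate the zeroth and +/- first
illumination orders.  For each spatial frequency k the detected spectra obey

    D_n(k) = C0(k) + e^{i phi_n} C+(k) + e^{-i phi_n} C-(k)

with C0 the widefield component and C+- the object spectrum shifted by the
pattern frequency, scaled by m/2.  Inverting this 3x3 system per frequency,
shifting the side bands back to their true frequencies, and recombining all
bands with a generalized Wiener filter extends the spectral support along x
from the widefield cutoff f_c to f_c + f_pattern — the theoretical
resolution-enhancement factor F = 1 + f_pattern / f_c.

Pattern phases need not be known a priori: they are retrieved a posteriori
from the complex phase of the spectral peak at the pattern frequency of
each raw frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import estimate_pattern_phase
from .phantoms import DetectionPSF

__all__ = [
    "SIMResult",
    "retrieve_phases",
    "separate_bands",
    "recombine",
    "reconstruct",
    "measure_enhancement",
    "spectral_support_radius",
]


def retrieve_phases(
    frames: np.ndarray, freq_hint_cycles_per_px: float
) -> np.ndarray:
    """A-posteriori pattern phases of phase-stepped frames, relative to frame 0.

    Each frame's phase is the complex argument of its spectral peak nearest
    the hinted pattern frequency; results are reported modulo 2 pi with the
    first frame as reference (its entry is 0).
    """
    frames = np.asarray(frames, dtype=float)
    raw = np.array(
        [estimate_pattern_phase(f, freq_hint_cycles_per_px) for f in frames]
    )
    rel = np.mod(raw - raw[0], 2.0 * math.pi)
    rel[0] = 0.0
    return rel


def separate_bands(
    frames: np.ndarray, phases: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert the per-frequency 3x3 phase-mixing system.

    Returns the complex spectra ``(band0, band_plus, band_minus)`` where
    ``band0`` is the widefield (zeroth-order) spectrum and ``band_plus`` /
    ``band_minus`` hold the object spectrum shifted by -/+ the pattern
    frequency, each still scaled by m/2 and by the detection OTF.
    """
    frames = np.asarray(frames, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if frames.ndim != 3 or frames.shape[0] != 3:
        raise ValueError("need exactly three frames")
    if phases.shape != (3,):
        raise ValueError("need exactly three phases")
    mixing = np.stack(
        [np.ones(3, dtype=complex), np.exp(1j * phases), np.exp(-1j * phases)],
        axis=1,
    )
    cond = np.linalg.cond(mixing)
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError(
            f"phase triplet {np.round(phases, 3)} makes the mixing matrix "
            f"singular (condition number {cond:.2e}); phases must be "
            "pairwise distinct"
        )
    spectra = np.fft.fft2(frames, axes=(1, 2))
    inv = np.linalg.inv(mixing)
    bands = np.tensordot(inv, spectra, axes=(1, 0))
    return bands[0], bands[1], bands[2]


def _estimate_modulation(
    band0: np.ndarray,
    band_plus: np.ndarray,
    pattern_freq_cycles_per_px: float,
    otf: DetectionPSF,
) -> float:
    """Modulation depth from the side-peak-to-DC amplitude ratio.

    At the pattern-frequency bin, ``band_plus`` holds (m/2) OTF(p) S(0);
    at DC, ``band0`` holds S(0).  Their magnitude ratio, corrected for the
    OTF attenuation at p, yields m.
    """
    W = band0.shape[1]
    bin_x = int(round(pattern_freq_cycles_per_px * W))
    peak = np.abs(band_plus[0, bin_x])
    dc = np.abs(band0[0, 0])
    att = otf.mtf(pattern_freq_cycles_per_px / otf.pixel_size_nm)
    if dc == 0 or att == 0:
        raise ValueError("cannot estimate modulation: empty spectrum or zero MTF")
    return float(np.clip(2.0 * peak / (dc * att), 1e-3, 1.0))


@dataclass
class SIMResult:
    """Reconstruction output with the quantities needed to audit it.

    ``upsample`` is the integer factor by which the reconstruction grid is
    finer than the acquisition grid (the extended spectral support would
    otherwise exceed the camera Nyquist frequency);
    ``pattern_freq_cycles_per_px`` is in acquisition pixels.
    """

    image: np.ndarray
    phases_rad: np.ndarray
    pattern_freq_cycles_per_px: float
    wiener_eps: float
    modulation: float
    band_weights: tuple[float, float, float]
    upsample: int = 1

    @property
    def phase_steps(self) -> np.ndarray:
        """Pairwise phase increments (should be near 2 pi / 3 for 3-step SIM)."""
        return np.diff(self.phases_rad)


def _apodization(shape: tuple[int, int], f_ext_cycles_per_px: float) -> np.ndarray:
    """Isotropic triangular apodization to the extended cutoff.

    Falls linearly from 1 at DC to 0 at the extended cutoff
    ``f_c + f_pattern``.  A single radial ramp is used for both axes: the
    anisotropy of the reconstruction is carried entirely by the physical
    OTF support (which ends at ``f_c`` along y), and the apodization only
    suppresses ringing from the hard support edge.
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    rho = np.hypot(fy, fx) / f_ext_cycles_per_px
    return np.clip(1.0 - rho, 0.0, None)


def _pad_spectrum(spectrum: np.ndarray, factor: int) -> np.ndarray:
    """Zero-pad an FFT spectrum to a `factor`-times finer real-space grid."""
    if factor == 1:
        return spectrum
    H, W = spectrum.shape
    out = np.zeros((H * factor, W * factor), dtype=complex)
    sh = np.fft.fftshift(spectrum)
    r0 = (H * factor - H) // 2
    c0 = (W * factor - W) // 2
    out[r0 : r0 + H, c0 : c0 + W] = sh
    return np.fft.ifftshift(out) * factor**2


def recombine(
    bands: tuple[np.ndarray, np.ndarray, np.ndarray],
    pattern_freq_cycles_per_px: float,
    otf: DetectionPSF,
    wiener_eps: float = 1e-2,
    phases: np.ndarray | None = None,
    apodize: bool = True,
    upsample: int = 2,
) -> SIMResult:
    """Shift the side bands to their true frequencies and Wiener-recombine.

    Bands are first zero-padded onto an ``upsample``-times finer grid (the
    extended support f_c + f_pattern generally exceeds the camera Nyquist
    frequency), side bands are translated by +/- the pattern frequency
    (real-space modulation, so non-integer bin shifts are exact), weighted
    by the conjugate of the correspondingly shifted OTF, normalized by the
    summed squared OTFs plus ``wiener_eps``, apodized with a triangle to
    the extended cutoff, and inverse transformed.
    """
    if wiener_eps <= 0:
        raise ValueError("wiener_eps must be positive")
    if upsample < 1:
        raise ValueError("upsample must be a positive integer")
    band0, band_plus, band_minus = bands
    p_px = pattern_freq_cycles_per_px
    p_nm = p_px / otf.pixel_size_nm
    m = _estimate_modulation(band0, band_plus, p_px, otf)

    # move to the finer reconstruction grid
    band0 = _pad_spectrum(band0, upsample)
    band_plus = _pad_spectrum(band_plus, upsample)
    band_minus = _pad_spectrum(band_minus, upsample)
    shape = band0.shape
    pix_up = otf.pixel_size_nm / upsample
    p_up = p_px / upsample  # cycles per upsampled pixel
    import dataclasses

    otf_up = dataclasses.replace(otf, pixel_size_nm=pix_up)

    x = np.arange(shape[1])[None, :]
    shift_plus = np.exp(-2j * math.pi * p_up * x)  # G(k) -> G(k + p)
    shift_minus = np.conj(shift_plus)

    def shifted(spectrum: np.ndarray, modulator: np.ndarray) -> np.ndarray:
        return np.fft.fft2(np.fft.ifft2(spectrum) * modulator)

    otf0 = otf_up.transfer(shape)
    otf_plus = otf_up.transfer(shape, shift_cycles_per_nm=(0.0, p_nm))
    otf_minus = otf_up.transfer(shape, shift_cycles_per_nm=(0.0, -p_nm))

    w0, w_side = 1.0, m / 2.0
    numerator = (
        w0 * np.conj(otf0) * band0
        + w_side * np.conj(otf_plus) * shifted(band_plus, shift_plus)
        + w_side * np.conj(otf_minus) * shifted(band_minus, shift_minus)
    )
    denominator = (
        w0**2 * np.abs(otf0) ** 2
        + w_side**2 * np.abs(otf_plus) ** 2
        + w_side**2 * np.abs(otf_minus) ** 2
        + wiener_eps
    )
    spectrum = numerator / denominator

    fc_up = otf.cutoff_per_nm * pix_up  # cycles per upsampled pixel
    if apodize:
        spectrum = spectrum * _apodization(shape, fc_up + p_up)
    image = np.fft.ifft2(spectrum).real

    return SIMResult(
        image=image,
        phases_rad=phases if phases is not None else np.zeros(3),
        pattern_freq_cycles_per_px=p_px,
        wiener_eps=wiener_eps,
        modulation=m,
        band_weights=(w0, w_side, w_side),
        upsample=upsample,
    )


def reconstruct(
    frames: np.ndarray,
    pattern_freq_cycles_per_px: float,
    otf: DetectionPSF,
    wiener_eps: float = 1e-2,
    phases: np.ndarray | None = None,
    apodize: bool = True,
    upsample: int = 2,
) -> SIMResult:
    """Full pipeline: a-posteriori phase retrieval, band separation, recombination."""
    if phases is None:
        phases = retrieve_phases(frames, pattern_freq_cycles_per_px)
    bands = separate_bands(frames, phases)
    result = recombine(
        bands,
        pattern_freq_cycles_per_px,
        otf,
        wiener_eps=wiener_eps,
        phases=phases,
        apodize=apodize,
        upsample=upsample,
    )
    return result


# --------------------------------------------------------------------------
# measurement helpers


def spectral_support_radius(
    image: np.ndarray, axis: str, rel_threshold: float = 1e-6
) -> float:
    """Largest |f| (cycles/px) along an axis with spectral magnitude above threshold.

    The threshold is relative to the spectral maximum; ``axis`` is ``'x'``
    (horizontal, the enhanced direction) or ``'y'``.
    """
    spec = np.abs(np.fft.fft2(image - image.mean()))
    thresh = rel_threshold * spec.max()
    if axis == "x":
        line = spec[0, :]
        freqs = np.abs(np.fft.fftfreq(image.shape[1]))
    elif axis == "y":
        line = spec[:, 0]
        freqs = np.abs(np.fft.fftfreq(image.shape[0]))
    else:
        raise ValueError("axis must be 'x' or 'y'")
    above = freqs[line > thresh]
    return float(above.max()) if above.size else 0.0


def _profile_fwhm(profile: np.ndarray, peak_index: int) -> float:
    """FWHM by linear interpolation of the half-maximum crossings."""
    baseline = float(np.min(profile))
    v = profile - baseline
    half = v[peak_index] / 2.0
    if half <= 0:
        raise ValueError("flat profile: no peak")

    def crossing(direction: int) -> float:
        i = peak_index
        while 0 < i < len(v) - 1:
            j = i + direction
            if v[j] < half:
                # interpolate between i and j
                frac = (v[i] - half) / (v[i] - v[j])
                return abs(i - peak_index) + frac
            i = j
        raise ValueError("half-maximum crossing not found inside the profile")

    return crossing(-1) + crossing(+1)


def measure_enhancement(
    widefield: np.ndarray,
    sim_image: np.ndarray,
    bead_centers: np.ndarray,
    window_px: int = 15,
    min_separation_px: float | None = None,
) -> dict:
    """Vertical-to-horizontal spot-width ratios of point emitters.

    For each bead the horizontal and vertical FWHM of its image in
    ``sim_image`` are measured on 1D profiles through the brightest pixel
    (half-max crossings located by linear interpolation).  Since only the
    horizontal direction is resolution-enhanced, the vertical/horizontal
    ratio exceeding one quantifies the anisotropic enhancement.  Beads with
    a neighbor closer than ``min_separation_px`` (default: two windows) are
    excluded as overlapping.

    If the SIM image lives on a finer grid than the widefield image (an
    integer upsampling factor), the widefield image is interpolated onto
    the SIM grid by spectral zero-padding; ``bead_centers`` and the window
    are interpreted in widefield pixels.
    """
    centers = np.asarray(bead_centers, dtype=float)
    if sim_image.shape != widefield.shape:
        factor = sim_image.shape[0] // widefield.shape[0]
        if factor < 1 or sim_image.shape != tuple(s * factor for s in widefield.shape):
            raise ValueError("SIM/widefield shapes differ by a non-integer factor")
        widefield = np.fft.ifft2(
            _pad_spectrum(np.fft.fft2(widefield), factor)
        ).real
        centers = centers * factor
        window_px = window_px * factor
    if min_separation_px is None:
        min_separation_px = 2.0 * window_px
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    isolated = d2.min(axis=1) >= min_separation_px**2

    H, W = sim_image.shape
    records = []
    for (cy, cx), ok in zip(centers, isolated):
        if not ok:
            continue
        r, c = int(round(cy)), int(round(cx))
        if not (window_px <= r < H - window_px and window_px <= c < W - window_px):
            continue
        # refine to the brightest pixel of the SIM spot
        patch = sim_image[r - 3 : r + 4, c - 3 : c + 4]
        dr, dc = np.unravel_index(np.argmax(patch), patch.shape)
        r, c = r - 3 + dr, c - 3 + dc
        try:
            horiz = _profile_fwhm(sim_image[r, c - window_px : c + window_px + 1], window_px)
            vert = _profile_fwhm(sim_image[r - window_px : r + window_px + 1, c], window_px)
            wf_h = _profile_fwhm(widefield[r, c - window_px : c + window_px + 1], window_px)
            wf_v = _profile_fwhm(widefield[r - window_px : r + window_px + 1, c], window_px)
        except ValueError:
            continue
        records.append((horiz, vert, wf_h, wf_v))
    if len(records) < 3:
        raise ValueError(
            f"only {len(records)} isolated measurable beads; need at least 3"
        )
    arr = np.array(records)
    ratios = arr[:, 1] / arr[:, 0]  # vertical / horizontal
    return {
        "ratios": ratios,
        "mean_ratio": float(ratios.mean()),
        "quartiles": tuple(np.percentile(ratios, [25, 50, 75])),
        "fwhm_horizontal_px": arr[:, 0],
        "fwhm_vertical_px": arr[:, 1],
        "widefield_fwhm_horizontal_px": arr[:, 2],
        "widefield_fwhm_vertical_px": arr[:, 3],
        "n_beads": len(records),
    }
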