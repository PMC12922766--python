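"""HiLo optical sectioning from one uniform and one structured image.

In-focus regions show the projected fringe at high contrast; out-of-focus
regions wash it out.  The absolute difference of the two images therefore
maps where the pattern — and hence in-focus signal — is visible.  Its
low-pass part supplies the sectioned low frequencies, the complementary
high-pass of the uniform image supplies the (inherently sectioned) high
frequencies, and the two are stitched in the Fourier domain with a scale
factor eta that makes the radially averaged spectra continuous at the seam.

Both filters are Gaussian with the same threshold frequency, set to half
the spatial frequency of the illumination pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HiLoResult",
    "gaussian_lowpass_transfer",
    "hilo_reconstruct",
    "hilo_stack",
    "sectioning_curve",
]


def gaussian_lowpass_transfer(
    shape: tuple[int, int], fc_cycles_per_px: float
) -> np.ndarray:
    """Gaussian low-pass transfer exp(-f^2 / (2 fc^2)) on the FFT grid.

    The threshold frequency ``fc`` is the filter's 1/sqrt(e) characteristic
    frequency.  The complementary high-pass is ``1 -`` this transfer, so the
    pair sums to one at every frequency.
    """
    if fc_cycles_per_px <= 0:
        raise ValueError("cutoff frequency must be positive")
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f2 = fy**2 + fx**2
    return np.exp(-f2 / (2.0 * fc_cycles_per_px**2))


def _radial_magnitude_at(spectrum: np.ndarray, f0: float, width: float) -> float:
    """Mean |spectrum| over the annulus |f| in [f0 - width, f0 + width]."""
    fy = np.fft.fftfreq(spectrum.shape[0])[:, None]
    fx = np.fft.fftfreq(spectrum.shape[1])[None, :]
    f = np.hypot(fy, fx)
    ring = (f >= f0 - width) & (f <= f0 + width)
    if not ring.any():
        raise ValueError("empty annulus at the seam frequency")
    return float(np.abs(spectrum[ring]).mean())


@dataclass
class HiLoResult:
    """Sectioned image plus retained intermediates for inspection."""

    hilo: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    difference: np.ndarray
    fc_cycles_per_px: float
    eta: float


def hilo_reconstruct(
    uniform: np.ndarray,
    structured: np.ndarray,
    pattern_freq_cycles_per_px: float,
    eta: float | None = None,
) -> HiLoResult:
    """Fuse a uniform/structured image pair into an optically sectioned image.

    Steps: equalize the structured frame's mean to the uniform frame's;
    take the absolute difference; low-pass it at ``fc`` = half the pattern
    frequency; high-pass the uniform image with the complementary filter;
    choose ``eta`` for spectral continuity at ``fc``; add the two parts in
    the Fourier domain.
    """
    uniform = np.asarray(uniform, dtype=float)
    structured = np.asarray(structured, dtype=float)
    if uniform.shape != structured.shape:
        raise ValueError("uniform and structured frames must share a shape")
    if pattern_freq_cycles_per_px <= 0:
        raise ValueError("pattern frequency must be positive")
    fc = pattern_freq_cycles_per_px / 2.0
    if fc >= 0.5:
        raise ValueError("cutoff at or above the Nyquist frequency")

    if structured.mean() > 0:
        structured = structured * (uniform.mean() / structured.mean())
    difference = np.abs(structured - uniform)

    lp = gaussian_lowpass_transfer(uniform.shape, fc)
    diff_spec = np.fft.fft2(difference)
    uni_spec = np.fft.fft2(uniform)
    lo_spec = diff_spec * lp
    hi_spec = uni_spec * (1.0 - lp)

    if eta is None:
        width = 1.0 / max(uniform.shape)  # one spectral bin
        lo_mag = _radial_magnitude_at(lo_spec, fc, width)
        hi_mag = _radial_magnitude_at(hi_spec, fc, width)
        eta = hi_mag / lo_mag if lo_mag > 0 else 1.0

    hilo_spec = eta * lo_spec + hi_spec
    return HiLoResult(
        hilo=np.fft.ifft2(hilo_spec).real,
        lo=np.fft.ifft2(lo_spec).real,
        hi=np.fft.ifft2(hi_spec).real,
        difference=difference,
        fc_cycles_per_px=fc,
        eta=float(eta),
    )


def hilo_stack(stack, pattern_freq_cycles_per_px: float | None = None) -> list[HiLoResult]:
    """HiLo-reconstruct every z plane of an interleaved uniform/structured stack.

    The pattern frequency is taken from the acquisition metadata unless
    given explicitly.
    """
    z_indices = sorted({m["z_index"] for m in stack.meta})
    results = []
    for z in z_indices:
        uni = stack.select(mode="uniform", z_index=z)
        struct = stack.select(mode="structured", z_index=z)
        if len(uni) != 1 or len(struct) != 1:
            raise ValueError(f"z={z}: need exactly one uniform and one structured frame")
        if pattern_freq_cycles_per_px is None:
            freq = stack.pixel_size_nm / struct.meta[0]["period_nm"]
        else:
            freq = pattern_freq_cycles_per_px
        offset = stack.camera_offset
        results.append(
            hilo_reconstruct(uni.frames[0] - offset, struct.frames[0] - offset, freq)
        )
    return results


def sectioning_curve(
    widefield_frames: np.ndarray,
    hilo_frames: np.ndarray,
    in_focus_masks: np.ndarray,
) -> dict:
    """In-focus / out-of-focus energy ratios per z, widefield vs HiLo.

    ``in_focus_masks[z]`` marks the image region owned by the structure that
    is in focus in frame ``z`` (ground-truth annotation).  The ratio for a
    frame is the mean intensity inside the mask over the mean outside;
    larger means better rejection of out-of-focus light.  Invariant to
    global gain.
    """
    widefield_frames = np.asarray(widefield_frames, dtype=float)
    hilo_frames = np.asarray(hilo_frames, dtype=float)
    if in_focus_masks is None:
        raise ValueError("ground-truth in-focus annotations are required")
    in_focus_masks = np.asarray(in_focus_masks, dtype=bool)
    if not (len(widefield_frames) == len(hilo_frames) == len(in_focus_masks)):
        raise ValueError("need one widefield frame, HiLo frame, and mask per z")

    def ratio(frame: np.ndarray, mask: np.ndarray) -> float:
        inside = frame[mask]
        outside = frame[~mask]
        if inside.size == 0 or outside.size == 0:
            raise ValueError("mask must split the field in two nonempty regions")
        denom = outside.mean()
        if abs(denom) < 1e-30 or inside.mean() <= 0:
            raise ValueError("empty (all-background) frame: ratio undefined")
        return float(inside.mean() / denom)

    wf = [ratio(f, m) for f, m in zip(widefield_frames, in_focus_masks)]
    hl = [ratio(np.clip(f, 0, None), m) for f, m in zip(hilo_frames, in_focus_masks)]
    return {
        "widefield": np.array(wf),
        "hilo": np.array(hl),
        "improvement": np.array(hl) / np.array(wf),
    }
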