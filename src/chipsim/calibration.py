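"""Device characterization analyses.

* Fringe-phase estimation from the complex phase of the Fourier peak at the
  pattern frequency.
* Phase-voltage calibration curves of the thermo-optic shifter, with
  stability / repeatability statistics across repeated curves.
* Fringe-contrast estimation on sparse sub-diffraction beads, which sample
  the excitation field pointwise and so escape the MTF attenuation that
  biases any measurement on an extended fluorescent sample.
* Location of the contrast extrema of the MZI voltage sweep (balanced split
  at maximum contrast, single-beam at minimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import peak_local_max

from .device import DeviceState, device_outputs, find_balance_voltage
from .optics import OpticalTrain, fringe_field, pattern_period
from .phantoms import ImageStack

__all__ = [
    "PatternNotDetectedError",
    "CalibrationCurve",
    "ContrastReport",
    "estimate_pattern_phase",
    "phase_voltage_curve",
    "curve_variability",
    "bead_contrast",
    "find_contrast_extrema",
]


class PatternNotDetectedError(ValueError):
    """No spectral peak above the noise floor near the expected frequency."""


def _pattern_freq_hint(stack: ImageStack, index: int = 0) -> float:
    """Pattern frequency in cycles/pixel from frame metadata."""
    md = stack.meta[index]
    if "period_nm" not in md:
        raise KeyError("frame metadata carries no pattern period")
    return stack.pixel_size_nm / md["period_nm"]


def estimate_pattern_phase(
    frame: np.ndarray,
    freq_hint_cycles_per_px: float,
    search_bins: int = 2,
    min_peak_snr: float = 5.0,
) -> float:
    """Pattern phase from the complex phase of the spectral peak.

    The frame is Fourier transformed, the magnitude peak nearest the hinted
    horizontal frequency (the fringe runs along the image x axis) is located
    within ``search_bins`` bins, and its complex argument is returned.  The
    estimate is taken at the integer DFT bin — no subpixel interpolation —
    and is invariant to global intensity scaling.

    A Hann window is applied along x before the transform: the fringe
    frequency generally falls between DFT bins, and without the window the
    leakage tail of the negative-frequency fringe component biases the
    phase of the positive-frequency peak.
    """
    frame = np.asarray(frame, dtype=float)
    H, W = frame.shape
    window = np.hanning(W)[None, :]
    spec_row = np.fft.fft((frame - frame.mean()) * window, axis=1).sum(axis=0) / (H * W)
    # positive-frequency half, excluding DC
    mags = np.abs(spec_row[1 : W // 2 + 1])
    hint_bin = int(round(freq_hint_cycles_per_px * W))
    if not 1 <= hint_bin <= W // 2:
        raise ValueError(
            f"frequency hint {freq_hint_cycles_per_px} cycles/px is outside "
            "the resolvable range"
        )
    lo = max(1, hint_bin - search_bins)
    hi = min(W // 2, hint_bin + search_bins)
    window = np.abs(spec_row[lo : hi + 1])
    peak_bin = lo + int(np.argmax(window))
    noise_floor = np.median(mags)
    peak_mag = np.abs(spec_row[peak_bin])
    if peak_mag <= 0.0 or peak_mag < min_peak_snr * noise_floor:
        raise PatternNotDetectedError(
            f"no spectral peak above {min_peak_snr}x the noise floor near "
            f"bin {hint_bin} — pattern not detected"
        )
    return float(np.angle(spec_row[peak_bin]))


@dataclass
class CalibrationCurve:
    """Phase-voltage characteristic: unwrapped phase per applied voltage.

    Phases are referenced to the first frame (zero offset assumed at zero
    voltage), with successive increments forced into (-pi, pi].
    """

    voltages: np.ndarray
    phases_rad: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.phases_rad = np.asarray(self.phases_rad, dtype=float)
        if self.voltages.shape != self.phases_rad.shape:
            raise ValueError("voltage and phase lists must have equal length")
        if len(self.phases_rad) and abs(self.phases_rad[0]) > 1e-12:
            raise ValueError("first phase must be zero by construction")


def _unwrap_increments(raw: np.ndarray) -> np.ndarray:
    """Reference to the first value and unwrap increments into (-pi, pi]."""
    out = np.zeros_like(raw)
    for i in range(1, len(raw)):
        d = raw[i] - raw[i - 1]
        d = d - 2 * math.pi * math.floor((d + math.pi) / (2 * math.pi))
        out[i] = out[i - 1] + d
    return out


def phase_voltage_curve(stack: ImageStack) -> CalibrationCurve:
    """Estimate the phase-voltage characteristic from a calibration stack."""
    hint = _pattern_freq_hint(stack)
    raw = np.array(
        [estimate_pattern_phase(f, hint) for f in stack.frames]
    )
    voltages = np.array([m["v_phase"] for m in stack.meta], dtype=float)
    if np.any(np.diff(voltages) < 0):
        raise ValueError("calibration stack voltages must be monotone")
    phases = _unwrap_increments(raw)
    return CalibrationCurve(
        voltages=voltages,
        phases_rad=phases,
        meta={"wavelength_nm": stack.meta[0].get("wavelength_nm")},
    )


def curve_variability(
    curves: list[CalibrationCurve],
) -> tuple[np.ndarray, float]:
    """Relative spread of repeated phase-voltage curves.

    At every voltage where the across-curve mean phase is nonzero, computes
    the sample standard deviation across curves divided by the mean; the
    summary is the average of these ratios, in percent.  This is the
    statistic used to quantify within-day stability and day-to-day
    repeatability of the phase shifter.
    """
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    grid = curves[0].voltages
    for c in curves[1:]:
        if not np.array_equal(c.voltages, grid):
            raise ValueError("curves must share one voltage grid")
    phases = np.stack([c.phases_rad for c in curves])  # (n_curves, n_v)
    mean = phases.mean(axis=0)
    sd = phases.std(axis=0, ddof=1)
    nonzero = np.abs(mean) > 1e-12
    rel_sd = np.full(grid.shape, np.nan)
    rel_sd[nonzero] = sd[nonzero] / np.abs(mean[nonzero])
    summary_pct = float(np.nanmean(rel_sd) * 100.0) if nonzero.any() else 0.0
    return rel_sd, summary_pct


@dataclass
class ContrastReport:
    """Per-bead fringe contrast C = (M - m) / (M + m - 2b) and aggregates.

    Out-of-range contrasts are reported and flagged, never clipped;
    beads with nonpositive denominator are flagged and excluded from the
    mean/sd.
    """

    bead_positions: np.ndarray  # (n, 2) row, col of the bead peak pixel
    contrasts: np.ndarray
    flagged: np.ndarray  # bool: excluded from aggregates
    dark_level: float
    n_requested: int

    @property
    def valid_contrasts(self) -> np.ndarray:
        return self.contrasts[~self.flagged]

    @property
    def mean(self) -> float:
        return float(self.valid_contrasts.mean())

    @property
    def sd(self) -> float:
        v = self.valid_contrasts
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    @property
    def n_used(self) -> int:
        return int((~self.flagged).sum())


def _detect_beads(
    mean_frame: np.ndarray,
    dark_level: float,
    min_distance_px: int,
    detect_snr: float = 5.0,
) -> np.ndarray:
    background = mean_frame[mean_frame <= np.percentile(mean_frame, 50)]
    noise_sd = float(np.std(background)) if background.size > 1 else 0.0
    # noise-free frames have a zero noise floor; fall back to a small
    # fraction of the dynamic range so the threshold stays above background
    floor = 0.02 * max(mean_frame.max() - dark_level, 0.0)
    threshold = dark_level + max(detect_snr * noise_sd, floor, 1e-9)
    return peak_local_max(
        mean_frame, min_distance=min_distance_px, threshold_abs=threshold
    )


def bead_contrast(
    stack: ImageStack,
    b: float | None = None,
    n_brightest: int = 100,
    positions: np.ndarray | None = None,
    min_distance_px: int = 4,
    intensity: str = "peak",
) -> ContrastReport:
    """Fringe contrast from phase-stepped images of point-like beads.

    Beads are detected as local maxima of the phase-averaged frame (or taken
    from ``positions``); for each of the ``n_brightest`` beads the maximum
    ``M`` and minimum ``m`` of its intensity across the phase steps give
    ``C = (M - m) / (M + m - 2 b)`` with ``b`` the camera dark level
    (defaults to the stack's recorded offset).  ``intensity`` selects the
    bead readout: the brightest pixel (``'peak'``, default) or the summed
    3x3 neighborhood (``'integrated'``).
    """
    if len(stack) < 5:
        raise ValueError("need at least 5 phase steps spanning the pattern period")
    if intensity not in ("peak", "integrated"):
        raise ValueError("intensity must be 'peak' or 'integrated'")
    if b is None:
        b = stack.camera_offset
    mean_frame = stack.frames.mean(axis=0)
    if positions is None:
        positions = _detect_beads(mean_frame, b, min_distance_px)
        if len(positions) == 0:
            raise ValueError("no beads detected above the noise floor")
    positions = np.asarray(positions, dtype=int)
    brightness = mean_frame[positions[:, 0], positions[:, 1]]
    order = np.argsort(brightness)[::-1]
    if len(order) < n_brightest:
        import warnings

        warnings.warn(
            f"only {len(order)} beads available (requested {n_brightest})",
            stacklevel=2,
        )
    keep = order[:n_brightest]
    positions = positions[keep]

    n_frames = len(stack)
    if intensity == "peak":
        traces = stack.frames[:, positions[:, 0], positions[:, 1]]
    else:
        H, W = stack.frames.shape[1:]
        traces = np.zeros((n_frames, len(positions)))
        for j, (r, c) in enumerate(positions):
            r0, r1 = max(r - 1, 0), min(r + 2, H)
            c0, c1 = max(c - 1, 0), min(c + 2, W)
            traces[:, j] = stack.frames[:, r0:r1, c0:c1].sum(axis=(1, 2))
        # integrated readout sums 9 dark-offset contributions
        b = b * 9

    M = traces.max(axis=0)
    m = traces.min(axis=0)
    denom = M + m - 2 * b
    contrasts = np.full(len(positions), np.nan)
    ok = denom > 0
    contrasts[ok] = (M[ok] - m[ok]) / denom[ok]
    # out-of-range values are retained unclipped in `contrasts`; only
    # nonpositive denominators are excluded from the aggregates
    return ContrastReport(
        bead_positions=positions,
        contrasts=contrasts,
        flagged=~ok,
        dark_level=float(b),
        n_requested=n_brightest,
    )


def find_contrast_extrema(
    state: DeviceState,
    voltage_grid: np.ndarray,
    train: OpticalTrain | None = None,
) -> dict:
    """Voltages of maximal and minimal simulated fringe contrast.

    Sweeps the MZI heater voltage over ``voltage_grid``, computes the fringe
    modulation at each point from the device output powers, and returns the
    grid points of the extrema.  Maximum contrast occurs at the balanced
    split; minimum where the split is most unbalanced.  If the coupler ratio
    is outside the balance-feasible range the achievable maximum is reported
    with a flag.
    """
    voltage_grid = np.asarray(voltage_grid, dtype=float)
    if train is None:
        train = OpticalTrain(wavelength_nm=state.wavelength_nm)
    period = pattern_period(train.replace(wavelength_nm=state.wavelength_nm))
    modulations = np.empty(voltage_grid.shape)
    for i, v in enumerate(voltage_grid):
        st = state.replace(v_mzi=float(v))
        p1, p2, _ = device_outputs(st)
        if p1 + p2 == 0:
            modulations[i] = 0.0
        else:
            modulations[i] = fringe_field(
                p1, p2, st.background_power, 0.0, period
            ).modulation
    i_max = int(np.argmax(modulations))
    i_min = int(np.argmin(modulations))
    from .device import balance_feasible

    feasible = balance_feasible(state.coupler_ratio)
    return {
        "v_max_contrast": float(voltage_grid[i_max]),
        "v_min_contrast": float(voltage_grid[i_min]),
        "max_modulation": float(modulations[i_max]),
        "min_modulation": float(modulations[i_min]),
        "modulations": modulations,
        "balance_feasible": feasible,
    }
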