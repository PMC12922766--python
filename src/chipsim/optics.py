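"""Free-space optical train: chip facet -> relay -> objective pupil -> sample.

The two guided beams leave the chip separated by ``d_chip`` and are relayed
(4f telescopes with focal lengths f1, f2, f3 and tube lens fT) onto the
objective back focal plane, where their separation is
``d_pp = (f2 fT) / (f1 f3) * d_chip``.  Two focused spots in the pupil
become two interfering plane waves at the sample; the fringe period follows
from the sine condition ``n sin(theta) = r / f_obj`` with ``f_obj = fT / M``,
giving ``period = lambda * f_obj / d_pp``.  The theoretical 1D-SIM
resolution-enhancement factor is ``F = 1 + d_pp / D`` with pupil diameter
``D = 2 NA fT / M``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OpticalTrain",
    "IlluminationPattern",
    "pupil_separation",
    "pupil_diameter",
    "enhancement_factor",
    "pattern_period",
    "fringe_field",
]


@dataclass(frozen=True)
class OpticalTrain:
    """Relay + objective geometry.

    Focal lengths in mm; ``d_chip_mm`` is the chip output separation;
    ``NA``/``magnification`` describe the imaging objective and
    ``immersion_index`` its immersion medium; ``wavelength_nm`` is the
    illumination wavelength.
    """

    f1_mm: float = 40.0
    f2_mm: float = 150.0
    f3_mm: float = 100.0
    fT_mm: float = 200.0
    d_chip_mm: float = 1.0
    NA: float = 1.49
    magnification: float = 60.0
    immersion_index: float = 1.515
    wavelength_nm: float = 638.0

    def __post_init__(self) -> None:
        for name in ("f1_mm", "f2_mm", "f3_mm", "fT_mm", "d_chip_mm", "NA",
                     "magnification", "wavelength_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.NA > self.immersion_index:
            raise ValueError("NA cannot exceed the immersion index")

    @property
    def f_obj_mm(self) -> float:
        """Objective focal length fT / M."""
        return self.fT_mm / self.magnification

    def replace(self, **changes) -> "OpticalTrain":
        import dataclasses

        return dataclasses.replace(self, **changes)


def pupil_separation(train: OpticalTrain) -> float:
    """Beam separation at the objective pupil plane, mm."""
    return train.f2_mm * train.fT_mm / (train.f1_mm * train.f3_mm) * train.d_chip_mm


def pupil_diameter(train: OpticalTrain) -> float:
    """Objective back-aperture diameter D = 2 NA fT / M, mm."""
    return 2.0 * train.NA * train.fT_mm / train.magnification


def enhancement_factor(train: OpticalTrain) -> float:
    """Theoretical 1D-SIM resolution enhancement F = 1 + d_pp / D."""
    d_pp = pupil_separation(train)
    D = pupil_diameter(train)
    if d_pp > D:
        raise ValueError(
            f"beam separation {d_pp:.2f} mm exceeds the pupil diameter "
            f"{D:.2f} mm: the pattern falls outside the objective aperture"
        )
    return 1.0 + d_pp / D


def pattern_period(train: OpticalTrain) -> float:
    """Sample-plane fringe period, nm.

    Each beam sits at pupil height d_pp/2, i.e. at angle
    ``n sin(theta) = (d_pp / 2) / f_obj``; two such plane waves interfere
    with period ``lambda / (2 n sin(theta)) = lambda * f_obj / d_pp``.
    """
    d_pp = pupil_separation(train)
    if d_pp == 0:
        raise ValueError("zero beam separation produces no fringe")
    return train.wavelength_nm * train.f_obj_mm / d_pp


@dataclass(frozen=True)
class IlluminationPattern:
    """Sinusoidal sample-plane illumination.

    ``I(x) = mean_intensity * (1 + modulation * cos(2 pi x / period + phase))``
    with the fringe oriented along the horizontal image axis.
    """

    period_nm: float
    modulation: float
    phase_rad: float = 0.0
    mean_intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.period_nm <= 0:
            raise ValueError("period must be positive")
        if not 0.0 <= self.modulation <= 1.0:
            raise ValueError("modulation must be in [0, 1]")
        if self.mean_intensity < 0:
            raise ValueError("mean intensity must be nonnegative")

    def intensity(self, x_nm):
        """Illumination intensity at horizontal position(s) x (nm)."""
        import numpy as np

        x = np.asarray(x_nm, dtype=float)
        return self.mean_intensity * (
            1.0 + self.modulation * np.cos(2.0 * math.pi * x / self.period_nm + self.phase_rad)
        )

    def replace(self, **changes) -> "IlluminationPattern":
        import dataclasses

        return dataclasses.replace(self, **changes)


def fringe_field(
    P1: float,
    P2: float,
    background: float,
    phase: float,
    period_nm: float,
) -> IlluminationPattern:
    """Interference fringe produced by two beams plus incoherent background.

    Two coherent beams of powers P1, P2 interfere with visibility
    ``2 sqrt(P1 P2) / (P1 + P2)``; a non-interfering uniform background adds
    to the mean intensity only, degrading the modulation to
    ``2 sqrt(P1 P2) / (P1 + P2 + background)``.
    """
    if P1 < 0 or P2 < 0 or background < 0:
        raise ValueError("powers must be nonnegative")
    total = P1 + P2 + background
    if P1 + P2 == 0:
        raise ValueError("at least one guided beam must carry power")
    modulation = 2.0 * math.sqrt(P1 * P2) / total
    return IlluminationPattern(
        period_nm=period_nm,
        modulation=modulation,
        phase_rad=phase,
        mean_intensity=total,
    )
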