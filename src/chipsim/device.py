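"""Photonic-chip model: directional couplers, tunable MZI, thermo-optic shifters.

The chip carries a Mach-Zehnder interferometer (MZI) built from two
identical directional couplers with a resistive heater on one arm, followed
by a second heater on one of the two output waveguides.  The MZI heater sets
the power split between the two outputs (and hence the fringe contrast at
the sample); the output heater sets their relative optical phase (and hence
the lateral fringe position).

Conventions
-----------
* The splitting ratio ``R`` of a coupler is the fraction of power that stays
  in the arm where light was input, so ``R = 0.5`` is a balanced 50/50
  splitter.
* The whole-device splitting ratio for a relative arm phase ``phi`` is
  ``1 - 4 R (1 - R) cos^2(phi / 2)``: it spans ``[1 - 4R(1-R), 1]`` and a
  balanced 50% output is reachable iff ``R`` lies in
  ``[0.25 (2 - sqrt 2), 0.25 (2 + sqrt 2)]`` (14.6 %..85.4 %).
* Heater phase follows the thermo-optic law
  ``dphi(V) = (2 pi / lambda) * (dn/dT) * dT(V) * L`` with Joule heating
  ``dT(V) = kappa * V^2 / R_heater``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "CouplerSpec",
    "HeaterModel",
    "DeviceState",
    "BalanceUnreachableError",
    "mzi_output_ratio",
    "sr_range",
    "balance_feasible",
    "heater_phase",
    "device_outputs",
    "find_balance_voltage",
    "FEASIBLE_R_MIN",
    "FEASIBLE_R_MAX",
]

#: endpoints of the coupler splitting-ratio range for which the MZI can
#: still reach a balanced (50 %) output: roots of 1 - 4R(1-R) = 1/2
FEASIBLE_R_MIN = 0.25 * (2.0 - math.sqrt(2.0))
FEASIBLE_R_MAX = 0.25 * (2.0 + math.sqrt(2.0))


class BalanceUnreachableError(ValueError):
    """A balanced 50 % split cannot be reached for this coupler."""


def _check_ratio(R: float) -> None:
    if not 0.0 <= R <= 1.0:
        raise ValueError(f"splitting ratio must be in [0, 1], got {R}")


@dataclass(frozen=True)
class CouplerSpec:
    """Wavelength-dependent splitting ratio of the two (identical) couplers.

    The lookup is exact-match by wavelength: the couplers are calibrated at
    discrete laser lines and no spectral interpolation is attempted.
    """

    splitting_ratio_by_wavelength: dict[float, float]

    def __post_init__(self) -> None:
        for wl, R in self.splitting_ratio_by_wavelength.items():
            if wl <= 0:
                raise ValueError(f"wavelength must be positive, got {wl}")
            _check_ratio(R)

    def ratio(self, wavelength_nm: float) -> float:
        try:
            return self.splitting_ratio_by_wavelength[float(wavelength_nm)]
        except KeyError:
            known = sorted(self.splitting_ratio_by_wavelength)
            raise KeyError(
                f"no calibrated splitting ratio at {wavelength_nm} nm "
                f"(calibrated wavelengths: {known})"
            ) from None


@dataclass(frozen=True)
class HeaterModel:
    """Thermo-optic phase shifter: gold resistor over one waveguide.

    Parameters
    ----------
    resistance_ohm : heater electrical resistance.
    length_mm : heated waveguide length ``L``.
    dn_dT : thermo-optic coefficient of the substrate glass, 1/K.
    kappa_K_per_W : lumped thermal coefficient — steady-state temperature
        rise of the waveguide per watt of dissipated electrical power.  It is
        a free parameter of the simulation (the chip geometry and heat
        sinking set it in hardware); the default is chosen so that a full
        2 pi shift occurs at 12 V for 638 nm light, matching the operating
        voltage range of the real heaters.
    max_voltage : highest drive voltage accepted.
    """

    resistance_ohm: float = 240.0
    length_mm: float = 3.0
    dn_dT: float = 7e-6
    kappa_K_per_W: float = field(default=None)  # type: ignore[assignment]
    max_voltage: float = 12.0

    def __post_init__(self) -> None:
        if self.resistance_ohm <= 0 or self.length_mm <= 0:
            raise ValueError("resistance and length must be positive")
        if self.kappa_K_per_W is None:
            object.__setattr__(
                self,
                "kappa_K_per_W",
                _kappa_for_full_shift(self, voltage=12.0, wavelength_nm=638.0),
            )
        if self.kappa_K_per_W < 0:
            raise ValueError("kappa must be nonnegative")

    def temperature_rise(self, voltage: float) -> float:
        """Steady-state temperature rise (K) from Joule heating V^2/R."""
        self._check_voltage(voltage)
        return self.kappa_K_per_W * voltage**2 / self.resistance_ohm

    def phase(self, voltage: float, wavelength_nm: float) -> float:
        """Optical phase shift (rad) at the given drive voltage and wavelength."""
        dT = self.temperature_rise(voltage)
        wavelength_m = wavelength_nm * 1e-9
        length_m = self.length_mm * 1e-3
        return 2.0 * math.pi / wavelength_m * self.dn_dT * dT * length_m

    def voltage_for_phase(self, phase_rad: float, wavelength_nm: float) -> float:
        """Invert the quadratic phase law; raises if above the voltage range."""
        if phase_rad < 0:
            raise ValueError("phase must be nonnegative")
        if phase_rad == 0.0:
            return 0.0
        full = self.phase(self.max_voltage, wavelength_nm)
        if full <= 0:
            raise ValueError("heater produces no phase shift (kappa = 0?)")
        v = self.max_voltage * math.sqrt(phase_rad / full)
        if v > self.max_voltage * (1 + 1e-12):
            raise ValueError(
                f"phase {phase_rad:.3f} rad needs {v:.2f} V, above the "
                f"{self.max_voltage} V limit"
            )
        return min(v, self.max_voltage)

    def _check_voltage(self, voltage: float) -> None:
        if voltage < 0 or voltage > self.max_voltage:
            raise ValueError(
                f"voltage {voltage} V outside [0, {self.max_voltage}] V"
            )


def _kappa_for_full_shift(
    heater: HeaterModel, voltage: float, wavelength_nm: float
) -> float:
    """kappa such that the heater reaches 2 pi at `voltage` for `wavelength_nm`."""
    wavelength_m = wavelength_nm * 1e-9
    length_m = heater.length_mm * 1e-3
    dT_needed = wavelength_m / (heater.dn_dT * length_m)  # dphi = 2 pi
    return dT_needed * heater.resistance_ohm / voltage**2


def heater_phase(voltage: float, heater: HeaterModel, wavelength_nm: float) -> float:
    """Functional alias for :meth:`HeaterModel.phase`."""
    return heater.phase(voltage, wavelength_nm)


def mzi_output_ratio(R: float, phi: float) -> float:
    """Whole-device splitting ratio 1 - 4R(1-R)cos^2(phi/2).

    ``R`` is the (common) coupler splitting ratio and ``phi`` the relative
    phase between the interferometer arms.  The result is the fraction of
    the total guided output power exiting the arm corresponding to the
    input waveguide.
    """
    _check_ratio(R)
    return 1.0 - 4.0 * R * (1.0 - R) * math.cos(phi / 2.0) ** 2


def sr_range(R: float) -> tuple[float, float]:
    """Reachable whole-device splitting-ratio interval for coupler ratio R."""
    _check_ratio(R)
    return (1.0 - 4.0 * R * (1.0 - R), 1.0)


def balance_feasible(R: float) -> bool:
    """Can the MZI reach an even 50/50 output split with coupler ratio R?

    True iff ``1 - 4R(1-R) <= 1/2`` (endpoints inclusive, with a small
    floating-point guard so the exact analytic endpoints qualify).
    """
    lo, _ = sr_range(R)
    return lo <= 0.5 + 1e-12


@dataclass(frozen=True)
class DeviceState:
    """Full chip state: couplers, the two heaters, drive voltages, stray light.

    ``background_fraction`` is the share of the total output power carried
    by light that never coupled into the waveguides; it propagates through
    the substrate and emerges as a spatially uniform, non-interfering
    background (34 % of the output without the gold output mask, under 1 %
    with it).
    """

    coupler: CouplerSpec
    mzi_heater: HeaterModel
    output_heater: HeaterModel
    v_mzi: float = 0.0
    v_phase: float = 0.0
    input_power: float = 1.0
    background_fraction: float = 0.01
    wavelength_nm: float = 638.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")
        if self.input_power < 0:
            raise ValueError("input_power must be nonnegative")

    @property
    def coupler_ratio(self) -> float:
        return self.coupler.ratio(self.wavelength_nm)

    @property
    def background_power(self) -> float:
        return self.input_power * self.background_fraction

    def replace(self, **changes) -> "DeviceState":
        import dataclasses

        return dataclasses.replace(self, **changes)


def device_outputs(state: DeviceState) -> tuple[float, float, float]:
    """Guided output powers (P1, P2) and their relative phase.

    P1 is the output in the arm corresponding to the input waveguide.  The
    interferometer itself is lossless: P1 + P2 equals the input power minus
    the uncoupled background share.
    """
    R = state.coupler_ratio
    phi_mzi = state.mzi_heater.phase(state.v_mzi, state.wavelength_nm)
    ratio = mzi_output_ratio(R, phi_mzi)
    guided = state.input_power * (1.0 - state.background_fraction)
    p1 = guided * ratio
    p2 = guided * (1.0 - ratio)
    rel_phase = state.output_heater.phase(state.v_phase, state.wavelength_nm)
    return p1, p2, rel_phase


def find_balance_voltage(state: DeviceState, tol: float = 1e-6) -> float:
    """MZI-heater voltage at which power is evenly split between the outputs.

    Solves ``mzi_output_ratio(R, phi(V)) = 1/2`` on the first monotone
    branch of the quadratic phase law, by bracketed root finding; ``tol``
    is the tolerance on the splitting ratio.
    """
    R = state.coupler_ratio
    if not balance_feasible(R):
        raise BalanceUnreachableError(
            f"coupler splitting ratio {R:.3f} cannot reach a balanced output; "
            f"feasible range is [{FEASIBLE_R_MIN:.4f}, {FEASIBLE_R_MAX:.4f}]"
        )
    heater = state.mzi_heater
    wl = state.wavelength_nm

    def residual(v: float) -> float:
        return mzi_output_ratio(R, heater.phase(v, wl)) - 0.5

    # Restrict to the first monotone branch: phi in [0, pi].
    try:
        v_hi = heater.voltage_for_phase(math.pi, wl)
    except ValueError as exc:
        raise BalanceUnreachableError(
            f"heater cannot reach a pi phase shift within its voltage range: {exc}"
        ) from exc
    lo, hi = residual(0.0), residual(v_hi)
    if lo > 0 and hi > 0 or lo < 0 and hi < 0:
        # ratio is monotone increasing on the branch; 0.5 must be bracketed
        raise BalanceUnreachableError(
            "balanced split not bracketed on the first phase branch"
        )
    v_star = brentq(residual, 0.0, v_hi, xtol=1e-12)
    # refine until the ratio tolerance is met (brentq xtol is on voltage)
    assert abs(residual(v_star)) < tol
    return float(v_star)
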