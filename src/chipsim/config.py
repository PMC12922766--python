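"""Run configuration: defaults mirroring the physical setup, strict validation.

A run is described by a plain-text YAML file with four sections —
``device``, ``train``, ``phantom``, ``analysis`` — all optional: omitted
keys take the defaults below, which reproduce the hardware being modelled
(240-ohm heaters, coupler splitting ratios 0.491 @ 638 nm / 0.819 @ 561 nm,
60x/1.49 objective, 34 % stray-light background without the output mask and
1 % with it).  Unknown keys are rejected with the offending key named.
Every run serializes its fully resolved configuration next to its outputs.
"""

from __future__ import annotations

import copy
import hashlib
from typing import Any

import yaml

from .device import CouplerSpec, DeviceState, HeaterModel
from .optics import OpticalTrain
from .phantoms import NoiseModel

__all__ = ["DEFAULTS", "RunConfig", "load_config"]

DEFAULTS: dict[str, dict[str, Any]] = {
    "device": {
        "splitting_ratio_by_wavelength": {638.0: 0.491, 561.0: 0.819},
        "heater_resistance_ohm": 240.0,
        "heater_length_mm": 3.0,
        "dn_dT": 7e-6,
        "kappa_K_per_W": None,  # None -> 2 pi shift at 12 V, 638 nm
        "max_voltage": 12.0,
        "masked": True,
        "background_fraction_mask": 0.01,
        "background_fraction_no_mask": 0.34,
        "input_power": 1.0,
        "wavelength_nm": 638.0,
    },
    "train": {
        "f1_mm": 40.0,
        "f2_mm": 150.0,
        "f3_mm": 100.0,
        "fT_mm": 200.0,
        "d_chip_mm": 1.0,
        "NA": 1.49,
        "magnification": 60.0,
        "immersion_index": 1.515,
        "pixel_size_nm": 65.0,
    },
    "phantom": {
        "type": "beads",  # beads | sectioning | sheet
        "field": [256, 256],
        "n_beads": 120,
        "min_spacing_px": 12.0,
        "brightness_range": [1000.0, 3000.0],
        "n_planes": 2,
        "z_spacing_um": 6.0,
        "sheet_density": 1000.0,
        "seed": 0,
        "noisy": False,
        "dark_offset": 100.0,
        "read_noise_sd": 2.0,
        "psf_model": "gaussian",
    },
    "analysis": {
        "mode": "sim",  # calibration | hilo | sim
        "voltages": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12],
        "n_phases": 3,
        "wavelengths": None,  # None -> device wavelength only
        "b": None,  # None -> stack camera offset
        "n_brightest": 100,
        "fc_override": None,
        "wiener_eps": 1e-2,
        "input_tiff": None,  # reconstruct a stack on disk instead of simulating
    },
}


def _merge_strict(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(f"unknown configuration key: {where!r}")
        if isinstance(defaults[key], dict) and key != "splitting_ratio_by_wavelength":
            if not isinstance(value, dict):
                raise ValueError(f"{where!r} must be a mapping")
            out[key] = _merge_strict(defaults[key], value, where)
        else:
            out[key] = value
    return out


class RunConfig:
    """Fully resolved run configuration with typed accessors."""

    def __init__(self, overrides: dict | None = None) -> None:
        overrides = overrides or {}
        for section in overrides:
            if section not in DEFAULTS:
                raise KeyError(f"unknown configuration section: {section!r}")
        self.data = {
            section: _merge_strict(DEFAULTS[section], overrides.get(section, {}), section)
            for section in DEFAULTS
        }

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw)

    # -- serialization -----------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the resolved configuration."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    # -- typed views -------------------------------------------------------
    def device_state(self, wavelength_nm: float | None = None) -> DeviceState:
        d = self.data["device"]
        coupler = CouplerSpec(
            {float(k): float(v) for k, v in d["splitting_ratio_by_wavelength"].items()}
        )
        heater = HeaterModel(
            resistance_ohm=d["heater_resistance_ohm"],
            length_mm=d["heater_length_mm"],
            dn_dT=d["dn_dT"],
            kappa_K_per_W=d["kappa_K_per_W"],
            max_voltage=d["max_voltage"],
        )
        background = (
            d["background_fraction_mask"] if d["masked"] else d["background_fraction_no_mask"]
        )
        return DeviceState(
            coupler=coupler,
            mzi_heater=heater,
            output_heater=heater,
            input_power=d["input_power"],
            background_fraction=background,
            wavelength_nm=float(wavelength_nm or d["wavelength_nm"]),
        )

    def optical_train(self, wavelength_nm: float | None = None) -> OpticalTrain:
        t = self.data["train"]
        return OpticalTrain(
            f1_mm=t["f1_mm"],
            f2_mm=t["f2_mm"],
            f3_mm=t["f3_mm"],
            fT_mm=t["fT_mm"],
            d_chip_mm=t["d_chip_mm"],
            NA=t["NA"],
            magnification=t["magnification"],
            immersion_index=t["immersion_index"],
            wavelength_nm=float(
                wavelength_nm or self.data["device"]["wavelength_nm"]
            ),
        )

    def noise_model(self) -> NoiseModel:
        p = self.data["phantom"]
        return NoiseModel(
            dark_offset=p["dark_offset"], read_noise_sd=p["read_noise_sd"]
        )

    def phantom(self):
        from . import phantoms as ph

        p = self.data["phantom"]
        t = self.data["train"]
        field = tuple(p["field"])
        if p["type"] == "beads":
            return ph.make_bead_phantom(
                n_beads=p["n_beads"],
                field=field,
                pixel_size_nm=t["pixel_size_nm"],
                brightness_range=tuple(p["brightness_range"]),
                min_spacing_px=p["min_spacing_px"],
                seed=p["seed"],
            )
        if p["type"] == "sectioning":
            return ph.make_sectioning_phantom(
                field=field,
                pixel_size_nm=t["pixel_size_nm"],
                n_planes=p["n_planes"],
                z_spacing_um=p["z_spacing_um"],
                seed=p["seed"],
            )
        if p["type"] == "sheet":
            return ph.make_sheet_phantom(
                field=field,
                pixel_size_nm=t["pixel_size_nm"],
                density=p["sheet_density"],
            )
        raise ValueError(f"unknown phantom type {p['type']!r}")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration (or defaults) with optional overrides."""
    cfg = RunConfig.from_yaml(path) if path else RunConfig()
    if overrides:
        merged = _merge_strict(cfg.data, overrides)
        out = RunConfig()
        out.data = merged
        return out
    return cfg
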