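"""Shared fixtures: default device/train and small synthetic stacks."""

from __future__ import annotations

import math

import numpy as np
import pytest

from chipsim.config import RunConfig
from chipsim.device import CouplerSpec, DeviceState, HeaterModel
from chipsim.optics import OpticalTrain
from chipsim.phantoms import (
    NoiseModel,
    acquire_series,
    make_bead_phantom,
    make_sheet_phantom,
)


@pytest.fixture(scope="session")
def heater() -> HeaterModel:
    return HeaterModel()


@pytest.fixture(scope="session")
def coupler() -> CouplerSpec:
    return CouplerSpec({638.0: 0.491, 561.0: 0.819})


@pytest.fixture(scope="session")
def device_state(coupler, heater) -> DeviceState:
    return DeviceState(coupler=coupler, mzi_heater=heater, output_heater=heater)


@pytest.fixture(scope="session")
def train() -> OpticalTrain:
    return OpticalTrain()


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def sheet_calibration_stack(device_state, train):
    """Noise-free phase-voltage calibration stack of a uniform dye sheet."""
    sheet = make_sheet_phantom((128, 128), 65.0, 1000.0)
    voltages = list(np.linspace(0.0, 12.0, 13))
    return acquire_series(device_state, train, sheet, "calibration", voltages=voltages)


@pytest.fixture(scope="session")
def bead_sim_stack(device_state, train):
    """Noise-free 3-phase SIM stack of isolated beads (diffraction PSF)."""
    beads = make_bead_phantom(22, (256, 256), 65.0, min_spacing_px=32, seed=3)
    stack = acquire_series(device_state, train, beads, "sim", psf_model="diffraction")
    return beads, stack


@pytest.fixture(scope="session")
def dense_phase_bead_stack(device_state, train):
    """Beads under a dense (24-step) phase sweep for contrast estimation."""
    beads = make_bead_phantom(120, (256, 256), 65.0, seed=1)
    phases = list(np.linspace(0.0, 2.0 * math.pi, 24, endpoint=False))
    stack = acquire_series(device_state, train, beads, "sim", phases=phases)
    return beads, stack
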