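#!/usr/bin/env python
"""Dual-color 3-phase 1D-SIM reconstruction and enhancement measurement.

Acquires sequential 638/561 nm phase-stepped bead stacks with the MZI
balanced at each color, reconstructs with band separation + generalized
Wiener recombination, and measures (a) the spectral-support extension along
the pattern axis against the theoretical factor F = 1 + f_pattern/f_c and
(b) the vertical/horizontal FWHM ratio of the bead images (only the
horizontal axis is resolution-enhanced).
Writes results/sim_reconstruction/summary.json and the reconstructions.
"""

import json
from pathlib import Path

import numpy as np

from chipsim.config import RunConfig
from chipsim.optics import IlluminationPattern, enhancement_factor
from chipsim.phantoms import (
    DetectionPSF,
    ImageStack,
    NoiseModel,
    acquire_series,
    make_bead_phantom,
)
from chipsim.simrecon import (
    measure_enhancement,
    reconstruct,
    spectral_support_radius,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "sim_reconstruction"
SEED = 3


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    beads = make_bead_phantom(22, (256, 256), 65.0, min_spacing_px=32, seed=SEED)
    train = cfg.optical_train()
    state = cfg.device_state()
    stack = acquire_series(state, train, beads, "sim",
                           wavelengths=[638.0, 561.0], psf_model="diffraction")

    summary, recon_frames = {}, []
    for wl in (638.0, 561.0):
        sub = stack.select(wavelength_nm=wl)
        period = sub.meta[0]["period_nm"]
        freq = 65.0 / period
        otf = DetectionPSF(NA=train.NA, wavelength_nm=wl, pixel_size_nm=65.0,
                           model="diffraction")
        phases = np.array([m["phase_rad"] for m in sub.meta])
        res = reconstruct(sub.frames - stack.camera_offset, freq, otf,
                          phases=phases)
        from chipsim.phantoms import render

        widefield = render(
            beads,
            IlluminationPattern(period_nm=period, modulation=0.0,
                                mean_intensity=1.0),
            otf, NoiseModel(dark_offset=0.0),
        )
        fc = otf.cutoff_per_nm * 65.0
        sx = spectral_support_radius(res.image, "x") * res.upsample
        wx = spectral_support_radius(widefield, "x")
        enh = measure_enhancement(widefield, res.image, beads.bead_centers)
        recon_frames.append(res.image)
        summary[f"{wl:g}nm"] = {
            "pattern_period_nm": period,
            "theoretical_F": enhancement_factor(train.replace(wavelength_nm=wl)),
            "support_extension": sx / wx,
            "mean_width_ratio": enh["mean_ratio"],
            "width_ratio_quartiles": list(map(float, enh["quartiles"])),
            "n_beads": enh["n_beads"],
            "modulation_estimate": res.modulation,
        }
        print(f"{wl:g} nm: period {period:.1f} nm, theoretical F = "
              f"{summary[f'{wl:g}nm']['theoretical_F']:.3f}, measured support "
              f"extension {sx/wx:.3f}, bead width ratio "
              f"{enh['mean_ratio']:.2f} over {enh['n_beads']} beads")

    ImageStack(frames=np.stack(recon_frames),
               meta=[{"mode": "sim", "wavelength_nm": wl} for wl in (638.0, 561.0)],
               pixel_size_nm=65.0 / 2).save(OUT / "sim_reconstruction.tif")
    (OUT / "summary.json").write_text(json.dumps(summary, indent=1))
    print(f"\nArtifacts in {OUT}")


if __name__ == "__main__":
    main()
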