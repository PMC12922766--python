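# Methods

## Device model

The chip is modelled as two identical directional couplers (splitting
ratio *R*, exact-match lookup per calibrated wavelength — no spectral
interpolation, since couplers are characterized only at discrete laser
lines) joined into a Mach–Zehnder interferometer with a thermo-optic
heater in one arm, followed by a second heater on one output waveguide.
The interferometer is treated as lossless: the two guided outputs sum to
the input power minus the stray-light share. The closed form for the
whole-device splitting ratio, `1 − 4R(1−R)cos²(φ/2)`, is verified in the
tests against explicit 2×2 transfer-matrix products (coupler · phase ·
coupler) to 1e-12.

**Thermo-optic law.** Measured phase–voltage data for the real heaters are
not tabulated anywhere, so the temperature rise is modelled as steady-state
Joule heating, ΔT(V) = κ·V²/R_h, with κ a lumped thermal coefficient
(kelvin per dissipated watt). Default parameters: R_h = 240 Ω, heated
length L = 3 mm, dn/dT = 7×10⁻⁶ /K (borosilicate glass), maximum drive
12 V. κ defaults to the value giving a full 2π shift at 12 V for 638 nm
light (≈50.6 K/W), consistent with the heaters' operating range; it is a
free simulation parameter, configurable per run. The 1/λ scaling of the
phase makes multicolor operation inherently sequential, and the
simulator's acquisition planner enforces that.

**Stray light.** Light that fails to couple into the waveguides emerges
from the output facet as a spatially uniform, *non-interfering* background
(no speckle structure is modelled). Its share of the output power defaults
to 34 % without the gold output mask and 1 % with it; it enters the fringe
model only through the modulation `2√(P1P2)/(P1+P2+B)`.

**Balance search.** The balanced-output voltage is found by bracketed
root-finding (Brent) on the first monotone branch of φ(V) ∈ [0, π], with a
1e-6 tolerance on the splitting ratio. Couplers outside
[0.25(2−√2), 0.25(2+√2)] raise an explicit "balance unreachable" error
naming the feasible range.

## Optical train

The pupil mapping uses the sine condition n·sinθ = r/f_obj with
f_obj = fT/M, making the pupil diameter D = 2·NA·fT/M and the fringe
period λ·f_obj/d_pp. Defaults (f1 = 40, f2 = 150, f3 = 100, fT = 200 mm,
d_chip = 1 mm, 60×/1.49 oil objective) give d_pp = 7.5 mm, D = 9.93 mm,
F = 1.755, and periods of 283.6 nm (638 nm) / 249.3 nm (561 nm); with the
0.5 mm chip at 561 nm, 498.7 nm. These periods follow from the stated
focal lengths alone; aberrations, pupil apodization and vectorial high-NA
effects are out of scope.

## Synthetic data

The generator emulates the three samples the characterization needs:

- **beads** — sub-diffraction point emitters, placed uniformly at random
  with a minimum pairwise spacing and deposited as single-pixel impulses
  (subpixel centers kept as annotations). Brightness uniform in
  1000–3000 counts.
- **sectioning phantom** — n_planes z-planes of smoothed random-walk
  filaments, each plane confined to its own vertical band of the field so
  in-focus and out-of-focus energy can be attributed unambiguously;
  default plane spacing 6 µm.
- **uniform sheet** — for fringe-phase calibration, where an extended
  emitter is what the real measurement uses.

The forward model per frame is
`Poisson(gain · exposure · Σ_z [object_z × I_illum] ⊛ PSF_z) + N(b, σ_r²)`
with dark offset b = 100 counts and read noise σ_r = 2 (camera gain and
offset are not documented for the real system; these are declared
defaults, recorded in the frame metadata so estimators can subtract them).
With no random generator supplied, the noise-free expectation plus b is
returned. The default pixel size of 65 nm Nyquist-samples the finest
fringe.

Two detection-PSF models sit behind one contract: a **Gaussian** with
in-focus width 0.21·λ/NA and defocus broadening
σ(z) = √(σ₀² + (z·NA/n)²) — analytically checkable and used for the HiLo
studies — and an exact **diffraction** model built from the analytic
incoherent OTF of a circular pupil (chat function, hard cutoff 2NA/λ),
used wherever a true frequency cutoff matters (SIM support measurements);
its defocus is an additional Gaussian broadening, which preserves the
cutoff. Emission wavelength is taken equal to excitation (no fluorophore
spectra). What the phantoms do **not** emulate: tissue scattering,
photobleaching, spectral bleed-through, fixed-pattern noise — so passing
tests certify the estimators and reconstructions, not robustness to those
real-data effects.

## Calibration analyses

**Pattern phase** is the complex argument of the image spectrum at the
integer DFT bin nearest the expected pattern frequency (no subpixel
interpolation). A Hann window is applied along the fringe axis first:
the fringe frequency generally falls between bins, and without the window
the leakage tail of the negative-frequency component biases the phase.
Curves are referenced to the first (zero-voltage) frame and unwrapped by
forcing successive increments into (−π, π], which presumes a voltage grid
dense enough that true increments stay below π (the quadratic law makes
late-sweep steps the largest). Curve-to-curve variability is summarized
as the mean over voltages of SD/mean across repeated curves, in percent.

**Bead contrast** uses C = (M−m)/(M+m−2b) with M, m the extremes of each
bead's intensity over the phase sweep. Bead intensity is the brightest
pixel of the bead by default (an integrated 3×3 variant is available);
beads are local maxima of the phase-averaged frame above a deterministic
threshold. Out-of-range contrasts are reported unclipped; beads with
nonpositive denominator are flagged and excluded from aggregates. A dense
sweep matters: with N equally spaced phases the sampled extremes
underestimate the true ones by the factor (N/π)·sin(π/N) (≈0.1 % at
N = 24, the analysis default). On an extended fluorescent sheet the same
estimator returns modulation × MTF(f_pattern) — the quantitative reason
point-like beads are the right sample for this measurement, asserted as a
test.

**Contrast extrema.** Over a voltage sweep covering a full MZI period, the
fringe-modulation maximum sits at the balanced split and the minimum at
the single-beam state (device SR = 1, modulation ≈ 0). The zero-voltage
modulation for an unbalanced coupler (e.g. 0.983 at R = 0.819) is neither
extreme.

## HiLo

Given a uniform and a structured image of the same plane, the structured
frame is first rescaled to the uniform frame's mean (so the difference
reflects modulation, not exposure), then `Dabs = |structured − uniform|`
is low-passed and the uniform image high-passed with **complementary
Gaussian filters** sharing the threshold frequency fc = f_pattern/2. The
filter transfer is exp(−f²/(2fc²)) — "threshold" interpreted as the 1/√e
characteristic frequency, a declared convention — and the complement is
one minus it, so the pair sums to one at every frequency exactly. The
fusion weight η is chosen so the radially averaged spectral magnitudes of
η·Lo and Hi match in a one-bin annulus at fc (spectral continuity at the
seam; the weight convention is not uniquely standard, so it is declared
here). Pattern frequency comes from acquisition metadata when present.

## SIM reconstruction

Three phase-stepped frames are mixed per spatial frequency as
`D_n = C0 + e^{iφn} C+ + e^{−iφn} C−`; the 3×3 system is inverted in one
vectorized solve (checked against a per-pixel brute-force solve to 1e-10)
and rejects near-singular phase triplets by condition number. Pattern
phases are retrieved a posteriori as above; on sparse bead fields the
object's own random spectral content at the pattern bin limits that
estimator (finite-N phasor noise), so the pipeline falls back to
acquisition metadata phases with a warning — retrieval accuracy is
asserted on extended samples, where the method is used in practice.

Recombination zero-pads the bands onto a 2× finer grid (the extended
cutoff f_c + f_p exceeds the camera Nyquist frequency at the default
sampling), shifts the side bands by ±f_p via real-space modulation (exact
for non-integer bin shifts), weights each band by the conjugate of its
shifted OTF, divides by Σ|OTF|² + ε with ε = 1e-2 (relative to the
unit-normalized OTF), and apodizes. The modulation depth used for band
weighting is estimated from the side-band-to-DC peak ratio, corrected for
MTF attenuation at f_p — no user input.

**Apodization convention.** A single isotropic triangular ramp from 1 at
DC to 0 at the extended cutoff f_c + f_p. An elliptical ramp (shorter axis
f_c along y) was considered and rejected: it additionally attenuates the
unenhanced axis, broadening the vertical PSF and inflating the
vertical/horizontal width-ratio statistic above the physically expected
~F; with the isotropic ramp the anisotropy of the result is carried
entirely by the OTF support, and the measured bead width ratio lands at
≈1.66 for the F = 1.755 configuration.

**Enhancement measurement.** Per isolated bead, horizontal and vertical
FWHM of the reconstructed spot from 1D profiles through the brightest
pixel, half-max crossings by linear interpolation (no Gaussian fitting);
overlapping beads are excluded, fewer than three valid beads is an error.
The statistic is the vertical/horizontal ratio (vertical is unenhanced).

## Problem sizes and numerical choices

Analyses and tests run on 64–256 px fields, 12–24 phase steps or
voltages, 20–120 beads, and 10 noisy repeats for variability studies —
sizes at which every quantity of interest (phase error, contrast bias,
support radii, width ratios) is already stable to well below the asserted
tolerances. Randomness is always drawn from one explicit seed per
invocation; acquisition order is frame order; all image I/O is multi-page
TIFF with a JSON metadata sidecar (lossless round trip, tested).

## Known limitations

- Thermal crosstalk between the two heaters is not modelled (negligible
  for the chip geometry being emulated) and neither is resistance drift.
- The fringe-period formula is the ideal sine-condition value; real relay
  trains can deviate at the few-percent level.
- The single-bin phase estimator is unsuitable for sparse scenes (see
  above); a cross-correlation retrieval would be the upgrade path.
- HiLo's η convention and the SIM Wiener/apodization settings are declared
  conventions: absolute intensities of fused or reconstructed images are
  meaningful only up to those choices.
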