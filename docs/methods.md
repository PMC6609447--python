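# Methods

This note records the scientific and numerical choices behind `oculight`:
what is computed, with which conventions and constants, what the synthetic
fixtures do and do not emulate, and where the open design decisions fell.

## Spectral representation and I/O

A stimulus is a tabulated spectral power distribution (SPD): a strictly
increasing wavelength grid (nm) with one spectral value per sample, tagged
as spectral irradiance (W·m⁻²·nm⁻¹) or spectral radiance
(W·m⁻²·sr⁻¹·nm⁻¹).  The kind tag propagates: irradiance input yields
alpha-opic irradiances (mW/m²) and illuminance (lux); radiance input yields
alpha-opic radiances (mW/(m²·sr)) and luminance (cd/m²).

Exchange format: uncompressed delimited ASCII, `# key: value` header lines
followed by `wavelength_nm,value` rows; comma, tab and semicolon are
accepted on input, comma is written.  Default exports cover 380–780 nm at
the input's native spacing clamped to 1–10 nm.  Numbers are written with
`repr`, the shortest decimal string that round-trips exactly, so
read → write → read is lossless and write → read → write is byte-identical.
Headers carry no auto-generated timestamps; a timestamp appears only when
supplied, keeping exports and rendered reports deterministic.

Resampling is piecewise linear — the convention for tabulated data, and the
choice that keeps oracle testing exact.  Values are never extrapolated:
outside the measured support the spectrum is zero-filled with a warning,
which is conservative for short-wavelength-weighted quantities.  Negative
samples (instrument noise) are retained and flagged; clipping to zero is an
explicit method call, never silent.

## Weighting functions (synthetic stand-ins)

The official standardized tabulations of the five alpha-opic sensitivities,
V(λ) and the blue-light hazard function are not redistributable with this
package, so the vendored tables are **synthetic stand-ins**, constructed
once, committed as ASCII files named `synthetic_*.csv`, and verified by
sha256 checksum at load time:

- **Alpha-opic functions** (1 nm, 380–780 nm): the Govardovskii et al.
  (2000) A1 pigment absorbance template (alpha + beta band) evaluated at the
  accepted pigment peaks — S 420, M 530, L 558, rods 500, melanopsin
  480 nm — multiplied by the 32-year lens transmittance of the two-component
  aging model below, and for the cones additionally by a macular-pigment
  template (Gaussian, peak density 0.10 at 460 nm, σ 25 nm, the scale
  appropriate to a 10° field).  Each function is unit-peak normalized.  The
  resulting corneal maxima (S-cone-opic 440, M 536, L 565, rhodopic 508,
  melanopic 487 nm) sit longward of the pigment peaks, as in the
  standardized functions, because pre-receptoral filtering removes short
  wavelengths.
- **V(λ)**: transcription of the widely published 5-nm photopic luminous
  efficiency tabulation, linearly interpolated to 1 nm; peak exactly 1.0 at
  555 nm.
- **B(λ)** (blue-light hazard): the widely published piecewise tabulation on
  its native 5-nm, 300–700 nm grid — unit plateau at 435–440 nm,
  10^((450−λ)/50) roll-off over 500–600 nm, 10⁻³ plateau to 700 nm.  It is
  kept on its native grid and aligned to SPDs by the shared resampler.

Consequence: absolute alpha-opic values computed with these tables agree
with the standardized ones in structure and behaviour but not digit-for-
digit; every threshold result in this package (safety limits, identity age)
is independent of table fidelity.

## Lens aging correction

Pre-receptoral filtering is modelled with the classic two-component lens
density model: D(λ, A) = TL1(λ)·g(A) + TL2(λ), with g(A) = 1 + 0.02(A−32)
for 20 ≤ A ≤ 60 and g(A) = 1.56 + 0.0667(A−60) for 60 < A ≤ 80 (continuous
at 60).  The correction applied to a weighting function is the transmittance
ratio 10^(−TL1(λ)·(g(A)−1)) relative to the 32-year standard observer: it is
exactly 1 at every wavelength at age 32, ≤ 1 at short wavelengths for older
observers, monotone non-increasing in age, and unity above 650 nm where TL1
vanishes.  Validity range 20–80 years; outside it the package raises rather
than extrapolating lens density.  The correction modifies the weighting
function, not the SPD — the stimulus is physical, the observer changes.
Corrected functions are deliberately not re-normalized.  The photopic entry
always uses standard V(λ): photometric units are defined for the standard
observer.

## Panel, photometry and photon system

Weighted integrals are rectangle sums Σ s(λ)·a(λ)·Δλ on a common 1-nm grid
over the overlapping support — the tabulated-toolbox convention.  The test
oracle is the independent alternative: trapezoid rule at 0.1-nm
oversampling.  The two agree to better than 10⁻³ relative for realistic
broadband and LED sources; for a narrowband source placed in the far tail of
an action spectrum (e.g. a deep-red line against the S-cone function) the
1-nm tabulation convention itself limits agreement to roughly the 10⁻³
level — a property of the convention, not of the implementation.

Constants: K_m = 683 lm/W exactly (the 683.002 variant is below reporting
precision); h = 6.62607015×10⁻³⁴ J·s and c = 299 792 458 m/s (CODATA 2018
exact).  Alpha-opic W→mW conversion (×1000) happens at panel assembly,
keeping the integral unit-neutral.  Photon irradiance is E_λ·λ/(hc) per
wavelength, ×10⁻⁴ to cm⁻², rectangle-summed; log₁₀ is reported as absent
for a zero spectrum.  Photon radiance is out of scope and rejected.

## Observer geometry

Visual angle is the planar formula θ = 2·atan(0.5·S/d) per dimension
(horizontal and vertical); no solid-angle computation.  Pupil diameter uses
the Watson & Yellott (2012) unified formula: Stanley–Davies base curve
D = 7.75 − 5.75·[(F/846)^0.41 / ((F/846)^0.41 + 2)] at effective corneal
flux density F = L·a·M(e) (L luminance in cd/m², a field area in deg²,
M = 1 binocular / 0.1 monocular), age-adjusted around the reference age
28.58 y via D + (y − 28.58)(0.02132 − 0.009562·D), clamped to the
physiological 1–10 mm range.  The variant identifier
`watson_yellott_2012_unified` is recorded in outputs.  The model ignores
non-luminance contributions to pupil control; none are corrected for.
A measured (or pharmacologically fixed) pupil always overrides the model and
is tagged `measured`; the model path is tagged `modelled`.  Trolands are
luminance × pupil area (mm²), not age-adjusted.

## Safety pre-screen

Decision logic, in order: luminance < 10,000 cd/m² → exempt (detailed
measurements typically not required; the weighted radiance is not computed
on this branch); otherwise the blue-light-weighted radiance is compared to
the risk-group-0 limit of 100 W/(m²·sr), binding for exposures longer than
10,000 s; a high-luminance source above the limit at shorter durations
passes with an explicit rationale that the long-exposure limit was not
triggered (time-dependent limits are not evaluated).  Every result carries
the caveat that regulatory compliance must be confirmed case by case.  The
full risk-group ladder, thermal, UV and skin hazards are out of scope.

## Compliance schema

The seven minimum reporting items are checked independently so that a single
omission flips exactly its own item: each SPD reference carries its own
"angle and distance from the source" note (items 1–2), distinct from the
stimulus geometry (item 6) and the instrument's measurement geometry
(item 7).  Missing elements fail; present-but-incomplete elements warn
(e.g. a flash-train timing block without flash duration, or a
manufacturer-tabulated stimulus spectrum without an in-situ photopic
illuminance measurement).  Validation is monotone: adding information never
turns a pass into a fail.  Clock times require ISO 8601 with timezone.  No
numeric "dim light" threshold is enforced for the background — presence of
a background SPD is what is checked.  Manifests are JSON (YAML accepted on
input) with a published JSON schema; reports render deterministically as
Markdown plus JSON.

## Synthetic fixtures: scope

- `planckian_spd(T)`: Planck's law in double precision on the 380–780 nm
  grid; absolute blackbody radiance scaled by a dimensionless factor.  Used
  as the high-luminance safety fixture (6500 K) and, heavily dimmed, as an
  incandescent-like background.
- `gaussian_led_spd`: area-normalized Gaussian bands, so a primary's weight
  is its band-integrated power.  The seeded random variant draws RGB(W)-like
  mixtures — one blue (440–480 nm), one green (510–560), one red
  (600–660), optionally a fourth broadband primary — emulating real
  multi-primary panels in which every photoreceptor class receives
  non-negligible drive.  Problem sizes in tests: 50 seeded mixtures for the
  oracle sweep.
- `monochromatic_spd`: single-bin lines (value = power/Δλ), not narrow
  Gaussians, so unit-peak pass-through identities are exact; off-grid
  wavelengths are rejected.
- `metamer_pair`: a blue-rich three-primary mixture and a long-wavelength
  two-primary mixture scaled to the same photopic value (equal within
  10⁻³ by construction); their melanopic irradiances differ severalfold —
  the executable demonstration that illuminance alone under-specifies a
  stimulus.
- `complete_record` / `deficient_record`: a fully populated exposure record
  (7/7 pass) and copies with named elements removed, for the compliance
  sweep.

What the fixtures do **not** emulate: instrument noise and stray light,
daylight (D-illuminant) spectra, sub-nm structure, and field-of-view
truncation by facial features.  Passing tests therefore demonstrate
correctness of the computations and decision logic, not robustness to
instrument artefacts.

## Known limitations

- The weighting tables are synthetic stand-ins; studies requiring the
  official standardized values digit-for-digit must substitute the official
  tabulations (same file format) — all logic is table-agnostic.
- Percentage-eyes-open and photograph/sketch items are free-text metadata;
  no estimation procedure is provided.
- Eye/head/trunk movement, retinal heterogeneity and individual differences
  beyond the lens-age model are not modelled.
- Chromaticity, CCT, colour rendering, melanopic EDI/DER and
  circadian dose-response models are out of scope.
- Sub-nm instrument data are resampled (linear), not bin-averaged.
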