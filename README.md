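# oculight

Retinally referenced light-exposure quantities and reporting compliance for
chronobiology, sleep research and environmental psychology.

Light acts on human physiology through five retinal photoreceptor classes —
the S, M and L cones, the rods, and the melanopsin-expressing ipRGCs — so
illuminance alone cannot specify a light stimulus: infinitely many spectra
(metamers) share the same lux value while differing severalfold in, say,
melanopsin excitation.  Reproducible light-exposure experiments therefore
report the tabulated spectral power distribution (SPD) plus the quantities
this package computes:

- **Alpha-opic (ir)radiances**: for each photoreceptor class α with spectral
  sensitivity s_α(λ), the stimulus E_λ(λ) is weighted and summed across
  wavelength bands,

      E_α = Σ_λ E_λ(λ) · s_α(λ) · Δλ,

  expressed in mW/m² (irradiance input) or mW/(m²·sr) (radiance input),
  alongside the photopic illuminance (lux) or luminance (cd/m²) computed
  with V(λ) and K_m = 683 lm/W.
- **Photon irradiance**: E_λ·λ/(hc), totalled in photons·cm⁻²·s⁻¹ (and
  log₁₀).
- **Observer geometry**: visual angle θ = 2·atan(0.5·S/d); light-adapted
  pupil diameter (Watson & Yellott unified formula: field size, luminance,
  age, one vs two eyes); retinal illuminance in trolands
  (luminance × pupil area in mm²).
- **Age correction**: pre-receptoral lens filtering relative to the 32-year
  standard observer, with an age sensitivity analysis over candidate
  observers.
- **Safety pre-screen**: blue-light-weighted radiance against the
  risk-group-0 limit of 100 W/(m²·sr) for exposures above 10,000 s, with the
  10,000 cd/m² low-luminance exemption.
- **Reporting compliance**: an exposure-record manifest (stimulus and
  background SPDs, timing, spatial and measurement metadata) validated
  against the seven minimum reporting items, rendered as Markdown + JSON.

The vendored spectral weighting tables are clearly labelled *synthetic
stand-ins* constructed from published pigment templates and ocular-media
models (see `docs/methods.md`); they reproduce the standardized functions'
structure (unit peaks, corneal peak positions, lens-age behaviour) but are
not the official tabulations.

## Worked example

```python
from oculight import fixtures, alpha_opic_panel
from oculight.quantities import panel_to_dict, photon_report, age_sensitivity_analysis

# a three-primary LED panel: (peak nm, FWHM nm, band power W/m²)
spd = fixtures.gaussian_led_spd(
    [(455.0, 18.0, 0.25), (520.0, 30.0, 0.45), (630.0, 20.0, 0.30)]
)
print(panel_to_dict(alpha_opic_panel(spd)))
```

prints (units embedded in the keys):

```
{'s_cone_opic_mW_per_m2': 186.38, 'm_cone_opic_mW_per_m2': 467.70,
 'l_cone_opic_mW_per_m2': 405.93, 'rhodopic_mW_per_m2': 522.23,
 'melanopic_mW_per_m2': 465.22, 'photopic_illuminance_lux': 273.38,
 'observer_age_years': 32.0, 'input_kind': 'spectral_irradiance'}
```

i.e. this 1-W/m² LED mixture delivers about 273 lux and a melanopic
irradiance of about 465 mW/m² to the standard observer.  Its photon
irradiance is 2.70×10¹⁴ photons·cm⁻²·s⁻¹ (log₁₀ = 14.43).  The age
sensitivity analysis shows how lens yellowing attenuates the
short-wavelength-weighted quantities while the (standard-observer) photopic
value is unchanged:

```
>>> age_sensitivity_analysis(spd, [25, 32, 50, 70]).round(2)
           s_cone_opic_mW_per_m2  ...  melanopic_mW_per_m2  photopic_illuminance_lux
age_years
25.0                      204.16  ...               494.93                    273.38
32.0                      186.38  ...               465.22                    273.38
50.0                      147.54  ...               397.66                    273.38
70.0                       84.28  ...               276.07                    273.38
```

From the shell, the same pathway plus compliance checking:

```sh
oculight simulate --source record -o demo/      # synthetic exposure record
oculight validate demo/exposure_record.json     # exit 0 iff 7/7 items pass
oculight report demo/exposure_record.json -o demo/report/
oculight compute demo/stimulus_spd.csv --ages 25,32,50,70
```

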