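# hydrosense

Analysis toolkit linking the THz absorption of hydration water around
DNA-wrapped single-wall carbon nanotubes (SWCNTs) to their near-infrared
fluorescence response upon analyte binding — for spectroscopists and
simulators working on nanotube fluorescent biosensors and their signal
transduction mechanism.

DNA-wrapped SWCNTs sense small molecules (the neurotransmitter dopamine,
the vitamin riboflavin, ...) through analyte-specific changes of their E11
exciton fluorescence near 990 nm. The mechanistic picture this package
operationalizes: the nanotube's charge fluctuations couple to the
charge-density fluctuations of its hydration shell, and that coupling is an
efficient non-radiative drain for the exciton. The coupling is measurable
as a THz difference absorption,

    alpha(nu)       = -(1/d) * log10( I(nu) / I0(nu) )          [cm^-1]
    delta_alpha(nu) = alpha_sample(nu) - alpha_water(nu)

with `d` the cell path length read off the empty-cell etalon fringes
(fringe period `1/(2d)` in wavenumber). Analytes shift the coupling, and
the relative change `x = (delta_alpha - delta_alpha_0)/delta_alpha_0`
(evaluated at 150 cm^-1 by convention) is inversely and linearly related
to the normalized fluorescence change `y = dI/I0`: per DNA sequence,
`y = m x + b` with `m < 0`. The package quantifies that relation
(OLS fit, studentized-bootstrap slope CI, one-sided permutation test for
negative correlation), implements the supporting MD-trajectory analyses
(Shrake–Rupley SASA contact areas with periodic boundaries, ligand
binding-event detection with a 400 ns residence threshold, surface- vs
corona-binding mode classification, localized water-contact tracking), and
fits titration calorimetry heats with a two-independent-site-class model
whose strong class gives the per-nanotube stoichiometry (`1:n`).

Every input class — etalon-fringed transmissions, THz scenes with vapor
lines, E11 emission sets, scripted binding/unbinding trajectories, and
two-class titration heats — can be generated synthetically with known
ground truth (`hydrosense.synthetic`), so the full pipeline is testable
without external data.

## Worked example

```python
import numpy as np
from hydrosense import (absorption_coefficient, difference_spectrum,
                        coupling_change, estimate_path_length)
from hydrosense.correlation import CouplingResponseModel, inverse_correlation_assessment
from hydrosense.itc import TwoSiteBindingModel
from hydrosense.synthetic import (ThzSceneSpec, gen_thz_scene,
                                  gen_etalon_transmission, gen_response_dataset,
                                  ItcTruth, gen_itc_heats)

# 1. path length from empty-cell etalon fringes (mid-IR scan, 13 um spacer)
grid = np.arange(400.0, 4000.0, 1.0)
etalon = gen_etalon_transmission(d=1.3e-3, grid=grid, noise_sd=0.01, seed=0)
pl = estimate_path_length(etalon)
print(f"path length: {pl.d * 1e4:.3f} um  (method: {pl.method})")

# 2. THz transmissions -> water-referenced difference spectra -> coupling change
scene = gen_thz_scene(ThzSceneSpec(noise_sd=0.0, seed=0))
alpha_w = absorption_coefficient(scene.water, scene.empty_cell, pl)
diffs = {}
for cond, sample in scene.samples.items():
    alpha = absorption_coefficient(sample, scene.empty_cell, pl)
    diffs[cond] = difference_spectrum(alpha, alpha_w)
cc, sem = coupling_change(diffs["gt10+dopamine"], diffs["gt10"], nu=150.0)
print(f"coupling change at 150 cm^-1 (dopamine): {cc:+.3f}")

# 3. coupling-response linear model on a synthetic sensor dataset
points, _ = gen_response_dataset(slope=-4.11557, intercept=0.1, seed=0)
res = CouplingResponseModel(points).fit()
print(res.summary())
a = inverse_correlation_assessment(points, seed=1)
print(f"permutation p (inverse correlation): {a['permutation_p']:.4f}")

# 4. two-site-class ITC fit
exp = gen_itc_heats(ItcTruth(), seed=0)
fit = TwoSiteBindingModel(exp, sigma=0.2).fit()
print(fit.summary())
print("stoichiometry:", fit.stoichiometry_report()["ratio_range"])
```

Output:

```
path length: 13.001 um  (method: fringe-fft)
coupling change at 150 cm^-1 (dopamine): -0.333
Coupling-response linear fit
============================================
sequence:       GT10
n points:       8
weighting:      none
slope m:        -3.72240 +/- 0.23634
intercept:       0.21589 +/- 0.06189
pearson r:      -0.9881
============================================
permutation p (inverse correlation): 0.0005
Two-site-class ITC binding fit
==================================================
injections used: 24 (of 25)
      n1:  36.342 +/- 0.158 sites/SWCNT
      K1:  1.9298e+07 +/- 2.73e+07 1/M
     dH1: -7.88 +/- 0.0862 kcal/mol
      n2:  66.335 +/- 12.3 sites/SWCNT
      K2:  2.0897e+05 +/- 3.49e+05 1/M
     dH2: -0.37412 +/- 0.269 kcal/mol
  offset: -0.36309 +/- 0.361 ucal
reduced chi-square: 0.5006
class-2 saturation at final injection: 0.85  [non-saturating]
==================================================
stoichiometry: 1:36 to 1:37
```

Reading the numbers: the fringe analysis recovers the 13 µm spacer to
0.01%. Adding a dopamine-like analyte weakens the hydration coupling by a
third (`-0.333`) in this scene, and across an 8-point dataset generated on
a line of slope −4.11557 with replicate-scale noise, the fitted slope is
−3.72 ± 0.24 with Pearson r = −0.99 and a permutation p at its attainable
floor — a clearly negative (inverse) coupling–fluorescence relation. The
ITC fit recovers ~36 strong surface sites per nanotube (truth 37, i.e. a
1:36–1:37 nanotube:analyte stoichiometry) plus a weak, more numerous
corona class that has not saturated by the final injection. Note that the
strong-class affinity K1 is weakly identified when the titration is steep
(its CI is wide); the stoichiometry n1 is the robust quantity.

The trajectory side works the same way from scripted systems:

```python
from hydrosense.synthetic import TrajectoryScript, LigandScript, gen_trajectory
from hydrosense.hydration import (detect_binding_events, classify_mode,
                                  local_region, local_water_contact)

script = TrajectoryScript(
    n_frames=100, frame_dt=10.0,
    ligands=[LigandScript("dopamine", [(200.0, 700.0, "SURFACE")])],
)
system, truth = gen_trajectory(script, seed=7)
event = detect_binding_events(system, "dopamine:0", min_duration=400.0)[0]
classify_mode(event, system)          # -> 1 (direct surface binding)
region = local_region(event, system, 60)
lw = local_water_contact(region, system)
# lw["bound_mean"] < lw["unbound_mean"]: binding displaces local water
```

A `hydrosense` console script mirrors the library (`hydrosense thz
pathlen|alpha|diff|vapor-correct|coupling`, `hydrosense nir response`,
`hydrosense correlate`, `hydrosense mdh events|bulk-contacts|local-water`,
`hydrosense itc fit`; the events table carries the binding-mode column).

See `docs/methods.md` for the models, assumptions, defaults and
limitations.

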