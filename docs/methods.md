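# Methods

`hydrosense` implements the analysis chain that links changes in the THz
absorption of hydration water around DNA-wrapped single-wall carbon
nanotubes (SWCNTs) to the nanotubes' near-infrared (NIR) fluorescence
response upon analyte binding, together with the trajectory-level hydration
analysis and the two-site-class titration calorimetry that support the
mechanistic picture. This note records the models, their assumptions, the
defaults that matter, and what the synthetic generators do and do not
emulate.

## THz difference spectroscopy of hydration water

A liquid cell with two windows separated by a thin spacer transmits
intensity `I(nu)`; referencing against a background channel `I0(nu)` and
the optical path length `d` gives the decadic absorption coefficient

    alpha(nu) = -(1/d) * log10(I(nu) / I0(nu))        [cm^-1]

and subtracting the bulk-water channel isolates the hydration-shell
signature

    delta_alpha(nu) = alpha_sample(nu) - alpha_water(nu).

The amplitude of `delta_alpha` is treated as a measure of how strongly
charge fluctuations in the nanotube couple to the charge-density
fluctuations of the surrounding water; analyte binding modulates that
coupling. The scalar readout is the relative coupling change
`(delta_alpha - delta_alpha_0) / delta_alpha_0` evaluated at a single
stated wavenumber — 150 cm^-1 by default (300 cm^-1 supported), read at
the nearest grid point because experimental conventions quote single
wavenumbers (linear interpolation is available via a flag). Replicate
difference spectra are averaged pointwise with SEM = SD/sqrt(n) (n = 2 is
the usual replication for THz spectra, n = 3 for fluorescence).

Decisions and numerical choices:

- **Logarithm base.** Decadic, matching the absorbance convention;
  a `log_base="e"` flag switches to Napierian. Only the overall scale of
  `alpha` changes; the relative coupling change is invariant.
- **Path length.** `d` is read off the etalon fringes of the *empty* cell:
  with refractive index 1 between the windows the fringe period in
  wavenumber is `1/(2d)`. The estimator takes the dominant nonzero
  frequency of the mean-subtracted transmission (DFT on a uniform grid,
  resampling if needed), refines it within one DFT bin by least-squares
  sinusoid fitting, and returns `d = f/2`. A peak-spacing fallback
  (`fringe-peaks`) provides an independent estimate and an empirical
  uncertainty. Spectra spanning fewer than 3 fringe periods are refused
  (the 50–500 cm^-1 THz band itself spans only ~1.2 periods for a 13 µm
  spacer — the thickness must come from a wider-band scan), as are spectra
  with no detectable modulation (dominant peak < 8x the median nonzero-
  frequency power).
- **Vapor lines.** Narrow rotational lines of atmospheric water vapor are
  masked by linear interpolation between the nearest grid points outside
  each window; overlapping windows are merged, untouched points are
  returned bit-identical, and windows touching the grid boundary are
  refused (no anchor). The shipped window list for 50–500 cm^-1 is
  editable configuration data, not a physical constant.
- **Grids.** Strictly increasing wavenumber grids; when two spectra differ,
  the second is linearly interpolated onto the first's grid and the
  resampling is recorded in metadata; extrapolation is forbidden.

## NIR fluorescence response

The E11 exciton of (6,5)-enriched SWCNTs emits near 990 nm. The sensor
readout is the normalized intensity change of the E11 peak,
`dI/I0 = (I_after - I_before)/I_before`, computed per replicate from
paired before/after spectra (paired by acquisition order by default,
by replicate id on request) and averaged with SEM over replicates.
Peak intensity is the in-band maximum (950–1050 nm default), with an
optional local-quadratic refinement; an integrated-area option was
deliberately left out of the default path because the peak height is the
conventional response measure. `dI/I0 <= -1` is rejected as non-physical
rather than clipped.

## Coupling–response correlation

Per DNA sequence, the paired points
`x = (delta_alpha - delta_alpha_0)/delta_alpha_0` (THz) and `y = dI/I0`
(fluorescence) are modelled as a line `y = m x + b`; the inverse relation
(m < 0) is the central claim this stage quantifies. The fit is exposed as
`CouplingResponseModel(points).fit() -> CouplingResponseResults` with a
`summary()`. Fits are per-sequence, never pooled. Ordinary least squares
is the default (matching fits to per-analyte mean points); `1/sem^2`
weighting is available. Errors-in-variables treatment of the x-axis SEM is
a documented limitation, not implemented.

Inference is nonparametric:

- **Slope CI** — pairs bootstrap (resample points with replacement,
  B = 2000 default) with a *studentized* (bootstrap-t) interval. At the
  n = 8 scale of these datasets the plain percentile interval undercovers
  (measured ~90% for a nominal 95%); the studentized interval achieves
  95.6% coverage over 500 synthetic ensembles at the default noise.
  Exact-fit data, where no studentized pivots exist, fall back to the
  percentile interval (degenerate at the slope).
- **One-sided permutation test** for negative correlation: permute y
  against x (B = 2000), `p = (1 + #{r_perm <= r_obs})/(B + 1)`; the
  smallest attainable p is `1/(B+1)`. Null calibration (slope-0
  generators) is checked by a KS test for uniformity in the test suite.

## Trajectory hydration analysis

The system is a coarse multi-frame model: nanotube carbons, DNA-corona
beads, single-site waters (oxygen only), ions and small rigid ligands,
with per-atom roles and radii, orthorhombic periodic box, minimum-image
distances, coordinates in Å, times in ns, 0-based indexing.

- **SASA.** Shrake–Rupley with a deterministic golden-spiral point set
  (960 points/atom default), probe radius 1.4 Å, periodic neighbour search
  via a periodic k-d tree and minimum-image burial tests. The isolated-atom
  case is exact; two-sphere and random-cluster cases are cross-checked in
  the tests against closed-form cap areas and an independent dense
  latitude–longitude quadrature.
- **Contact area** between disjoint groups A and B is half the solvent-
  accessible area lost on union formation,
  `(SASA_A + SASA_B - SASA_{A∪B})/2`, computed with only the named groups
  present. Atoms without cross-group neighbours contribute identically to
  both sides and are skipped — an exact optimization, verified against the
  naive evaluation.
- **Binding events.** A frame is bound when any ligand atom is within the
  contact cutoff (5.0 Å default) of any nanotube carbon or DNA atom.
  Bound runs bridged across gaps <= 2 frame spacings (configurable in ns)
  become events if they last at least 400 ns (last minus first bound frame
  time). Event boundaries are frame-aligned.
- **Binding modes.** Mode 1 (directly on the nanotube surface) requires a
  ligand atom within the surface cutoff (5.0 Å) of a carbon in at least
  half of the event frames; otherwise mode 2 (DNA corona). The 5.0 Å /
  0.5 thresholds and the region size below are declared assumptions at
  first-solvation-shell scales, exposed as parameters — not literature
  values.
- **Local regions and water contact.** For each event, the N = 60 carbons
  (configurable) with smallest time-averaged distance to the ligand centre
  form the local region (ties break by atom index). The per-frame contact
  area between the region and all water oxygens is normalized by its
  maximum (so regions of different size are comparable; the normalized
  series peaks at exactly 1) and summarized as bound-window vs unbound
  means. Mode-1 binding displaces first-layer water and lowers the bound
  mean; mode-2 binding leaves it unchanged within noise.
- **Direct-binding tally.** A ligand counts as directly bound when the
  mode-1 criterion holds over the whole analysis window; counts are
  reported per analyte.

## Two-site-class titration calorimetry

Dopamine binding to DNA-wrapped nanotubes shows two thermodynamically
distinct site populations: strong sites on the exposed nanotube surface
(large enthalpic footprint, saturating) and weak sites in the DNA corona
(small footprint, not saturating at the concentrations titrated). The
model is two independent site classes: with free ligand L and nanotube
concentration M, class c holds `bound_c = M n_c K_c L/(1 + K_c L)` and the
mass balance `L_total = L + sum_c bound_c` is solved by vectorized Newton
iteration (the balance is increasing and concave in L, so iteration from
the upper bracket converges monotonically; residuals are driven below
1e-14 M). Injections dilute cell contents by `1 - dV/V0` (perfusion-cell
displacement) and the heat of injection i is
`V0 * sum_c dH_c (B_c,i - B_c,i-1 (1 - dV_i/V0))` plus a constant offset.
The macromolecule is the *nanotube*, so n is sites per nanotube and the
stoichiometry report renders `1:n` with its 95% CI range.

Fitting (`TwoSiteBindingModel.fit()`):

- Weighted least squares against observed heats, first injection excluded
  by default (standard practice).
- Affinities are fit in log10 space with bounds that encode the model's
  premises: `|dH| <= 30 kcal/mol` (physical noncovalent range),
  `logK in [2, 9]` (ITC-measurable window) and `K1/K2 >= 10` via a
  separation parameter. The separation constraint matters: without it the
  optimizer can split the strong transition between both classes and
  overfit noise with a phantom ultra-tight class.
- Multi-start: three deterministic grid starts plus one data-driven start
  seeded from a one-class (Wiseman) fit; best residual wins. scipy's
  trust-region `least_squares` (Jacobian-based scaling) via lmfit.
- Diagnostics: parameter standard errors and 95% CIs from local curvature,
  a non-saturation flag for class 2 (< 90% occupancy at the final
  injection), and a nested-model F-test (`class2_significance()`) against
  the one-class fit.

K1 itself is only weakly identified once the titration is steep (it often
runs to its bound while n1 stays accurate); n1 — the stoichiometry — is the
robust quantity, which is also what the scientific claim rests on.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic for a fixed seed and return their ground
truth alongside the data, so every downstream stage has an exact oracle.

- **THz scenes** (`gen_thz_scene`): smooth source envelope; etalon fringes
  on the empty-cell channel only (a filled cell is index-matched); Beer–
  Lambert attenuation with a smooth bulk-water-like baseline and
  per-condition broadband `delta_alpha` humps (solvated-sensor reference
  ~+6 cm^-1, a coupling-weakening dopamine-like condition, a
  coupling-strengthening riboflavin-like one); multiplicative vapor dips
  shared across channels, with optional per-channel depth jitter — the
  mechanism that leaves vapor residuals in difference spectra; and
  multiplicative detector noise. Default grid 50–500 cm^-1 at 0.5 cm^-1,
  path 13 µm. Not emulated: detector nonlinearity, drift between scans,
  temperature effects (cells are thermostatted in practice).
- **Etalon transmissions** (`gen_etalon_transmission`): cosine fringes of
  period `1/(2d)` on a flat envelope (any spectral range; thickness scans
  are made in the mid-IR).
- **Emission sets** (`gen_fluorescence_set`): a single Gaussian E11 band
  at 990 nm (width 25 nm), after-spectra scaled by `1 + dI/I0`, additive
  count noise, triplicates by default. Multi-chirality shoulders,
  solvatochromic wavelength shifts and baseline drift are not modelled —
  by design, since wavelength-shift analysis is out of scope.
- **Response datasets** (`gen_response_dataset`): points on
  `y = slope*x + b` over 8 coupling-change values spanning ±0.4 with, by
  default, y-noise of 10% of the dynamic range (the replicate-SEM scale of
  sensor data); optional x-noise for errors-in-variables studies.
- **Scripted trajectories** (`gen_trajectory`): carbons on a cylindrical
  lattice (12 nm long, 3.75 Å radius), eight DNA bead helices 10 Å off the
  surface, single-site waters in a cylindrical shell with *half of them in
  the first hydration layer* against the tube (hydration water is layered
  and densest at the interface — and without that layering the water-
  displacement signal would depend on where the random binding site
  lands), a few ions, and rigid 4-bead ligands. Each scripted SURFACE
  interval parks the ligand 3.8 Å off the carbon shell (displacing
  first-layer waters within 6 Å radially outward); CORONA intervals park
  it against a DNA bead, far outside the carbon cutoff; otherwise the
  ligand sits in the far solvent. The script itself is returned as the
  truth event list with frame-aligned boundaries. The default frame
  spacing of 0.1 ns mirrors the 30,000-configurations-per-3-µs convention
  of production trajectories; the test suite and the acceptance script use
  10 ns spacing and a few hundred waters so SASA-bearing analyses run in
  seconds (event detection is proven invariant to time rescaling, so
  nothing tested depends on the stride). Not emulated: force-field
  energetics, diffusion, corona conformational change, explicit hydrogens
  — passing tests show the *operators* are correct on systems with known
  truth, not that real trajectories will show effects of any given size.
- **Titration heats** (`gen_itc_heats`): the same two-class forward model
  as the fitting stage plus Gaussian heat noise. Defaults describe a
  well-designed dopamine-into-nanotube titration: n1 = 37 strong surface
  sites (the regime reported for DNA-wrapped nanotubes), K1 = 3e6 1/M,
  dH1 = -8 kcal/mol; n2 = 60 corona sites, K2 = 1e4 1/M, dH2 = -1.5
  kcal/mol (smaller footprint, non-saturating); 500 nM nanotubes in a
  1.4 mL cell so the Wiseman c-value `n1 K1 M ≈ 55` sits inside the
  canonical 10–100 window; 25 x 10 µL injections of 400 µM analyte, which
  puts the strong-class equivalence point mid-titration and keeps the
  weak-class tail heats well above the noise floor; heat noise 0.2 µcal,
  typical of modern microcalorimeters. These are experimental-design
  choices, and they matter: at substantially higher noise or lower
  concentrations the two-class decomposition becomes statistically
  non-identifiable — maximum-likelihood fits can prefer solutions with n1
  off by tens of percent even when started at the truth. That regime is a
  known limitation of two-class ITC analysis, not of this optimizer.

## Known limitations

- The coupling-change x-axis carries replicate SEM that the default OLS
  fit ignores (errors-in-variables noted, not implemented).
- K1 is reported but weakly identified for steep titrations (c >> 100
  after the K1 bound); interpret its CI cautiously.
- The SASA kernel loops per atom in Python/numpy; it is sized for the
  coarse systems generated here (10^2–10^3 atoms per frame), not for
  all-atom solvated boxes.
- Vapor masking interpolates across windows; structure genuinely inside a
  window is lost by construction.
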