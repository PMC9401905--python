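# Methods

This note records the models implemented in `uavcal`, their assumptions,
the numerical choices behind them, and what the synthetic campaigns do and
do not establish about real data.

## Radiometric calibration

All three methods map per-band digital numbers x to reflectance y using
reference panels of known reflectance imaged in the scene. Panel DN is the
plain arithmetic mean over the panel ROI (a symmetric trimmed mean is
available via the `trimmed` argument but is off by default: the panels are
assumed clean and uniformly lit). ROIs are 0-based, half-open rectangles
everywhere in the package.

**EL** fits one ordinary least-squares line per band over all panels.
It is exact for a linear sensor but extrapolates badly below the darkest
panel: with a negative intercept, dark water and shadow pixels come out
negative — the characteristic dark-band artifact the piecewise method
exists to remove.

**SEL** splits the twelve bands into a visible group (bands 1–7,
490–700 nm), fitted with a power law, and a red-edge/NIR group (bands
8–12, 720–950 nm), fitted linearly. The power fit is closed-form
log–log least squares rather than iterative nonlinear fitting: it is
deterministic, has no starting-point or convergence concerns, and is
exact whenever the data truly follow y = a·x^b. It requires strictly
positive DN and reflectance.

**PEL** combines a through-origin segment y = a4·x for dark targets with
a linear segment y = a5·x + b5 for bright ones, switching at a reflectance
threshold τ = 0.03. Two choices need stating:

* *Branch test.* The switch condition nominally depends on the unknown
  true reflectance, so at application time the linear prediction
  y_lin = a5·x + b5 is tested against τ: y_lin ≤ τ routes the pixel to
  the proportional segment. This is the only self-consistent reading.
  Continuity at τ is **not** enforced; a small jump at the branch point
  is a documented property of the method.
* *Panel partition.* Panels with nominal reflectance ≤ 0.06 (the 3 % and
  6 % panels — two points stabilize a through-origin fit) feed the a4
  segment; the remaining, brighter panels feed the linear segment. The
  dark panels are excluded from the linear fit deliberately: on a sensor
  with a floor response they sit off the affine line, and including them
  would bias a5/b5 and break the exact-inversion property. When fewer
  than two bright panels exist the linear fit falls back to all panels;
  with no dark panel at all, PEL degrades to EL with a logged warning.

No calibration output is clamped by default; negative and >1 values are
preserved and counted per band in the returned diagnostics (they are
themselves informative — see the EL artifact above). `clamp=(0, 1)` is
available.

Calibration assumes the panels and the scene share the illumination and
that atmospheric effects over tens to hundreds of meters are negligible;
no irradiance-sensor correction is attempted.

## Band-equivalent reflectance

Field-spectrometer spectra are converted to camera bands by the
response-weighted mean R_j = ∫R·S_j dλ / ∫S_j dλ over the response
support [s, e]. Both curves are treated as piecewise linear on the union
of their sample grids. On each union segment the integrand R·S is
quadratic, so the numerator uses the segment-exact rule
h/6·(r0(2w0+w1) + r1(w0+2w1)) and the denominator the trapezoid rule
(exact for the linear S). The quadrature is therefore exact for
piecewise-linear inputs: constants are reproduced to machine precision
for any response shape, convolution is linear in the spectrum, and the
result cannot leave the spectrum's range over the band support. A
spectrum that fails to cover [s, e] is a hard error, as is a response
integrating to zero.

The camera's true spectral responses are not public. When a band lacks a
measured response a Gaussian centered at the band center (FWHM 10 nm,
configurable, sampled every 0.5 nm out to ±4σ) is synthesized and flagged
as synthetic in the log. Results that depend on response shape should be
read accordingly.

## Vegetation indices

Nine indices are computed from calibrated reflectance; formulas are in
the module docstring. Defaults assign red = 670 nm and NIR = 800 nm, with
680 nm and 850/900/950 nm as legal alternates; MCARI always uses the
700/670/550 nm triplet. WDRVI's weighting coefficient defaults to
α = 0.1 (its common literature value; at α = 1 it reduces to NDVI
exactly, which the tests assert). Division by zero produces NaN, counted
in diagnostics, never an exception — index maps always complete.

## Fully constrained unmixing

FCLS minimizes ‖R − E·A‖₂ over the abundance simplex. The solver stacks a
sum-to-one row onto the endmember matrix, scaled by
δ = 1e3 × (largest endmember column norm), and solves the non-negative
least-squares problem; the result is then renormalized to sum exactly to
one (the residual sum defect before renormalization is O(1/δ²)). This
enforces both constraints to better than 1e-8 without a quadratic-
programming dependency, which testing against an exhaustive 0.01-step
simplex grid search confirms (objective gap ≤ 1e-4 on random
3-endmember problems; in practice ~1e-16). Endmember matrices with
condition number above 1e8 trigger a warning, not an error: the solution
is still feasible, just not unique in some directions.

The six canonical endmembers (lit/shaded leaf, water, soil) are supplied
per run, measured or synthetic; no in-image endmember extraction is
attempted. The background factors are literal abundance sums:
attenuation = A_lw + A_sw + A_ls + A_ss (in [0, 1]) and
enhancement = A_lw + A_ls + A_ss − A_sw (in [−1, 1]). The subtraction of
shaded water in the enhancement factor is adopted as defined by its
source; it is not re-derived here.

## Viewing geometry

Flat terrain and a gimbal-stabilized, nadir-pointing camera are assumed
throughout. A target offset x meters from the nadir point at altitude H
is seen at α = arctan(x/H); a target at the horizontal image edge is at
α = fov_h/2 = 19.13° regardless of altitude. GSD is linear in H, so an
ROI drawn at one altitude is rescaled by the altitude ratio to cover the
same ground area at another; dimensions round to the nearest integer
(ties away from zero) with a 1 px floor and the center preserved, which
makes plot means reproducible bit-for-bit. The round trip H→H′→H changes
each dimension by at most 1 px for altitude ratios up to 2 (the flown
pairs); larger ratios can amplify rounding beyond that bound.

The altitude-sensitivity summary uses the **population** standard
deviation over altitudes (all flown altitudes are enumerated, not
sampled) and normalizes by the reflectance at a reference near-nadir
altitude to give STDR.

## Trait models

Trait ~ VI lines are ordinary least squares with in-sample R², RMSE and
RRMSE (RMSE over the observed mean, in percent) — the published reference
tables report fit statistics, not held-out validation, so fitted models
are comparable like-for-like. CCC is the product LAI_green × SPAD_upper.
The published coefficient sets ship as a read-only catalog keyed by
(experiment, method-or-altitude, trait) with provenance `published`;
they are comparison fixtures, never training targets.

## Synthetic campaigns

The generator emulates the reference field setup with known ground truth:

* **Endmembers**: lit leaf/water/soil templates with multiplicative
  per-band jitter (±8 %), constrained by construction so leaf NIR exceeds
  every background NIR and leaf red lies below lit-soil red. Shaded
  variants scale the lit spectra by a per-band factor around 0.35
  (spread ±10 %): the per-band spread keeps the endmember matrix full
  rank — exactly proportional lit/shaded pairs would make abundances
  non-identifiable — while a shading factor of 1 reproduces the lit
  spectra exactly.
* **Altitude response**: a plot offset x from nadir is seen at
  α = arctan(x/H); its background fraction is f = clip(f0 + g·tan α, 0, 1)
  with nadir fraction f0 = 0.15 and gain g = 0.6. The tan-α form is a
  footprint-elongation heuristic, not a fitted BRDF; g is exposed, not
  hidden. Leaf abundance splits 70/30 lit/shaded; background splits
  30/20/30/20 over lit/shaded water/soil. An open-water strip along the
  bottom tenth of the image supplies realistically dark (<3 %) pixels.
* **Sensor transfers** are exact inverses of the calibration models:
  affine (slope ≈ 9e-4 DN⁻¹, negative intercept), two-group power
  (a = 0.001, b = 1.2 in the visible), and piecewise with a proportional
  sensor-floor segment up to 0.06 reflectance — covering the two darkest
  panels — whose affine-segment parameters are constrained so the branch
  rule routes every pixel correctly. Noise is additive Gaussian in DN,
  truncated at zero; panels are always rendered noiseless so
  calibration-recovery tests isolate method error, and panel ROIs carry
  their nominal reflectance in the stored truth (the abundance truth is
  undefined there; a panel mask flags those pixels).
* **Scale**: the default desk-scale camera keeps the reference band set
  and FOV on a 160×128 pixel grid, and campaigns default to the fourteen
  60–250 m altitudes of the multi-altitude reference experiment; trait
  tables default to slope 0.336, intercept 1.0176, σ = 0.3, matching the
  reference LAI ~ CI_green conditions. All randomness flows from one
  explicit seed per call; identical seeds reproduce DN stacks bit-exactly.

What passing these closed loops shows: the fitting, inversion, unmixing
and regression machinery is correct under its own model assumptions. What
it does not show: performance under real BRDF anisotropy, atmospheric
variation, panel non-uniformity, band-to-band misregistration or
non-Gaussian sensor noise — none of which the generator emulates.

## Known limitations

* PEL's proportional segment has no intercept, so it cannot invert a
  general affine sensor below τ; it is exact only where the dark targets
  truly follow a through-origin response (the regime it was designed
  for).
* The spectral response functions are synthetic Gaussians unless measured
  ones are supplied.
* The pipeline fits calibration per altitude from the panels in each
  image; cross-flight transfer of coefficients is out of scope, as are
  orthomosaicking, georeferencing and physical BRDF modeling.
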