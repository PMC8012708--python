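# Methods

This note documents the models behind each analysis stage, the synthetic
instrument emulators used to test them, the numerical conventions, and the
known limitations.

## Reactor geometry and hydrodynamic descriptors

The cultivation chamber is a cuboid; all external interfaces use bench
units (mm, µL, mL min⁻¹, h⁻¹) while computation is done in SI, with the
conversions centralized in `geometry.py`.  Three 550 µL chamber designs
ship as presets:

| preset | width × depth × height (mm) | A (mm²) | d = √(4A/π) (mm) | h/d |
|--------|------------------------------|---------|-------------------|-----|
| narrow | 3.5 × 3.5 × 45               | 12.25   | 3.95              | 11.4 |
| medium | 4 × 5 × 27.5                 | 20      | 5.05              | 5.4 |
| wide   | 6 × 4 × 23                   | 24      | 5.53              | 4.2 |

Reported ratios are rounded half-away-from-zero at one decimal **from the
unrounded diameter** (27.5/5.0463 = 5.4496 → 5.4).  This convention is a
deliberate choice: rounding the diameter first would give 27.5/5.0 = 5.5
for the medium chamber, which is not how such tables are conventionally
reported.

The local Reynolds number Re_L = ρ_c·d_h·|v_c|/µ_c is exposed only as a
scalar formula for user-supplied velocity magnitudes; no flow field is
computed.  The hydraulic diameter of the rectangular section uses the
standard convention d_h = 4A/perimeter.

## Bubble sizing

Segmentation thresholds the 8-bit ROI (Otsu by default, fixed grey value as
an override), labels dark connected components (8-connectivity), and drops
components below `min_area_px` (default 20) or touching the ROI border
(border-touching bubbles are partially out of view and would bias the axis
fit).  Merged bubbles are **not** split — no watershed is applied, because
no defensible separation rule exists for heavily overlapping bubble images;
an optional solidity filter can exclude merged (non-convex) components
instead.

Axes come from the component's normalized second central moments (the
moment-equivalent ellipse), converted to mm by the mandatory
`pixel_scale_mm` metadata.  The equivalent spherical diameter treats the
bubble as an ellipsoid of revolution with semi-axes h = d_major/2 (twice)
and z = d_minor/2:

d_SB = ∛(8·(d_major/2)²·(d_minor/2)) = ∛(d_major²·d_minor).

Population summaries use at most `max_n` (default 400) measurements in
chronological order and report mean, population sd, n, and maximum.

Accuracy: for rendered bubbles at least ~10 px across with noise up to 5
grey levels, the full chain recovers d_SB within 2 % (tested over a grid of
sizes and orientations); the moment-based fit is exact in the limit of a
well-resolved filled ellipse.

## Mixing time

The pipeline follows the colorimetric standard: per-frame ROI mean grey
value, two-point normalization, 95 % homogeneity threshold.  Conventions:

* **Reference windows.** The initial reference I_grey(t₀) is the mean of
  the 10 frames up to the injection frame (or the first 10 frames when the
  injection frame is index 0); the final reference the mean of the last 10.
  A contrast floor (default 5 grey levels) raises a no-tracer error instead
  of dividing by a vanishing difference.
* **t₀.** The mixing time is measured from the initial reference frame
  (first frame by default). The injection frame can be supplied or
  auto-detected as the largest single-frame grey change.
* **Hold rule.** The default is *sustained* (earliest time from which the
  threshold holds to the end of the record) because bubbles crossing the
  ROI make the raw signal fluctuate; the pure first-crossing rule is
  available as a flag.  Sustained t_M ≥ first-crossing t_M always.
* The normalization is invariant to affine grey-level maps of the whole
  sequence, so camera gain/offset drift between runs does not matter.

## Oxygen transfer (dynamic gassing-out)

Model: c(t) = c* − (c* − c₀)e^(−k_L a·t) after the N₂ → air switch.  The
estimator regresses y(t) = ln((c* − c₀)/(c* − c(t))) on t by OLS with a
**free intercept** and reports the slope (×3600 → h⁻¹): forcing the origin
would make the estimate hostage to the exact switch-time and c₀ choice,
while the slope is invariant to both.  The fit window keeps samples between
c₀ and 40 % of saturation — "40 %" is interpreted as a fraction of
saturation (identical to percentage points when c* = 100 %).  Samples at or
above c* are excluded (log undefined); fewer than two usable samples is an
error.  c* defaults to the mean of the trailing 10 samples, c₀ to the first
sample after the switch.  A cruder point-wise variant (closed-form rate per
sample, averaged) is provided for comparison only.

Error characteristics (seeded study, 200 curves): with 1 % saturation
noise and 1 Hz sampling, median relative error is ≈ 3–4 % over
k_L a = 200–800 h⁻¹; error grows with k_L a because fast curves leave few
samples below the 40 % window.  The sensor's own response time is **not**
modeled or corrected for — at k_L a near 800 h⁻¹ (time constant ≈ 4.6 s) a
real optical sensor's lag biases the estimate low, which is a limitation of
the method itself, not just of this implementation.

## Diauxic growth

Specific growth rates are ln-linear OLS slopes of biomass vs. time; on a
noiseless exponential this is exact to machine precision, and on
log-normal multiplicative noise it is unbiased (seeded simulation, 200
replicates).  Glucose depletion is detected as the steepest negative
derivative of the (5-sample moving-average) smoothed off-gas CO₂ after its
peak; traces whose post-peak drop is < 20 % of their dynamic range report
"no shift".  Detection is invariant to affine rescaling of the CO₂ channel.

Phase windows derived from the detected boundaries are trimmed by 10 % of
the phase duration at each end to avoid transition bias.  Two yield
conventions are reported, matching how such summaries are customarily
printed: the glucose-phase yield uses biomass *produced* up to depletion,
(X(t_dep) − X₀)/S₀, while the total yield uses the maximum biomass reached,
X_max/S₀ — the latter slightly mixes conventions (it includes the inoculum)
but is the form in which total yields are conventionally quoted.
Reporting rounding is half-away-from-zero (0.605 → 0.61 at two decimals).

## Synthetic data generators

All generators are deterministic under a fixed seed (bit-identical
output) and attach the exact ground truth they were built from, so every
estimator is tested as a recovery problem.

* **Bubbly frames** render dark ellipses (grey 30) on a bright background
  (grey 220) with 4×4 sub-pixel area-coverage anti-aliasing, then optional
  additive Gaussian pixel noise.  Out-of-frame bubbles are refused unless a
  clip mode is requested.
* **Mixing videos** impose the exponential (or step) relaxation on the
  frame mean.  Because frames are 8-bit, a fixed stratified dither pattern
  is baked into each frame so the spatial mean resolves grey levels below
  the quantization step — emulating the spatial shading any real camera
  image has.  50 fps and a 40×40 px ROI are the defaults.
* **DOT curves** are the exact first-order model plus optional Gaussian
  noise, at configurable sampling (defaults: 1 s over 60 s).
* **Cultivation records** integrate a piecewise-exponential diauxic batch
  with hard substrate switches.  This is a deliberate stand-in — minimal
  while reproducing every qualitative feature of a monitored
  Crabtree-positive yeast batch.  Defaults encode a published-style
  timeline: lag 0.5 h; glucose phase at µ₁ = 0.403 h⁻¹ ending at 5.3 h with
  6.3 g L⁻¹ biomass produced from S₀ = 20 g L⁻¹ (Y₁ = 0.315); ethanol and
  CO₂ formed at 1 and 2.16 mol per mol glucose; ethanol phase at
  µ₂ = 0.147 h⁻¹ up to X_max = 12.1 g L⁻¹.  Requiring depletion at 5.3 h
  fixes the inoculum at X₀ ≈ 1.06 g L⁻¹, and the 12.1 g L⁻¹ peak fixes the
  ethanol yield Y₂ ≈ 0.93 g g⁻¹; under these parameters the ethanol phase
  spans 5.3–8.7 h.  The ethanol phase is generated as *exponential* at µ₂
  (a specific rate is the natural parameter even where such phases can look
  linear over short windows).  pH, DOT and off-gas channels are
  phenomenological shapes (acid-proxy pH fall, DOT fall during growth and
  recovery in stationary, off-gas CO₂ proportional to the instantaneous
  CO₂ evolution rate, O₂ mirroring CO₂ in phase 1).  Whether O₂ dips again
  during ethanol growth is configurable (`o2_phase2`), defaulting to flat.

What passing these tests shows — and does not.  The generators contain no
bubble coalescence, no sensor response lag, no DOT–k_L a coupling to the
biology, no mechanistic Crabtree metabolism and no real optical
distortions; recovery results therefore validate the *estimators and
plumbing*, not the instrument physics.  On real data the same chains apply
unchanged but inherit those un-modeled effects.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately compact
problems — 40×40 px mixing videos of a few seconds, single 256×256 px
bubble frames, 10 ms-sampled DOT curves of ≤ 5 s, 1-min-sampled 12 h
cultivation records, and 100–200-replicate noise studies — chosen as the
smallest sizes at which each estimator's error is dominated by its own
properties rather than discretization.  Tolerances follow from those sizes:
one frame interval (0.02 s at 50 fps) for mixing times, one pixel
equivalent for fitted axes, 2 % for end-to-end bubble sizing, 0.5 % for
noiseless rate recovery.  Ties and degenerate inputs are handled
explicitly: constant frames segment to nothing, monotone CO₂ reports no
shift, equal calibration anchors / zero viscosity / empty ROIs raise typed
errors rather than propagating NaN.
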