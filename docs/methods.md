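# Methods

This note documents the models, numerical choices and limitations behind
`leaftrack`, in the order data flows through the package.

## Measurement model

A growing grass leaf is coupled by a low-stretch thread to a white bead
(ø 20 mm) riding a vertical u-rail on a black 100 × 60 cm panel; a 20 g
counterweight opposed by the 6 g bead and ~1 g roller resistance keeps the
thread taut with a net force of (20 − 6 − 1) g × g ≈ 0.13 N, small enough
not to perturb elongation. Because graminoid leaves elongate from a basal
growth zone, bead travel equals leaf elongation. The observable is a
grayscale frame of the panel every 120 s at ≈ 2.1 px/mm.

## Tracking

**Statistic.** Zero-normalized cross-correlation (mean-subtracted,
variance-normalized) between a fixed per-bead template (cut from the
seeding frame) and a search region. ZNCC is invariant to affine intensity
changes, so the day → near-infrared night transition does not depress the
correlation coefficient; only noise does. The template is never updated:
bead appearance is constant, and template adaptation would risk slow drift
that masquerades as growth.

**Sub-pixel refinement.** The default refinement is upsampled Fourier
cross-correlation (Guizar-Sicairos matrix-multiply DFT, upsampling 200,
i.e. 1/200 px quantization) between the template and the window at the
integer ZNCC peak. The common 3×3 paraboloid fit is implemented and
selectable (`method="parabolic"`), but it is *not* the default for a
reason measured on analytically rendered beads: the ZNCC peak of a disc is
near-conical (the overlap area of two discs falls linearly with shift), so
a quadratic fit to the 3×3 neighborhood carries a phase-dependent bias of
up to ~0.05 px, while the Fourier refinement stays near 0.01 px. At
2.1 px/mm that difference is the bulk of the method's 0.03 mm error
budget. The paraboloid offsets are clamped to ±0.5 px and flagged when
clamping occurs; a flat 3×3 patch returns (0, 0) with a degeneracy flag.

**Loss and re-acquisition.** A localization with CC below `cc_min`
(default 0.5) is marked lost; its position never enters any downstream
series. The search region — a rectangle recentred on the last valid
position, half-extents defaulting to 1× the template width horizontally
and 2× vertically (motion is rail-constrained) — widens by 1.5× per
consecutive lost frame up to 4× base; after 50 consecutive losses
(configurable) the bead is flagged abandoned. Integer-peak ties break
toward the previous valid position, then lexicographically by (y, x).

**Coordinates.** Image origin top-left, x rightward, y downward, 0-based,
pixel centers at integer coordinates. Metric conversion happens only in
the calibration module.

## Rectification

A single view of a planar checkerboard cannot constrain full camera
intrinsics, so the model is deliberately minimal: a plane-to-plane
homography composed with one radial distortion coefficient about the
detected-corner centroid, radii normalized by the corner-set half-diagonal.
The closed-form direction is mm → px (project then distort); px → mm
inverts the radial map by fixed-point iteration (mild coefficients; the
round trip is identity to < 1e−6 px). The homography is initialized by the
normalized DLT and all nine parameters refined jointly by
Levenberg–Marquardt on pixel reprojection residuals. The reported RMS
residual is in mm, after mapping observed corners to the plane; the local
scale at the board center (mean singular value of the Jacobian) summarizes
pixel size.

Corner detection matches a 2×2 checker (saddle) kernel by |ZNCC|, keeps
the strongest rows × cols peaks, refines each with a least-squares saddle
fit (`skimage.corner_subpix`), and orders them row-major assuming a
roughly axis-aligned board (rows separated in y) — which holds for a
panel-mounted camera; a strongly rotated board raises a detection error
rather than mis-ordering silently. On rendered boards the detector is
accurate to < 0.1 px.

The board is assumed to lie in the plane of bead motion; the panel's 5°
backward tilt is absorbed by the homography, not modeled separately.
Whole-image rectification is intentionally not implemented — only tracked
coordinates are mapped.

## Displacement along the path

All valid metric positions of a bead are fitted with a least-squares
quadratic, transverse coordinate as a function of the motion-axis
coordinate (the axis with the larger range; centered for conditioning).
Each position is orthogonally projected onto the curve by solving the
cubic stationarity condition with `numpy.roots`; among real roots the
closest wins, ties break toward the previous frame's projection, and the
parameter is clamped to the observed range extended by 5% + 1 mm.
Projection suppresses the transverse component of localization noise.

Arc length uses the closed-form antiderivative for quadratics,
(t√(1+t²) + asinh t)/(4c₂) with t the curve slope (numeric quadrature is
kept as a test oracle). Displacement is the arc length from the first
valid projection, signed so the configured growth direction (default: up
the panel, decreasing y) is positive. Projection is per-point, so deleting
one frame never changes another frame's displacement.

**Drift correction.** Reference beads (threads anchored to the ground) see
only rig drift — thread stretch with moisture and temperature, wind-induced
panel motion. Their displacement series are linearly interpolated in time
(nearest value beyond coverage, flagged; a warning when > 10% of a bead's
frames lie outside all reference coverage), averaged, re-zeroed at the
bead's first valid frame, and subtracted. Subtraction happens on
displacements, not rates: equivalent after differencing and cleaner with
gaps. Thread elasticity is not modeled mechanistically; the reference
subtraction is the entire correction.

## Growth statistics

**LER.** ΔL/Δt per clock-aligned interval (default 1 h), with boundary
displacements linearly interpolated between the nearest valid frames
(≤ 120 s apart in normal operation). Intervals with < 50% of expected
frames are flagged missing. On gap-free data, Σ(LER·Δt) telescopes exactly
to the boundary displacement difference.

**Environment alignment.** Channel means over the same intervals; boundary
samples count toward both adjacent intervals so the mean is symmetric
about the interval midpoint (left-open binning would bias a 30-sample hour
by ~0.02 °C on a diurnal sinusoid).

**Temperature response.** LER = a·(T − i). Fixed mode holds the anchor at
i = 0 °C (the measured cereals extrapolate to zero growth within a
fraction of a degree of 0 °C) and reduces to least squares through the
origin, a = Σ(T·LER)/Σ(T²); its R² follows the no-intercept (uncentered)
convention. Free mode is ordinary least squares; the base temperature is
the x-intercept −intercept/slope with a delta-method standard error.
Missing LER or temperature values drop pairwise.

**Base temperature from hinge data.** Growth is zero below T_b, so a
straight line fitted through data that include sub-base observations has a
deterministically biased x-intercept (−0.7 °C for a −2…20 °C course with
T_b = 0 and ~20% sub-zero hours). `estimate_base_temperature_from_data`
therefore restricts the fit self-consistently: fit on all data, drop
temperatures below the current x-intercept estimate, refit until stable.
The true base temperature is a fixed point of this map; on simulated data
the estimator is unbiased with an SD of ~0.1 °C at field-like noise
(0.05 mm h⁻¹, 7 days hourly).

**Thermal time.** The correction LER − aT uses `a` from a through-origin
fit on the variety-mean LER series; per-leaf slopes feed the ANOVA. The
vapour-pressure-deficit term sometimes added to such models is
deliberately omitted. Residuals of the through-origin fit satisfy
Σ(T·r) = 0 exactly.

**Genotype comparison.** One-way fixed-effects ANOVA on per-leaf slopes
(degenerate all-equal input reported as F = 0, p = 1), then all-pairs
Tukey–Kramer HSD: |m̄ᵢ − m̄ⱼ| > q(1−α; k, df)·√(MSW/2·(1/nᵢ + 1/nⱼ)),
which handles unequal group sizes. The compact letter display uses the
insert-and-absorb algorithm, so groups share a letter exactly when no
rejection separates them; letters order by descending group mean. Analyses
are per measurement period; cross-period pooling and mixed-effects
corrections are out of scope.

## Synthetic rig

The simulator exists to provide exact ground truth for every stage.

* **Discs** are rasterized by the exact area of circle–pixel intersection
  (closed form, no supersampling), so the rendered intensity centroid
  equals the requested sub-pixel position and tracking error can be
  measured in hundredths of a pixel.
* **Checkerboards** without distortion use exact analytic coverage; with
  radial distortion, 4× supersampling in distorted space with per-sample
  undistortion. Corner ground truth is always analytic.
* **Illumination**: day (06–19 h) full contrast and noise SD 0.01; night
  contrast ×0.5 and noise SD 0.03, emulating the NIR look. These levels
  put clean-scene correlation coefficients in the ranges a well-adjusted
  field rig shows (> 0.95 day, > 0.85 night).
* **Temperature** is a 24 h sinusoid between configured extremes (minimum
  at 05:00) plus Gaussian noise; **growth** integrates
  LER = a·max(T − T_b, 0) + noise, truncated at zero so length is
  non-decreasing.
* **Drift** is a sum of two sinusoids (defaults 0.15 and 0.08 mm at 16 h
  and 6.3 h when enabled) applied equally to all beads — a surrogate for
  thread stretch and wind, matched to what reference subtraction is meant
  to remove, not a mechanistic model.
* All randomness flows from one seed; identical seeds give byte-identical
  bundles. The 2.1 px/mm scale and the sensor format are independent
  configuration values (a panel need not fill the sensor).

What the simulator does **not** emulate: perspective foreshortening in the
scene generator (beads move in the calibrated plane by construction),
raindrops/snow (the physical rig's roof exists to exclude them), image
shake beyond common-mode drift, bead appearance changes, and shadows.
Passing the synthetic suites therefore demonstrates the correctness and
noise behavior of the *analysis*, not robustness to every field artifact.

## Problem sizes used in the standard checks

The built-in verification renders 10 × 1.0 mm steps at 23 positions plus 3
static beads on the full 1000 × 600 mm panel (11 frames); quality probes
use 200-frame, 5-bead sequences on a 400 × 300 mm panel; the genotype power
check uses 3 genotypes × 7 leaves at 30-min frames for 2 days over a
2–16 °C course. Base-temperature recovery uses 100 replicates of 7-day
hourly data. These sizes make the whole acceptance run complete in well
under a minute on one CPU while keeping every estimate comfortably inside
its statistical tolerance.

## Known limitations

* Seeding is manual/config-driven (as in the original GUI workflow); there
  is no automatic bead detection.
* One camera, one panel: no multi-view registration, no tangential
  distortion, no full intrinsic calibration.
* The linear temperature-response model underestimates growth just above
  T_b and near saturation; nonlinear (exponential/saturating) responses
  are out of scope.
* Corner ordering assumes the board is not rotated by more than roughly
  half a square between adjacent rows.
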