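# Methods

This note documents the models, conventions and numerical choices behind
`miop`, and what the synthetic test bed does and does not establish.

## Coordinate and sign conventions

Contours are sampled as (x, z) in mm: x is the signed lateral position from
the corneal apex, z increases away from the camera toward the eye, so the
undeformed cornea is convex toward small z with its apex at the minimum-z
point of the first frame (ties broken toward x = 0). Frame indices are
1-based and all frame ranges are inclusive. The frame interval defaults to
32/140 ms.

The angular coordinate of a sample is the signed angle θ, at the center of
the reference circle fitted to frame 1, between the sample's ray and the
apex ray. The half-aperture θ_R is fixed per sequence as
min(0.6 rad, available support of frame 1) and reused for every frame, so
coefficients are comparable across time; s = θ/θ_R maps the aperture onto
[−1, 1].

## Deflection definition

The deflection is, by default, the *vertical difference against frame 1*:
u(x, t) = z_t(x) − z_1(x), interpolated linearly on a common 241-point
uniform x grid over the lateral overlap. This makes M₀ cleanly capture
whole-eye movement (a rigid translation loads mode 0 only, which the tests
assert). A `raw_radial` variant (distance to the reference circle minus its
radius, per frame) is retained as an option since per-frame profiles are
also a defensible reading; the default is used throughout the pipeline.

On noisy contours the apex (the angular origin) is located on a GCV
smoothing spline of frame 1 rather than on the raw samples — a raw argmin
jitters laterally under noise and would shift every frame's angular origin.
The angular map itself uses the raw reference: ∂φ/∂z vanishes at the apex,
so it is insensitive to sample noise exactly where precision matters.

## Modal decomposition

Basis: Legendre polynomials Pₙ(s) evaluated by the Bonnet recurrence
(cross-checked against an independent library implementation in the tests).
The decomposition is truncated at N = 5; an AIC-based order scan
(`select_order_aic`, per-frame m·ln(RSS/m) + 2(N+1) summed over frames) is
provided as a diagnostic and recovers the generating order on synthetic
input.

Projection: aₙ = (2n+1)/2 ∫ u(s) Pₙ(s) ds by composite trapezoid on the
sample grid, followed by inversion of the discrete Gram matrix of the basis
computed with the same weights on the same grid. The correction makes
projection and synthesis exact mutual inverses for any profile in the span
of the basis — projections of sampled basis functions return exact unit
vectors, and decomposing a synthesized sequence returns the generating
coefficients to ~10⁻⁸ mm on the standard 241-point grid, where the
uncorrected trapezoid projection is only O(h²) ≈ 10⁻³ accurate. The
correction vanishes as the grid refines; `grid_corrected=False` restores
the plain quadrature projection.

A `literal_eq2` convention, aₙ = (2n+1)/2 ∫ u(θ) Pₙ(cos θ) sin θ dθ over
[−θ_R, θ_R], is retained for comparison. Over a symmetric θ range its odd
weight suppresses symmetric input and cannot produce the antisymmetric
odd-mode shapes, so the normalized convention above (which has the expected
parity behavior) is the default. Whether a one-sided integration domain was
intended in the original formulation cannot be determined and is not
guessed.

## Features and the mIOP model

AUCs integrate a modal profile over the *frame index* with the composite
trapezoid rule (the interval cancels from every ratio); they are signed —
no rectification — since the ratio definitions carry no absolute value.
The rising window is the fixed range frames 24–40 for every eye (puff onset
to around the first applanation); the downward window runs from the second
applanation to frame 140. Applanation frames are detected per frame from
the signed central curvature (circle fit over |x| ≤ 1 mm; sign from the
side the fitted center falls on; flat tolerance κ_tol = 0.005 mm⁻¹): A1 is
the first frame with κ ≤ κ_tol and A2 the last. A1/A2 are diagnostic; the
estimator itself needs only the fixed rising window.

The ten secondary ratios divide each mode's total AUC (frames 1–140) by its
rising-phase and downward-phase AUCs (modes 1–5). A mode whose profile is
numerically zero throughout (all three AUCs below 10⁻⁹ mm·frame, e.g. odd
modes under a perfectly centered puff) reports NaN ratios; a nonzero
profile whose phase denominator vanishes raises `DegenerateFeature`. The
mIOP model is the fixed published calibration 0.586 × M₄ ratio + 8.2698
mmHg; estimates outside the 8–30 mmHg calibration range produce a warning,
not an error. Scale invariance — ratio(c·profile) = ratio(profile) — holds
exactly and is property-tested; it is the mechanism by which thickness- and
stiffness-driven amplitude differences cancel.

The primary feature catalog (per mode: initial/final values, signed
extremum and its frame with earliest-frame tie-breaking, least-squares
slope over the rising window, and the three phase AUCs) is a documented
representative set of classical waveform descriptors, not a reconstruction
of any particular historical list.

## Cohort statistics

Univariate fits use OLS; the slope p value is the extra-sum-of-squares F
test of the slope model against the horizontal line at mean(y), which
equals the squared-t slope test exactly (asserted to 10⁻¹² against an
independent implementation). Zero-variance conventions: r := 0 and p := 1
when y is constant; a constant-difference Bland–Altman comparison is
flagged degenerate rather than assigned infinite evidence. Bland–Altman
uses differences (first − second), a 1.96·SD limits-of-agreement
multiplier, and tests proportional bias by regressing the difference on the
pairwise mean. Repeated-measures ANOVA with sphericity correction is out of
scope; paired pre/post contrasts are summarized with `paired_change`
(mean difference, t-based 95% CI, paired test).

## The synthetic deformation generator

Raw tonometer recordings are not generally available, so the study
conditions are defined by a mode-space generator (`airpuff_simulator`): it
draws the modal profiles from closed-form equations and synthesizes
contours through the same Legendre basis, giving exact ground truth for
recovery tests. Defaults describe a healthy adult eye: corneal radius
7.8 mm, θ_R = 0.6 rad, CCT 540 µm, 140 frames / 32 ms, puff onset at frame
24, whole-eye movement 0.2 mm late in the sequence, deformation amplitude
~0.9 mm at 16 mmHg.

* M₂ (the main bending mode) follows a smoothstep plateau envelope
  (on ~frame 26, off ~frame 120) with amplitude
  c₂/(1 + k_c·(CCT−540)/540)·(16/IOP)^0.3: thicker and more pressurized
  corneas deform less. Its depth drives the apex curvature
  κ(t) = 1/R + (3a₂ − 7.5a₄)/(Rθ_R)² through zero and back — one concave
  episode with two applanation crossings (≈ frames 32 and 113 at defaults).
  The plateau's steep flanks make the crossing frames insensitive to
  amplitude (±1 frame for a 20 % deeper indentation), so applanation timing
  is set by the generator's phase, not its scale.
* M₄ is the sum of two Gaussian lobes: one centered in the rising window
  (t_p1 = 32 − 0.6·(IOP−16) frames; earlier at higher pressure) and a
  rebound lobe (t_p2 = 95 + 0.8·(IOP−16); later at higher pressure) whose
  relative weight (IOP/16)^2.5 grows with pressure. Since the rebound lobe
  lies far outside the fixed rising window, the M₄ total-to-rising AUC
  ratio is strictly increasing in IOP (verified over 10–22 mmHg), while the
  common amplitude factor cancels from the ratio entirely — the generator
  reproduces the qualitative pressure dependence the estimator relies on
  without claiming mechanical fidelity.
* Odd modes are proportional to the misalignment angle (zero when
  centered); whole-eye movement is a smoothstep ramp after frame 90 in M₀
  only.

Cohort sampling: IOP ~ U(10, 22) mmHg, CCT ~ N(540, 38) µm truncated to
(450, 650), age ~ N(39, 14) years truncated to (18, 80) (recorded but not a
generator input), misalignment ~ N(0, 0.02) rad, additive contour noise
0.002 mm; per-eye seeds derive from the master seed, so cohorts are exactly
reproducible. The default recovery experiment uses 200 eyes — large enough
for stable correlation estimates, small enough to run in a couple of
minutes on one core.

What the generator does *not* emulate: corneal asphericity and regional
stiffness variation, the continuum mechanics of the puff–cornea
interaction, device optics and speckle statistics, or the absolute scale of
the ratio–pressure relationship. Consequently, passing tests establish that
the pipeline recovers what the generator encodes (modal coefficients,
applanation timing, a monotone pressure index with r > 0.9), not that the
published calibration constants are accurate for real eyes — the simulated
mIOP scale sits below the generator's true pressures (a fixed negative
Bland–Altman offset), which is expected for an uncalibrated synthetic ratio
scale.

The image renderer rasterizes a contour as an anti-aliased bright band
(default 10 px thick, 0.02 mm/px, Gaussian blur σ = 1 px, optional
speckle) with the true sub-pixel edge attached, providing ground truth for
the segmentation stage.

## Segmentation

Per frame: 3×3 median filter → min–max normalization → Otsu binarization →
largest connected bright component → per-column topmost boundary →
sub-pixel refinement by a 3-point parabolic fit of the vertical intensity
gradient, with a +0.5 px pixel-center correction (pixel r samples the band
coverage of [r, r+1)). On noise-free renders this is accurate to ≤ 0.3 px
max / ~0.01 px mean; with 10 % speckle, ≤ 2 px max. The workflow is this
package's own design — deliberately standard and parameter-light (defaults:
minimum component area 1 % of the image, contrast ratio ≥ 1.5, contour gap
≤ 5 px, ≤ 5 bad frames per sequence) — and makes no claim to replicate any
device's proprietary edge detector.

## Numerical choices and degenerate inputs

* Circle fits: algebraic (Kasa) seed + geometric (orthogonal-distance)
  refinement; collinear input raises `DegenerateGeometry`; near-flat input
  in the applanation detector maps to κ ≈ 0 instead of failing.
* Smoothing: classical cubic smoothing spline with explicit roughness
  penalty λ; λ = 0 interpolates exactly (the pipeline default — synthetic
  contours need no smoothing and the projection averages point noise), and
  λ → ∞ tends to the least-squares line.
* AIC residuals are floored at an RMS of 10⁻¹¹ mm so exact fits tie (to
  the smaller order) instead of rewarding extra modes for fitting solver
  round-off.
* Extremum frame ties break to the earliest frame; screening sorts are
  stable so tied scores preserve input order.
* Truncation-style comparisons against printed reference values in the
  tests truncate toward zero at the printed precision.

## Known limitations

Single-meridian (2-D) analysis only; posterior surface, pachymetry maps and
3-D reconstruction are out of scope. The device-specific reference IOP
formulas (pachymetry-corrected and biomechanically corrected readings) are
not implemented; validation tooling accepts them as input columns where
available. Real-eye performance of the fixed calibration constants cannot
be established from synthetic data (see above).
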