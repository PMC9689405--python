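# Methods

This note records the models, conventions and numerical choices behind
`hipmetrics`, and what the synthetic phantoms do and do not establish.

## Coordinate and laterality conventions

All geometry lives in image coordinates: x = column, y = row, **y grows
downward** (raster convention). "Superior" is defined relative to the
reference line, not the image: the superior unit normal of the reference
line `(dy, −dx)` points toward smaller rows for the canonical
(x-component ≥ 0) direction. Every angle is computed in the reference-line
frame, so radiograph tilt cancels by construction.

By radiographic convention the patient's right hip appears on the image
left; a `laterality_convention` flag (`right_on_left`, default, or
`right_on_right`) flips this. All medial/lateral logic derives from the
side plus this flag — never from the raw sign of x.

Angle signs: LCEA is positive when the lateral sourcil lies lateral to the
CFH perpendicular and negative when medial; AIA is positive for an
up-sloping (lateral end superior) acetabular roof and negative otherwise.
Dysplastic or unusual anatomy (lateral sourcil inferior to the CFH) yields
a value plus a warning flag rather than an error, because a screening tool
must report on exactly those hips. Angles are in degrees at double
precision; widths in pixels, or mm when a pixel spacing is supplied; FOI is
unit-free.

## Circle fit

The femoral-head center is the center of a circle fitted to contour points
by the algebraic (Kåsa) least-squares method: minimizing
Σ(x² + y² + Dx + Ey + F)² is a linear problem with a closed-form solution,
exact on noiseless circles and bit-deterministic — which the engine's
double-read consistency contract requires. The reported residual is the
RMS of radial deviations. An iterative geometric (Gauss–Newton) refinement
was considered and rejected as the default: at segmentation-quality noise
the two solutions differ far below measurement noise (the test suite bounds
the difference against a brute-force grid search), and the closed form has
no convergence state. Collinear or < 3 input points raise an error.

## Landmark extraction from masks

* **Tuberosities**: per image side of the pelvic midline, the foreground
  pixel with the largest row; ties broken toward the most medial pixel,
  then the lowest column. Integer-pixel, matching the clinical idiom of a
  single annotated point.
* **Head contour**: marching-squares boundary of the largest connected
  component (sub-pixel), resampled to n equidistant points by arc length
  (default 64). Multiple components are flagged, not fatal.
* **Sourcil extents**: extremal foreground pixels along the
  reference-line direction, toward (medial) and away from (lateral) the
  midline — tilt-safe by construction. A single-pixel sourcil is flagged;
  the downstream AIA then fails with a coincident-landmark error.
* **Foramen widths**: the outline is the marching-squares boundary with
  half-pixel corner cuts sharpened back to true corners (the iso-contour of
  a binary mask clips every right-angle corner by a half-pixel diagonal;
  restoring them keeps a rectangular opening at its full caliper width on
  the extreme lines). Widths are measured on 13 lines parallel to the
  reference line, equally spaced across the foramen's own perpendicular
  extent, endpoints inclusive (line 1 at the superior extent). This
  placement is parameter-free and reproducible; a fixed anatomical window
  would have required a constant the measurement definition does not
  supply. Width on a line is the outermost-crossing distance — the
  caliper reading — not the sum of foreground runs, which matters for
  non-convex outlines. The midline is the mean femoral-head centroid
  column when both heads are present, else the image center column.

## Synthetic phantoms

`PhantomSpec` states true LCEA/AIA per side, true FOI, head radius, canvas,
and scene rotation. `landmarks_from_truth` inverts the angle definitions in
closed form — the lateral sourcil is placed on the ray at the true LCEA
from the superior perpendicular at the CFH (lever 1.45 r), the medial
sourcil at the true AIA along the roof line (span 1.5 r), foramen ellipse
axes realize the true FOI — so the measurement engine returns the stated
truths to < 1e-9°. Scene rotation (validated to |θ| < 45° so the canonical
reference direction cannot flip) rotates every landmark rigidly and changes
no measured value.

`rasterize_phantom` renders binary masks: filled discs for femoral heads,
tapered strips with snapped tip pixels for sourcils (so extremal-pixel
extraction lands within one pixel of truth), ellipses for foramina, and
tuberosity blobs with a pointed inferior tip at the exact truth point —
a flat-bottomed blob would make the most-inferior-pixel rule ambiguous
across a multi-pixel run and bias the tie-break medially. Optional seeded
radial boundary jitter emulates segmentation roughness. At a 1024-px canvas
the full mask→measurement pipeline recovers angles within 0.5° and FOI
within 0.02; error shrinks with resolution.

Default truth distributions for phantom batches — LCEA ~ N(25.4°, 7.0²),
AIA ~ N(4.7°, 5.7²) (each truncated to feasible geometry),
FOI ~ N(1, 0.05²) truncated positive, tilt ~ N(0°, 2²) — follow the
population statistics of adult hip-pain referrals that this generator
emulates.

**What the phantoms do not show.** They are geometric, not photorealistic:
no bone texture, no occlusion, no osteophytes, no segmentation failure
modes beyond boundary jitter and missing structures. Passing the phantom
suite establishes that the *post-segmentation* computation is correct and
stable; it says nothing about how an upstream segmenter behaves on real
radiographs.

## Reader-study simulator

`simulate_reader_study` draws from the same crossed random-effects model
the analysis fits: y = x'β + a_p + b_r + c_pk + ε, with the occasion effect
c_pk shared across readers — the re-presented radiograph is what all
readers see again. This makes the repeated-measure variance identifiable
separately from the residual through the replicate subset (default: the
first 5 of 78 patients read 3 times by all 5 readers, the emulated study's
design). Patient covariates (age uniform over 18–91 years, sex ~
Bernoulli(½), FOI ~ N(1, 0.05²), noise standardized) feed optional fixed
effects. A single `numpy` Generator seeded from the spec drives all
randomness; identical seeds give identical tables.

Sides are treated as separate metrics analyzed independently, mirroring
per-side reporting; the simulator does not model a reader-by-side
interaction.

## Variance components

The REML fit is written directly on the mixed-model equations because the
random effects are fully crossed (patient × reader) with an occasion term
nested in patient — a structure nested-grouping LMM APIs do not express.
With W = [X Z] and variance ratios λ_c = σ²_c/σ²_e, the restricted
deviance reduces to

    −2 l_R = (n − p) log σ̂²_e + Σ_c q_c log λ_c + log|M(λ)| + (n − p),

with σ̂²_e profiled analytically. M is block-sparse: ordering unknowns as
(fixed effects, reader effects) then per-patient blocks (patient effect +
that patient's occasions) makes the patient part block-diagonal with tiny
blocks, so each evaluation is a batched small Cholesky plus a Schur
complement on the dense block — exact, and fast enough that the recovery
experiments in the test suite run hundreds of fits. Optimization is
L-BFGS-B on log-ratios (bounds ±25) followed by a damped Newton polish with
central differences; on balanced designs the estimates match the
closed-form ANOVA expected-mean-squares estimators to ~1e-8. Ratios
converging below e⁻¹⁰ are reported as boundary zeros. Convergence failure
raises with diagnostics; a rank-deficient fixed design raises naming the
aliased covariates.

**Interval method.** Three CI constructions are implemented and selectable:
Satterthwaite chi-square (default), lognormal Wald, and profile likelihood.
All derive from the observed REML information on the log-variance scale.
The default is Satterthwaite (effective df ν = 2/SE²_log, interval
[νσ̂²/χ²_{1−α/2,ν}, νσ̂²/χ²_{α/2,ν}]) because calibration experiments in
the test suite show it closest to nominal across all four components; the
lognormal Wald form is symmetric on the log scale and undercovers slightly
for components with few levels (here: 5 readers), and the χ²₁-calibrated
profile interval undercovers for the occasion component, which only the
small replicate subset identifies and whose likelihood is boundary-skewed.
Components at the zero boundary report no interval, the way
variance-component software prints N/A.

No multiple-testing correction is applied anywhere; the methods report
estimates and intervals, not screened p-values.

## Agreement statistics

Bland-Altman bias is the mean difference; the 95% limits of agreement are
bias ± 1.96·SD. The multiplier is the normal quantile, not a t quantile —
the same convention under which the repeatability coefficient constant is
2.77 = 1.96·√2; mixing conventions would make RC and LoA inconsistent. The
bias CI is exact-t. Two LoA CI constructions are available: the classic
approximate ± t·SD·√(3/n), and (default) an exact MOVER interval combining
the t interval for the mean with the chi-square interval for the SD — the
resulting intervals are asymmetric, with the longer arm outward, which is
the finite-sample truth the symmetric approximation hides. Agreement
functions operate on complete pairs only and report the number of excluded
(unpaired) ids rather than imputing.

The Bland-Altman sample size follows the cited procedure of Lu et al.
(2016): per side, the probability that the LoA confidence bound falls
inside the clinical limit ±δ is approximated by a normal for the estimated
LoA with a t-quantile bound,

    p_side = Φ( (δ ∓ μ₀ − 1.96σ) / (σ·√(1/n + 1.96²/(2(n−1)))) − t_{1−α/2, n−1} ),

and the joint power is p_upper + p_lower − 1; the returned n is the
smallest (≥ 3) reaching the requested power by ascending search. A
Monte-Carlo companion (`ba_power_mc`) simulates studies at a given n and
reports the empirical joint containment, used as an independent cross-check
of the analytic formula. An unattainable specification
(δ ≤ 1.96σ + |μ₀|) raises rather than returning a misleading n. The
patients-from-measurements conversion is
ceil((n − extra)/hips_per_patient) with extra = replicated patients ×
extra reads × hips.

Descriptive summaries use SD with the n−1 denominator and
linear-interpolation quantiles (Q1 of 1..100 is 25.75).

## Determinism

The measurement engine contains no randomness, no iteration-order
dependence, and no parallel reductions; the double-read command runs the
engine twice and summarizes first-minus-second differences, which must be
exactly zero — the test suite asserts equality to zero bytes, not to a
tolerance. All simulation randomness flows through explicit seeds; output
files embed the software version, a configuration hash, and the seed.

## Problem sizes in the test suite

The suite's statistical experiments use 100 replicate simulations of
400-patient studies for variance-component recovery, 10⁵ draws for LoA
coverage, 5 × 10⁴ simulated studies for sample-size cross-validation, and
phantom batches at 512–2048-px canvases — sizes at which the sampling error
of each check is several times smaller than the tolerance it enforces.

## Known limitations

* Masks are an input contract; no segmentation model is included, and no
  DICOM pixel handling is performed.
* The phantom's realism limits are listed above; in particular boundary
  jitter is not a model of systematic segmentation bias.
* The occasion variance is identifiable only through the replicate subset;
  with the study-sized design (5 patients × 3 reads) its interval is wide
  and its estimate frequently lands on the boundary in simulation. That is
  a property of the design, not the estimator.
* No dysplasia classification thresholds are applied: the package reports
  measurements, not diagnoses.
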