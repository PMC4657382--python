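# Methods

This note records the models, conventions, numerical choices and known
limitations behind femcurve. Units are mm and degrees at every API boundary
(radians internally).

## Coordinate convention

All measurements are made in the standardized ("osteometric board") frame:

- +z runs distal → proximal; the axial plane is z = 0 and the bone lies in
  z ≥ 0 with the distal condyles in contact;
- +y runs posterior → anterior; the coronal plane is y = 0 and the bone lies
  in y ≥ 0 with a posterior three-point contact;
- the medial direction is +x for left femurs and −x for right, so left/right
  pairs are exact mirror images across x = 0.

## The curvature model

The medullary canal's centerline is modeled as (and, for measurement,
fitted by) a circular arc: points `c + R(cosθ·d + sinθ·ẑ)`, where R is the
radius of femoral curvature and `d` — the bow (apex) direction — lies in the
transverse plane at angle β (the banking angle) from the medial direction.
The arc subtends only ~15–25° of its circle at anatomical R (700–1400 mm)
and shaft length (~280 mm), which drives two choices:

- **Circle fitting.** The algebraic (linearized, Kåsa) fit is biased on
  short noisy arcs, so it serves only as the initialization of a
  Gauss–Newton minimization of the true radial residuals (relative step
  tolerance 1e-10, max 200 iterations; non-convergence warns and returns the
  last iterate). On noisy 25° arcs (σ = 0.5 mm) the refined radius agrees
  with a 100-start Nelder–Mead global search to ~1e-8 relative.
- **Banking measurement.** β is measured from the apex direction — the unit
  vector from the centerline chord midpoint to the centerline point farthest
  from the chord — projected into the transverse plane: β = arccos(m̂ · d̂),
  m̂ the medial direction. A plane dihedral alone cannot distinguish β from
  180° − β; the apex direction can, and it is exactly insensitive to where
  along the arc the apex sits (the axial component of the apex vector
  projects away). The plane-normal sign convention in `fit_plane` (first
  non-negligible component of (x, y, z) made positive) keeps fitted normals
  reproducible across runs.

Projection closed forms: a circle of radius R inclined at β to the coronal
plane projects to an ellipse whose radius of curvature at the bow apex is
R/sin β (sagittal) and R/|cos β| (coronal). These are exact and are used
both as API (`apex_projected_radius`) and as the oracle for the fitted
projections; the coronal form is the precise statement of the observation
that the coronal bow radius increases toward β = 90° from either side and is
infinite (straight projection) exactly there. Fitting circles to projected
arcs reproduces these values within 1 % only for short spans (≤ ~10°); the
error grows monotonically with span (tested at 10/25/40°) because an ellipse
arc is not a circle arc.

## Centerline extraction

The canal mesh is sliced by planes: initial stations along the principal
(PCA) axis of the vertices, per-slice area-weighted centroid of the section
polygon (the loop nearest the expected point when a slice cuts several),
then two refinement passes that re-slice each station perpendicular to the
tangent estimated by central differences. 10 % of stations are trimmed at
each end, where the canal flares and the section centroid is no longer a
centerline point. Empty slices are skipped with a warning; more than 20 %
empty aborts. Proximal→distal output order is fixed by a `proximal_hint`
direction (default +z, i.e. a standardized mesh); callers that extract in an
arbitrary frame pass the transformed hint, which is what makes extraction
exactly equivariant under rigid motions.

Inscribed diameters use the GEOS maximum-inscribed-circle of each section
polygon (tolerance 0.0025 mm, i.e. diameters good to ~0.005 mm); the isthmus
is the minimum over stations, ties broken proximally. Because the profile is
sampled at stations, the reported isthmus exceeds the continuum minimum by
at most the profile curvature over half a station spacing (≤ 0.001 mm at the
default 60 slices) — this is why a nail surrogate sized at exactly the
measured isthmus diameter sits at tangency, with a signed clearance of
0 ± ~0.001 mm rather than exactly ≥ 0.

## Pose standardization

The dynamic rigid-body settling of a physical osteometric measurement is
replaced by a deterministic quasi-static computation:

1. **Stable rests.** On the convex hull, faces are merged by outward normal;
   a merged support polygon is a stable rest if the center of mass (from the
   enclosed volume) projects strictly inside it and the polygon holds at
   least 1 % of the hull area. The area floor encodes that a smooth convex
   region (a sphere, the side of a tube) gives point/line contact, not a
   rest — without it, a discretized sphere would count every facet as
   stable.
2. **`settle_on_plane`** picks the stable face nearest the requested down
   direction — settling from the given orientation without simulating
   tumbling.
3. **`slide_to_axial`** works on the (x, z) silhouette with coronal contact
   preserved (rotation about y, translation in the plane): among stable 2D
   hull edges reachable by < 45° rotation whose length exceeds 10 mm (two
   condyles, not one point), the nearest is rotated level and translated to
   z = 0.
4. **`standardize`** must be invariant to the initial pose, which
   "nearest stable face" is not; it therefore canonicalizes: the coronal
   rest is the largest-area stable support (the designed posterior
   three-point triangle is by far the widest base), the distal rest is the
   qualifying edge maximizing center-of-mass height (head up — the
   anatomical orientation), and x is centered on the distal contact pair.
   On synthetic femurs the recovered pose matches the generating frame to
   < 0.2° and < 0.5 mm from any initial pose.

Femoral length is the axial (z) extent of the standardized cortex — a
bounding-box property, differing from the 3D head-to-condyle distance by
< 0.1 % at anatomical bows.

## Nail-surrogate clearance

The torus uses the fitted circle as centerline (restricted to the angular
range actually spanned by the trimmed centerline) and a tube diameter equal
to the measured isthmus diameter. Clearance is evaluated by sampling the
analytic torus surface on a quasi-uniform (ψ, φ) grid (default 20 000
samples; doubling changes the minimum by < 0.01 mm on the fixtures) and
taking the signed distance to the canal mesh — positive inside — via an
exact point-to-triangle query with angle-weighted pseudonormal sign
(`femcurve._meshdist`, kd-tree candidate prefilter with a certified
fallback, verified against brute force over all triangles). A signed margin
in mm strictly strengthens a visual interference check; `intersects` is by
definition `min_clearance < 0`, so exact tangency resolves to ±1 mesh
tolerance (see above).

## The synthetic femur

The generator emulates exactly the features the pipeline measures and
nothing else:

- canal: a tube swept along the arc with radius profile
  `r(t) = r_min + (r_max − r_min)((t − t_isthmus)/0.5)²` clipped at `r_max`
  — quadratic, hence a single interior minimum at a known arc fraction;
  every surface vertex sits exactly at `r(t)` from the analytic arc;
- cortex: an outer tube (canal radius + cortical thickness), a femoral-head
  sphere whose pole vertex fixes the total length exactly, three posterior
  landmark bumps (hemispherically protruding spheres, radius 4 mm) whose
  apex vertices are exactly coplanar — the ground-truth coronal plane — two
  distal condylar bumps with apexes exactly on the axial plane, and a medial
  epicondyle marker. The center of mass is verified to project inside the
  posterior support triangle with ≥ 2 mm margin (stable rest guaranteed).

Because no boolean-union engine is used, the cortex is a multi-body
watertight mesh (each component closed, consistently wound). All quantities
the pipeline uses — extremes, convex hull, center of mass, slicing of the
canal — are well defined on such a mesh; containment tests are run per
component. Default resolution is 96 circumferential × 160 axial segments;
the polygonal cross-section makes the measured inscribed diameter smaller
than the analytic one by a factor cos(π/96) (≈ 0.005 mm at anatomical
sizes). Right femurs are exact mirror images of the left construction.

What the generator does **not** emulate: real condyle and trochanter
geometry, neck anteversion, the linea aspera, non-circular canal sections,
cortical thickness variation, or CT noise. Passing recovery tests therefore
demonstrates the correctness of the measurement chain on its geometric
model, not segmentation robustness on clinical CT.

## The cohort simulator

Two rows (left/right) per subject. Demographics come from per-gender normal
distributions typical of a large adult CT cohort (age, height, weight, with
~31 % female); femoral length follows height with slope 275 mm/m (marginal
mean ≈ 428 mm, SD ≈ 25 mm, corr(height, length) ≈ 0.85) plus a small
left–right offset (+0.59 mm left). Banking and RFC follow documented linear
models with Gaussian noise (codings: gender female = 1/male = 0, laterality
left = 1/right = 0, chosen so the model signs are internally consistent with
males and left femurs having larger RFC):

- banking = 59.69 + 5.7·gender + 0.236·age + 0.157·weight + ε,
  σ_banking = 10 (the RFC feedback term of the companion model is folded
  into the intercept at the cohort-mean RFC, avoiding a circular pair of
  generating equations);
- RFC = 267.36 + 2.23·length − 2.88·banking + 57.49·laterality −
  50.3·gender + ε, σ_RFC = 190 by default. The default σ reproduces a
  realistic fit quality (R² ≈ 0.19 for the RFC model); note that at this
  noise level the weakest model term (gender, −50.3) carries |t| ≈ 2.4 at
  426 femurs, so any selection procedure recovers it in only ~60–70 % of
  replicates — structure-recovery experiments therefore run at σ_RFC = 100,
  chosen a priori by power analysis so the weakest term carries |t| ≈ 4.5.
- isthmus diameter: mildly right-skewed (standardized gamma, mean 10.5 mm,
  SD 1.55) — the one deliberately non-normal measure, exercising the
  normality screen and Mann–Whitney path.

The two femurs of a subject share demographics but the regression treats
rows as independent, replicating common practice in cohort morphometry; a
mixed-effects treatment of the pair dependence is deliberately out of scope.

## Statistics

- **Normality**: one-sample K-S statistic against a normal with estimated
  mean/SD. Estimated parameters make the asymptotic K-S p anti-conservative,
  so the primary p-value is Monte-Carlo Lilliefors (default 10 000 null
  replicates, seeded, cached per sample size; add-one estimator); the
  asymptotic p is reported alongside.
- **Group comparisons**: classic pooled-variance Student's t between
  genders (Welch behind a flag), paired t between sides, Mann–Whitney U for
  non-normal measures. Degenerate paired inputs (zero-variance differences)
  return an explicit flag rather than NaN.
- **Stepwise OLS**: forward–backward with p-enter 0.05 / p-remove 0.10
  (partial-F p of a single term equals its coefficient's t-test p); full
  step log retained. With thresholds fully open it reduces exactly to the
  full OLS model, with p-enter = 0 to intercept-only. Calibration: each
  test's empirical type-I error at α = 0.05 lies in [0.03, 0.07] under its
  null (n = 100, 2000 replicates).
- **Sample size** for a two-sided two-means comparison reports both the
  normal-approximation n = ⌈2(z₁₋α/₂ + z_pow)²(sd/diff)²⌉ and a noncentral-t
  refinement (the reported value); at sd = 20, diff = 10, α = 0.05, power
  0.80 these are 63 and 64 per group. The t-refined value matches
  `statsmodels.stats.power.TTestIndPower` to the integer.

## Problem sizes

Defaults were chosen so a full validation pass is quick on one CPU while
staying inside the regime where the estimators are converged: mesh
resolution 96 × 160 (doubling changes the fitted RFC by < 0.2 %), 60
centerline slices, 20 000 clearance samples, 2000 replicates for test
calibration, 300 replicates for stepwise-recovery rates (the larger count
shrinks the Monte-Carlo error of the rate; the acceptance bars do not move),
and 40 replicates for the exhaustive-subset comparison, whose oracle uses
the information criterion equivalent to the stepwise entry rule (RSS
penalized by the α = 0.05 F threshold per parameter) so that it tests
greedy-versus-global search rather than a difference between selection
philosophies.

## Known limitations

- The centerline scheme assumes a single unbranched canal; side branches or
  highly non-convex sections would mislead the nearest-loop rule.
- Pose canonicalization relies on femur-like geometry (a unique wide
  posterior support, a wide distal pair, a heavy proximal end); it is not a
  general resting-pose solver.
- Clearance is geometric: no elastic nail deformation, no insertion path.
- The banking-angle convention requires side metadata; anatomical
  left/right detection from shape alone is out of scope, as is automatic
  landmark detection for the three-section bounds (the bounds are inputs).
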