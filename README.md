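# femcurve

Three-dimensional morphometry of the femoral medullary canal, for orthopaedic
and anthropometric work on implant fit: intramedullary (IM) nails and the
femoral components of knee arthroplasty must match the bow of the canal they
occupy, and a mismatched curvature causes anterior cortex impingement and
penetration.

The package measures, from triangulated surface meshes (STL, mm) of a femur
and its medullary canal:

- **RFC — radius of femoral curvature.** The canal centerline is treated as
  part of a virtual circle in 3D; the circle's radius is the RFC (larger =
  straighter femur). The centerline is extracted by plane slicing with
  tangent refinement, and the circle is fitted algebraically and then refined
  by geometric least squares, `min Σ(‖p_i − c‖ − r)²`.
- **Banking angle β.** The inclination of the plane holding that circle
  relative to the coronal plane, opening toward the medial side: β = 90° is a
  pure anterior bow, β < 90° an anteromedial apex, β > 90° anterolateral.
  The projection of the 3D bow behaves as R/sin β on the sagittal plane and
  R/|cos β| on the coronal plane, so the coronal radius grows without bound
  as β → 90° — the nonlinearity that decouples the 3D bow from its coronal
  shadow.
- **Isthmus diameter.** The smallest maximum-inscribed-circle diameter over
  the canal cross-sections; it sizes the nail surrogate.
- **Femoral length**, and the sagittal three-section radii (proximal, middle,
  distal circumcircles of seven equally spaced centerline points).
- **Nail-surrogate clearance.** A torus with the fitted circle as centerline
  and the isthmus diameter as tube diameter is checked for interference with
  the canal by signed-distance sampling, giving a worst-case margin in mm.

Before any measurement the femur is posed on a **virtual osteometric board**:
it settles posterior-side-down onto the coronal plane (three-point contact:
both posterior condyles and the greater trochanter), then slides so both
distal condyles touch the axial plane — a deterministic convex-hull contact
computation, not a physics simulation, so the standardized frame is exactly
reproducible and independent of the input pose.

Because real CT cohorts are not redistributable, the package ships a
parametric **synthetic femur generator** with exact ground truth (canal
centerline on a circle of known R and β, parabolic canal radius profile with
a known isthmus, landmark bumps defining the standard pose exactly) and a
**cohort simulator** producing demographics and per-femur morphometrics from
documented linear models. Every stage of the pipeline is validated against
these oracles.

A statistics module covers the cohort battery: Lilliefors-corrected
Kolmogorov–Smirnov normality screening, pooled-variance and paired t tests,
Mann–Whitney U, Pearson correlation matrices, variance-inflation factors,
forward–backward stepwise OLS (p-enter 0.05 / p-remove 0.10), and the
two-means sample-size formula `n = 2 (z₁₋α/₂ + z_pow)² (sd/diff)²` with
noncentral-t refinement.

## Worked example

```bash
femcurve simulate --config params.json --out-dir demo   # params: {"banking": 93.66}
femcurve measure --cortex demo/cortex.stl --canal demo/canal.stl \
                 --side left --out demo/record.json
```

prints

```
RFC 1000.0 mm, banking 93.66 deg, isthmus 10.50 mm, length 428.0 mm
```

i.e. for a synthetic left femur generated with R = 1000 mm, β = 93.66°,
isthmus 10.5 mm and length 428 mm, the full pipeline (standardize →
centerline → inscribed diameters → circle fit → banking) returns the
generating values: RFC to 0.0004 %, banking to < 10⁻⁵ degrees, isthmus to
0.005 mm. A clearance check on the same bone,

```bash
femcurve standardize --cortex demo/cortex.stl --canal demo/canal.stl --out-dir demo
femcurve clearance --canal demo/canal_std.stl --out demo/clearance.json
```

prints `min clearance -0.001 mm (intersects)`: a nail surrogate at exactly
the isthmus diameter is tangent to the canal at the isthmus (the ±0.001 mm
is mesh-discretization noise around exact tangency); `--tube-extra 2` makes
the interference unambiguous (`min clearance -1.001 mm`, worst location at
the isthmus).

A full simulated cohort run:

```bash
femcurve run --n-femurs 20 --seed 7 --out-dir run7
```

writes `cohort.csv`, per-femur `records.json`, and `summary.json` with
per-gender means ± SD, paired left/right comparisons, the correlation
matrix, and the stepwise model of RFC — byte-identical on rerun with the
same seed.

Library use mirrors the CLI:

```python
from femcurve import FemurParams, make_femur_meshes, measure_femur

cortex, canal, truth = make_femur_meshes(FemurParams(banking=93.66))
rec = measure_femur(cortex, canal, {"side": "left"})
print(rec.rfc, rec.banking)   # 999.996  93.65999...
```

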