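"""Banking angle, per-femur morphometric records, and the sagittal
three-section curvature analysis.

The banking angle describes how the plane of the femoral bow is inclined to
the coronal plane, opening toward the medial side: 90 deg is a pure anterior
bow, < 90 an anteromedial apex, > 90 an anterolateral apex.  It is measured
from the bow (apex) direction — the vector from the centerline chord midpoint
to the centerline point farthest from the chord — projected into the
transverse plane, which distinguishes beta from 180 - beta where a plane
dihedral alone cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import trimesh

from .centerline import (
    Centerline,
    extract_centerline,
    inscribed_diameter_profile,
    isthmus,
)
from .circle_geometry import (
    Circle3D,
    circumcircle_2d,
    fit_circle_3d,
    project_points,
)
from .errors import DegeneracyError, ParameterError, PipelineStageError
from .pose_standardization import femoral_length, standardize

__all__ = [
    "FemurRecord",
    "banking_angle",
    "measure_femur",
    "three_section_radii",
]


@dataclass
class FemurRecord:
    """Morphometrics of one femur in the standardized frame."""

    subject_id: str
    side: str
    femoral_length: float
    rfc: float
    banking: float
    isthmus_diameter: float
    fit_rmse: float
    section_radii: tuple | None = None

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right'")
        if not (self.rfc > 0 and self.isthmus_diameter > 0):
            raise ParameterError("rfc and isthmus_diameter must be > 0")
        if not 0.0 < self.banking < 180.0:
            raise ParameterError("banking must lie in (0, 180)")

    def to_dict(self) -> dict:
        return asdict(self)


def _apex_direction(cl: Centerline) -> np.ndarray:
    """Unit vector, chord midpoint -> point farthest from the chord."""
    p0, p1 = cl.points[0], cl.points[-1]
    chord = p1 - p0
    cn = np.linalg.norm(chord)
    if cn < 1e-12:
        raise DegeneracyError("centerline chord has zero length")
    chord = chord / cn
    rel = cl.points - p0
    perp = rel - np.outer(rel @ chord, chord)
    apex = cl.points[int(np.argmax(np.linalg.norm(perp, axis=1)))]
    return apex - (p0 + p1) / 2.0


def banking_angle(circle: Circle3D, centerline: Centerline, side: str) -> float:
    """Inclination of the femoral bow to the coronal plane, in degrees.

    The apex direction is projected into the transverse (x, y) plane and
    measured against the medial direction (+x left, -x right):
    0 = apex medial, 90 = apex anterior, 180 = apex lateral.  ``circle`` is
    carried for context (its plane holds the bow) but the apex direction
    comes from the centerline, whose chord fixes the opening side.
    """
    if side not in ("left", "right"):
        raise ParameterError("side must be 'left' or 'right'")
    d = _apex_direction(centerline)
    d2 = d[:2]
    n = np.linalg.norm(d2)
    if n < 1e-6:
        raise DegeneracyError("bow apex direction has no transverse component")
    d2 = d2 / n
    m = np.array([1.0, 0.0]) if side == "left" else np.array([-1.0, 0.0])
    return float(math.degrees(math.acos(np.clip(m @ d2, -1.0, 1.0))))


def measure_femur(
    cortex: trimesh.Trimesh,
    canal: trimesh.Trimesh,
    meta: dict,
    n_slices: int = 60,
    trim_fraction: float = 0.10,
    sections: bool = False,
) -> FemurRecord:
    """Full measurement pipeline for one femur.

    standardize -> extract_centerline -> inscribed diameters/isthmus ->
    3D circle fit (RFC) -> banking angle -> femoral length.  ``meta`` must
    contain ``side``; ``subject_id`` is optional.  Stage failures are
    re-raised as :class:`PipelineStageError` with the stage tag.
    """
    side = meta.get("side")
    if side not in ("left", "right"):
        raise ParameterError("meta['side'] must be 'left' or 'right'")

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - tagged and re-raised
            raise PipelineStageError(stage, exc) from exc

    pose, (canal_std,) = run("standardize", standardize, cortex, (canal,))
    cortex_std = pose.apply_to(cortex)
    cl = run(
        "centerline",
        extract_centerline,
        canal_std,
        n_slices=n_slices,
        trim_fraction=trim_fraction,
    )
    cl = run("profile", inscribed_diameter_profile, canal_std, cl)
    _, isthmus_d = run("isthmus", isthmus, cl)
    circle = run("circle_fit", fit_circle_3d, cl.points)
    beta = run("banking", banking_angle, circle, cl, side)
    length = run("length", femoral_length, cortex_std)
    radii = run("sections", three_section_radii, cl) if sections else None
    return FemurRecord(
        subject_id=str(meta.get("subject_id", "")),
        side=side,
        femoral_length=length,
        rfc=float(circle.radius),
        banking=beta,
        isthmus_diameter=float(isthmus_d),
        fit_rmse=float(circle.rmse),
        section_radii=radii,
    )


def three_section_radii(
    centerline_std: Centerline,
    bounds: tuple = (0.0, 1.0),
    plane: str = "sagittal",
) -> tuple:
    """Sagittal three-section radii of curvature (proximal, middle, distal).

    The centerline is projected onto the sagittal plane, seven points are
    placed at equal (projected) arc-length spacing between the bounds, and
    the overlapping triples {1,2,3}, {3,4,5}, {5,6,7} are each fitted with
    their exact circumcircle.  A collinear triple yields ``inf``.
    """
    lo, hi = bounds
    if not 0.0 <= lo < hi <= 1.0:
        raise ParameterError("bounds must satisfy 0 <= lo < hi <= 1")
    proj = project_points(centerline_std.points, plane)
    seg = np.linalg.norm(np.diff(proj, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < 1e-12:
        raise DegeneracyError("projected centerline has zero length")
    targets = (lo + (hi - lo) * np.linspace(0.0, 1.0, 7)) * total
    seven = np.column_stack(
        [np.interp(targets, s, proj[:, i]) for i in range(proj.shape[1])]
    )
    radii = []
    for k in (0, 2, 4):
        _, r = circumcircle_2d(seven[k], seven[k + 1], seven[k + 2])
        radii.append(r)
    return tuple(radii)
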