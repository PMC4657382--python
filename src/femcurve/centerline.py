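"""Medullary-canal centerline extraction and inscribed-diameter profiling.

The canal axis is recovered by planar slicing: an initial axis from the
principal direction of the mesh vertices, evenly spaced cross-sections along
it, area-weighted section centroids, then two refinement passes that re-slice
each station perpendicular to the locally estimated tangent.  The ends of the
profile are trimmed (the canal cross-section degenerates where the shaft
flares), mirroring the practice of cutting centerline endings before any
downstream fit.  The inscribed-diameter profile takes, at each control point,
the diameter of the largest circle inscribed in the local cross-section
polygon; the smallest such circle along the canal is the isthmus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import trimesh

from .errors import ExtractionError, InputError, ParameterError, SectionError, StateError

__all__ = [
    "Centerline",
    "extract_centerline",
    "section_at",
    "inscribed_diameter_profile",
    "isthmus",
]


@dataclass
class Centerline:
    """Ordered centerline control points (proximal -> distal), in mm.

    ``arc_length`` is cumulative from the proximal end; ``tangents`` are
    central-difference unit tangents; ``inscribed_diameter`` is filled by
    :func:`inscribed_diameter_profile`.
    """

    points: np.ndarray
    arc_length: np.ndarray = field(default=None)
    tangents: np.ndarray = field(default=None)
    inscribed_diameter: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.arc_length = np.asarray(self.arc_length, dtype=float)
        if self.tangents is None:
            t = np.gradient(self.points, self.arc_length, axis=0)
            t /= np.maximum(np.linalg.norm(t, axis=1), 1e-300)[:, None]
            self.tangents = t
        else:
            self.tangents = np.asarray(self.tangents, dtype=float)
        if np.any(np.diff(self.arc_length) <= 0):
            raise InputError("arc_length must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def transformed(self, matrix: np.ndarray) -> "Centerline":
        """Centerline under a rigid transform given as a 4x4 matrix."""
        m = np.asarray(matrix, dtype=float)
        pts = self.points @ m[:3, :3].T + m[:3, 3]
        tan = self.tangents @ m[:3, :3].T
        return Centerline(
            points=pts,
            arc_length=self.arc_length.copy(),
            tangents=tan,
            inscribed_diameter=(
                None
                if self.inscribed_diameter is None
                else self.inscribed_diameter.copy()
            ),
        )

    def to_dict(self) -> dict:
        out = {
            "points_mm": self.points.tolist(),
            "arc_length_mm": self.arc_length.tolist(),
            "tangents": self.tangents.tolist(),
        }
        if self.inscribed_diameter is not None:
            out["inscribed_diameter_mm"] = self.inscribed_diameter.tolist()
        return out


def _section_polygon(mesh, origin, normal, near_point):
    """Cross-section polygon of the mesh by a plane, as (shapely poly, to_3d).

    Of multiple section loops, keeps the one whose centroid is nearest to
    ``near_point``.  Returns None when the plane misses the mesh.
    """
    try:
        path3d = mesh.section(plane_origin=origin, plane_normal=normal)
    except Exception:
        return None
    if path3d is None or len(path3d.entities) == 0:
        return None
    try:
        path2d, to_3d = path3d.to_2D()
    except Exception:
        return None
    polys = path2d.polygons_full
    if len(polys) == 0:
        return None
    best = None
    best_d = np.inf
    for poly in polys:
        if poly is None or poly.is_empty:
            continue
        c2 = np.array([poly.centroid.x, poly.centroid.y, 0.0, 1.0])
        c3 = (to_3d @ c2)[:3]
        d = np.linalg.norm(c3 - near_point)
        if d < best_d:
            best, best_d = poly, d
    if best is None:
        return None
    return best, to_3d


def section_at(canal_mesh, point, tangent):
    """Closed cross-section polygon at a point, perpendicular to ``tangent``.

    Returns ``(polygon, to_3d)``: a shapely polygon in section-plane (u, v)
    coordinates and the 4x4 matrix mapping (u, v, 0, 1) back to 3D.  Raises
    :class:`SectionError` when the plane misses the mesh.
    """
    point = np.asarray(point, dtype=float)
    tangent = np.asarray(tangent, dtype=float)
    res = _section_polygon(canal_mesh, point, tangent, point)
    if res is None:
        raise SectionError("section plane does not intersect the mesh")
    return res


def extract_centerline(
    canal_mesh: trimesh.Trimesh,
    n_slices: int = 60,
    trim_fraction: float = 0.10,
    proximal_hint=(0.0, 0.0, 1.0),
) -> Centerline:
    """Extract the canal centerline by sliced-centroid refinement.

    ``n_slices`` planes are spaced evenly along the principal axis of the
    mesh vertices; per-slice area-weighted section centroids are refined in
    two passes, re-slicing each station perpendicular to the local tangent.
    The first and last ``trim_fraction`` of stations are discarded (the
    "endings cut").  ``proximal_hint`` orients the output proximal -> distal;
    pass the transformed hint to preserve equivariance under rigid motions.
    """
    if not isinstance(canal_mesh, trimesh.Trimesh):
        raise InputError("canal_mesh must be a trimesh.Trimesh")
    if not canal_mesh.is_watertight:
        raise InputError("canal mesh must be watertight")
    if n_slices < 20:
        raise ParameterError("n_slices must be >= 20")
    if not 0.0 <= trim_fraction <= 0.25:
        raise ParameterError("trim_fraction must lie in [0, 0.25]")

    verts = canal_mesh.vertices.view(np.ndarray)
    centroid = verts.mean(axis=0)
    _, _, vt = np.linalg.svd(verts - centroid, full_matrices=False)
    axis = vt[0]
    hint = np.asarray(proximal_hint, dtype=float)

    s = (verts - centroid) @ axis
    lo, hi = s.min(), s.max()
    inset = 0.005 * (hi - lo)
    stations = np.linspace(lo + inset, hi - inset, n_slices)

    # pass 0: slice along the fixed principal axis
    pts = []
    n_empty = 0
    for si in stations:
        origin = centroid + si * axis
        res = _section_polygon(canal_mesh, origin, axis, origin)
        if res is None:
            n_empty += 1
            warnings.warn("empty slice skipped during centerline extraction")
            continue
        poly, to_3d = res
        c = to_3d @ np.array([poly.centroid.x, poly.centroid.y, 0.0, 1.0])
        pts.append(c[:3])
    if n_empty > 0.2 * n_slices:
        raise ExtractionError(
            f"{n_empty}/{n_slices} slices produced no cross-section"
        )
    pts = np.asarray(pts)

    # refinement passes: re-slice perpendicular to local tangents
    for _ in range(2):
        cl = Centerline(points=pts)
        new_pts = []
        for p, t in zip(cl.points, cl.tangents):
            res = _section_polygon(canal_mesh, p, t, p)
            if res is None:
                new_pts.append(p)
                continue
            poly, to_3d = res
            c = to_3d @ np.array([poly.centroid.x, poly.centroid.y, 0.0, 1.0])
            new_pts.append(c[:3])
        pts = np.asarray(new_pts)

    # orient proximal -> distal
    if (pts[0] - pts[-1]) @ hint < 0:
        pts = pts[::-1]

    k = int(round(trim_fraction * len(pts)))
    if k > 0:
        pts = pts[k:-k]
    if len(pts) < 10:
        raise ExtractionError("fewer than 10 stations remain after trimming")
    return Centerline(points=pts)


def _max_inscribed_diameter(poly: shapely.Polygon) -> float:
    if poly.area < 1e-6:
        raise SectionError("degenerate cross-section polygon")
    # GEOS maximum inscribed circle: radius to 0.0025 mm
    seg = shapely.maximum_inscribed_circle(poly, tolerance=0.0025)
    return 2.0 * float(seg.length)


def inscribed_diameter_profile(
    canal_mesh: trimesh.Trimesh, cl: Centerline
) -> Centerline:
    """Fill the maximum-inscribed-circle diameter at every control point."""
    diam = np.empty(len(cl))
    for i, (p, t) in enumerate(zip(cl.points, cl.tangents)):
        poly, _ = section_at(canal_mesh, p, t)
        diam[i] = _max_inscribed_diameter(poly)
    return replace(cl, inscribed_diameter=diam)


def isthmus(cl: Centerline) -> tuple[int, float]:
    """Index and diameter of the narrowest cross-section.

    Ties break to the smallest arc length (most proximal station).
    """
    if cl.inscribed_diameter is None:
        raise StateError("inscribed diameters not computed; profile first")
    idx = int(np.argmin(cl.inscribed_diameter))
    return idx, float(cl.inscribed_diameter[idx])
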