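"""Resting-pose standardization on a virtual osteometric board.

A femur is placed into a standardized anatomical frame by two contact
stages, emulating how an osteometrist rests a bone on a measuring board:

1. coronal rest — the bone settles posterior-side-down onto the plane y = 0,
   contacting it at the most posterior points of the two condyles and the
   greater trochanter;
2. axial rest — keeping that contact, the bone rotates about the plane normal
   and slides until the most distal points of both condyles touch z = 0.

Instead of a dynamic physics simulation, settling is a deterministic
quasi-static computation on the convex hull: a resting orientation is a hull
face whose supporting plane sees the center of mass project inside the
(merged, coplanar) contact polygon.  For femur-like geometry with a
three-point posterior support the wide-base rest is unique, which makes the
full standardization invariant to the initial pose of the input mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .centerline import Centerline
from .circle_geometry import Circle3D
from .errors import ContactError, InputError, ParameterError, SettlingError, StateError

__all__ = [
    "RigidTransform",
    "settle_on_plane",
    "slide_to_axial",
    "standardize",
    "femoral_length",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ParameterError("rotation must be 3x3, translation length 3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-10):
            raise ParameterError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-10):
            raise ParameterError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_to(self, obj):
        """Transform a mesh, centerline, circle, or point array."""
        if isinstance(obj, trimesh.Trimesh):
            out = obj.copy()
            out.apply_transform(self.matrix)
            return out
        if isinstance(obj, Centerline):
            return obj.transformed(self.matrix)
        if isinstance(obj, Circle3D):
            return Circle3D(
                center=self.apply(obj.center),
                radius=obj.radius,
                normal=self.rotation @ obj.normal,
                rmse=obj.rmse,
            )
        return self.apply(obj)

    def to_dict(self) -> dict:
        return {
            "rotation_row_major": self.rotation.ravel().tolist(),
            "translation_mm": self.translation.tolist(),
        }


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(a @ b)
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        # antipodal: rotate pi about a deterministic perpendicular axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return trimesh.transformations.rotation_matrix(np.pi, axis)[:3, :3]
    axis = np.cross(a, b)
    angle = np.arctan2(np.linalg.norm(axis), c)
    axis = axis / np.linalg.norm(axis)
    return trimesh.transformations.rotation_matrix(angle, axis)[:3, :3]


def _stable_rests(mesh: trimesh.Trimesh, min_area_frac: float = 0.01):
    """Candidate stable resting orientations from the convex hull.

    Hull faces are merged by outward normal; a merged support polygon is a
    stable rest when the center of mass projected along the normal falls
    strictly inside it and the polygon covers at least ``min_area_frac`` of
    the hull area (tiny facets of smooth convex regions are treated as
    unstable point contacts).  Returns a list of dicts with the outward
    normal, support polygon area, and the COM containment margin.
    """
    hull = mesh.convex_hull
    com = mesh.center_mass
    normals = hull.face_normals.view(np.ndarray)
    areas = hull.area_faces
    total_area = float(areas.sum())

    key = np.round(normals, 5)
    order = np.lexsort(key.T)
    groups = []
    start = 0
    for i in range(1, len(order) + 1):
        if i == len(order) or not np.array_equal(key[order[i]], key[order[start]]):
            groups.append(order[start:i])
            start = i

    rests = []
    for g in groups:
        area = float(areas[g].sum())
        if area < min_area_frac * total_area:
            continue
        n = normals[g[0]]
        n = n / np.linalg.norm(n)
        vidx = np.unique(hull.faces.view(np.ndarray)[g].ravel())
        vpts = hull.vertices.view(np.ndarray)[vidx]
        # in-plane basis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(n @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, ref)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        p2 = np.column_stack([vpts @ u, vpts @ v])
        com2 = np.array([com @ u, com @ v])
        try:
            from scipy.spatial import ConvexHull

            h2 = ConvexHull(p2)
        except Exception:
            continue
        # signed distance of com2 to each hull edge (positive inside)
        margin = np.inf
        inside = True
        for eq in h2.equations:  # a*x + b*y + c <= 0 inside
            d = eq[0] * com2[0] + eq[1] * com2[1] + eq[2]
            margin = min(margin, -d)
            if d > 0:
                inside = False
        if not inside or margin <= 1e-9:
            continue
        rests.append(
            {"normal": n, "area": area, "margin": float(margin)}
        )
    return rests


def settle_on_plane(mesh: trimesh.Trimesh, down) -> RigidTransform:
    """Quasi-static rest of the mesh on the support plane through the origin.

    Among stable hull faces, the one whose outward normal is angularly
    closest to ``down`` is selected; the mesh is rotated so that face lies on
    the plane (normal -> down) and translated so contact occurs at height 0
    on the positive side.  Deterministic; no time-stepping.
    """
    if not mesh.is_watertight:
        raise InputError("mesh must be watertight to compute its mass")
    down = np.asarray(down, dtype=float)
    down = down / np.linalg.norm(down)
    rests = _stable_rests(mesh)
    if not rests:
        raise SettlingError("no stable resting face found on the convex hull")
    best = max(rests, key=lambda r: float(r["normal"] @ down))
    rot = _rotation_between(best["normal"], down)
    up = -down
    verts = mesh.vertices.view(np.ndarray) @ rot.T
    h = verts @ up
    translation = -h.min() * up
    return RigidTransform(rot, translation)


def _stable_edges_2d(xz: np.ndarray, com_xz: np.ndarray):
    """Stable support edges of the 2D silhouette (x, z), resting toward -z.

    Returns per-edge dicts: rotation angle about +y that levels the edge at
    the bottom, the two support points, and the COM stability margin.
    """
    from scipy.spatial import ConvexHull

    h = ConvexHull(xz)
    out = []
    hv = xz[h.vertices]  # counter-clockwise
    n = len(hv)
    for i in range(n):
        a = hv[i]
        b = hv[(i + 1) % n]
        e = b - a
        elen = np.linalg.norm(e)
        if elen < 1e-12:
            continue
        e = e / elen
        outward = np.array([e[1], -e[0]])  # CCW hull: outward = right of edge
        # stability: com projects inside the segment
        s = (com_xz - a) @ e
        margin = min(s, elen - s)
        if margin <= 1e-9:
            continue
        # rotation about y leveling this edge with outward -> (0, -1)
        angle = np.arctan2(outward[0], -outward[1])
        out.append(
            {
                "a": a,
                "b": b,
                "length": float(elen),
                "angle": float(angle),
                "margin": float(margin),
                "normal": outward,
            }
        )
    return out


def _rot_about_y(angle: float) -> np.ndarray:
    return trimesh.transformations.rotation_matrix(
        angle, [0.0, 1.0, 0.0]
    )[:3, :3]


def slide_to_axial(
    mesh: trimesh.Trimesh,
    pose1: RigidTransform,
    min_separation: float = 10.0,
) -> RigidTransform:
    """Second stage: bring the distal condyles onto the axial plane z = 0.

    With the coronal contact preserved (motion restricted to rotation about
    the coronal normal and translation in the coronal plane), the silhouette
    in the (x, z) plane is rotated onto the stable support edge nearest the
    current down direction (-z) whose two contact points are separated by
    more than ``min_separation`` mm in x — two condyles, not one point.
    Returns the composite transform (``pose1`` followed by the slide).
    """
    m1 = pose1.apply_to(mesh)
    if float(m1.vertices[:, 1].min()) < -1e-6:
        raise StateError("mesh is not resting on the coronal plane")
    verts = m1.vertices.view(np.ndarray)
    com = m1.center_mass
    edges = _stable_edges_2d(verts[:, [0, 2]], np.array([com[0], com[2]]))
    # the support edge is horizontal after the rotation, so its length is the
    # contact separation: two condyles, not one point.  This stage adjusts
    # the distal end while the bone stays put, so only rests reachable by a
    # modest rotation (< 45 deg) from the current orientation qualify.
    edges = [
        e
        for e in edges
        if e["length"] > min_separation and abs(e["angle"]) < np.pi / 4
    ]
    if not edges:
        raise ContactError(
            "no stable distal support with two contact points separated by "
            f"> {min_separation} mm"
        )
    best = min(edges, key=lambda e: abs(e["angle"]))
    rot = _rot_about_y(best["angle"])
    v2 = verts @ rot.T
    tz = -v2[:, 2].min()
    slide = RigidTransform(rot, np.array([0.0, 0.0, tz]))
    return slide.compose(pose1)


def _canonical_coronal_rest(mesh: trimesh.Trimesh) -> RigidTransform:
    """Pose-independent coronal rest: the largest-area stable support."""
    rests = _stable_rests(mesh)
    if not rests:
        raise SettlingError("no stable resting face found on the convex hull")
    best = max(rests, key=lambda r: r["area"])
    down = np.array([0.0, -1.0, 0.0])
    rot = _rotation_between(best["normal"], down)
    verts = mesh.vertices.view(np.ndarray) @ rot.T
    ty = -verts[:, 1].min()
    return RigidTransform(rot, np.array([0.0, ty, 0.0]))


def _contact_pair_x(verts: np.ndarray, tol: float = 0.1):
    """x positions of the two lowest-z contact clusters (None if < 2)."""
    low = verts[verts[:, 2] < verts[:, 2].min() + tol]
    xs = np.sort(low[:, 0])
    gaps = np.diff(xs)
    if len(xs) < 2 or gaps.max() < 5.0:
        return None
    split = int(np.argmax(gaps)) + 1
    left = xs[:split]
    right = xs[split:]
    lx = float(left[np.argmin(np.abs(left - np.median(left)))])
    rx = float(right[np.argmin(np.abs(right - np.median(right)))])
    return lx, rx


def standardize(
    cortex: trimesh.Trimesh, extras=(), min_separation: float = 10.0
):
    """Full two-stage standardization; returns (transform, transformed extras).

    The coronal rest is chosen pose-independently (the largest-area stable
    support polygon — the designed posterior three-point support), the distal
    rest among qualifying stable silhouette edges is chosen head-up (maximal
    center-of-mass height, the anatomical orientation), and the frame is
    centered so the distal contact pair straddles x = 0.  The identical
    transform is applied to every object in ``extras`` (canal mesh,
    centerline, fitted circle).
    """
    pose1 = _canonical_coronal_rest(cortex)
    m1 = pose1.apply_to(cortex)
    verts = m1.vertices.view(np.ndarray)
    com = m1.center_mass
    edges = _stable_edges_2d(verts[:, [0, 2]], np.array([com[0], com[2]]))
    edges = [e for e in edges if e["length"] > min_separation]
    if not edges:
        raise ContactError("no qualifying distal contact pair found")

    def com_height(e):
        rot = _rot_about_y(e["angle"])
        c = rot @ com
        v = verts @ rot.T
        return c[2] - v[:, 2].min()

    best = max(edges, key=com_height)
    rot = _rot_about_y(best["angle"])
    v2 = verts @ rot.T
    tz = -v2[:, 2].min()
    pose = RigidTransform(rot, np.array([0.0, 0.0, tz])).compose(pose1)

    # center the distal contact pair on x = 0
    v3 = pose.apply(cortex.vertices.view(np.ndarray))
    pair = _contact_pair_x(v3)
    if pair is not None:
        tx = -(pair[0] + pair[1]) / 2.0
        pose = RigidTransform(np.eye(3), np.array([tx, 0.0, 0.0])).compose(pose)

    transformed = tuple(pose.apply_to(obj) for obj in extras)
    return pose, transformed


def femoral_length(cortex_std: trimesh.Trimesh) -> float:
    """Axial (z) extent of a standardized femur: head apex to condylar rest."""
    z = cortex_std.vertices.view(np.ndarray)[:, 2]
    if z.min() < -1e-3:
        raise StateError("mesh is not standardized (distal contact below z=0)")
    return float(z.max() - z.min())
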