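"""Nail-surrogate torus construction and canal-clearance checking.

An intramedullary nail matched to the bone is modeled as a torus segment:
its centerline is the circle fitted to the canal centerline and its tube
diameter is the isthmus diameter.  Whether such a nail interferes with the
inner cortex is decided quantitatively: the torus surface is sampled
quasi-uniformly and the signed distance to the canal surface (positive
inside) is evaluated at every sample, giving a worst-case clearance margin in
mm and the arc location where it occurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh

from ._meshdist import MeshDistance
from .centerline import Centerline
from .circle_geometry import Circle3D
from .errors import InputError, ParameterError

__all__ = [
    "ClearanceReport",
    "TorusSpec",
    "torus_spec_for_centerline",
    "build_torus",
    "check_clearance",
]


@dataclass(frozen=True)
class ClearanceReport:
    """Result of a torus-vs-canal interference check.

    ``min_clearance`` is the smallest signed distance of any torus-surface
    sample to the canal surface (positive = torus inside the canal with that
    margin); ``intersects`` is exactly ``min_clearance < 0``;
    ``worst_location`` is the arc fraction (0 proximal, 1 distal) of the
    worst sample.
    """

    min_clearance: float
    intersects: bool
    worst_location: float

    def __post_init__(self):
        if self.intersects != (self.min_clearance < 0):
            raise ParameterError("intersects must equal min_clearance < 0")

    def to_dict(self) -> dict:
        return {
            "min_clearance_mm": float(self.min_clearance),
            "intersects": bool(self.intersects),
            "worst_location_arc_fraction": float(self.worst_location),
        }


@dataclass(frozen=True)
class TorusSpec:
    """Parametric partial torus: centerline circle, tube diameter, and the
    angular range (radians, about ``u_ref`` in the circle plane)."""

    circle: Circle3D
    tube_diameter: float
    angle_range: tuple
    u_ref: np.ndarray

    def __post_init__(self):
        if not 0.0 < self.tube_diameter < 2.0 * self.circle.radius:
            raise ParameterError(
                "tube_diameter must lie in (0, 2 * circle radius)"
            )
        u = np.asarray(self.u_ref, dtype=float)
        u = u - (u @ self.circle.normal) * self.circle.normal
        n = np.linalg.norm(u)
        if n < 1e-12:
            raise ParameterError("u_ref must have an in-plane component")
        object.__setattr__(self, "u_ref", u / n)

    def frame(self):
        u = self.u_ref
        v = np.cross(self.circle.normal, u)
        return u, v

    def surface_points(self, psi: np.ndarray, phi: np.ndarray):
        """Torus surface at center-angle psi and tube-angle phi (paired)."""
        u, v = self.frame()
        c = self.circle.center
        R = self.circle.radius
        r = self.tube_diameter / 2.0
        ring_dir = np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * v
        ring = c + R * ring_dir
        nrm = np.broadcast_to(self.circle.normal, ring_dir.shape)
        return ring + r * (
            np.cos(phi)[:, None] * ring_dir + np.sin(phi)[:, None] * nrm
        )


def torus_spec_for_centerline(
    circle: Circle3D, centerline: Centerline, tube_diameter: float
) -> TorusSpec:
    """Torus spec whose angular range spans the (trimmed) centerline.

    The reference direction is taken toward the proximal centerline end, so
    arc fraction 0 of the torus corresponds to the proximal end of the
    centerline and 1 to the distal end.
    """
    u, v = _plane_basis(circle)
    rel = centerline.points - circle.center
    ang = np.unwrap(np.arctan2(rel @ v, rel @ u))
    a0, a1 = float(ang[0]), float(ang[-1])
    return TorusSpec(
        circle=circle,
        tube_diameter=tube_diameter,
        angle_range=(0.0, a1 - a0),
        u_ref=np.cos(a0) * u + np.sin(a0) * v,
    )


def _plane_basis(circle: Circle3D):
    n = circle.normal
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def build_torus(
    circle: Circle3D,
    tube_diameter: float,
    arc_range: tuple = (0.0, 1.0),
    n_u: int = 128,
    n_v: int = 32,
    u_ref=None,
) -> trimesh.Trimesh:
    """Watertight (partial) torus mesh on the circle.

    ``arc_range`` is in fractions of the full circle measured from ``u_ref``;
    a full-circle range produces a closed torus, anything shorter is capped
    with planar fans at both ends.
    """
    if not 0.0 < tube_diameter < 2.0 * circle.radius:
        raise ParameterError("tube_diameter must lie in (0, 2 * circle radius)")
    a0, a1 = arc_range
    if not a1 > a0:
        raise ParameterError("arc_range must be increasing")
    if u_ref is None:
        u_ref = _plane_basis(circle)[0]
    spec = TorusSpec(
        circle=circle,
        tube_diameter=tube_diameter,
        angle_range=(2 * math.pi * a0, 2 * math.pi * a1),
        u_ref=u_ref,
    )
    closed = math.isclose(a1 - a0, 1.0, abs_tol=1e-12)
    psi0, psi1 = spec.angle_range
    n_rings = n_u if closed else n_u + 1
    psi = (
        np.linspace(psi0, psi1, n_u, endpoint=False)
        if closed
        else np.linspace(psi0, psi1, n_rings)
    )
    phi = np.linspace(0.0, 2.0 * math.pi, n_v, endpoint=False)

    u, v = spec.frame()
    c = circle.center
    R = circle.radius
    r = tube_diameter / 2.0
    ring_dir = np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * v
    centers = c + R * ring_dir
    nrm = spec.circle.normal
    verts = (
        centers[:, None, :]
        + r * np.cos(phi)[None, :, None] * ring_dir[:, None, :]
        + r * np.sin(phi)[None, :, None] * nrm[None, None, :]
    ).reshape(-1, 3)

    faces = []
    n_seg = n_u if closed else n_rings - 1
    for i in range(n_seg):
        i2 = (i + 1) % n_rings
        b0, b1 = i * n_v, i2 * n_v
        for j in range(n_v):
            jn = (j + 1) % n_v
            faces.append([b0 + j, b1 + j, b1 + jn])
            faces.append([b0 + j, b1 + jn, b0 + jn])
    if not closed:
        for j in range(1, n_v - 1):
            faces.append([0, j, j + 1])
        last = (n_rings - 1) * n_v
        for j in range(1, n_v - 1):
            faces.append([last, last + j + 1, last + j])

    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def check_clearance(
    torus,
    canal: trimesh.Trimesh,
    n_samples: int = 20000,
) -> ClearanceReport:
    """Signed clearance of a torus inside a canal mesh.

    ``torus`` is a :class:`TorusSpec` (preferred: samples are placed exactly
    on the analytic surface) or a torus mesh (vertices are used as samples,
    with arc locations from the angle about the mesh's best-fit plane).
    Samples are laid on a quasi-uniform (psi, phi) grid; the report carries
    the minimum signed distance (positive inside the canal) and the arc
    fraction of the worst sample.
    """
    if not isinstance(canal, trimesh.Trimesh) or not canal.is_watertight:
        raise InputError("canal must be a watertight trimesh.Trimesh")
    if isinstance(torus, TorusSpec):
        psi0, psi1 = torus.angle_range
        span = abs(psi1 - psi0)
        R = torus.circle.radius
        r = torus.tube_diameter / 2.0
        aspect = max(span * R / max(2 * math.pi * r, 1e-9), 1.0)
        n_psi = max(int(round(math.sqrt(n_samples * aspect))), 8)
        n_phi = max(int(round(n_samples / n_psi)), 8)
        psi = np.linspace(psi0, psi1, n_psi)
        phi = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)
        PP, FF = np.meshgrid(psi, phi, indexing="ij")
        pts = torus.surface_points(PP.ravel(), FF.ravel())
        frac = ((PP.ravel() - psi0) / (psi1 - psi0)) if span > 0 else np.zeros(PP.size)
    elif isinstance(torus, trimesh.Trimesh):
        pts = torus.vertices.view(np.ndarray)
        from .circle_geometry import fit_plane

        centroid, normal = fit_plane(pts)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(normal, ref)
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        rel = pts - centroid
        ang = np.arctan2(rel @ v, rel @ u)
        frac = (ang - ang.min()) / max(ang.max() - ang.min(), 1e-12)
    else:
        raise InputError("torus must be a TorusSpec or a trimesh.Trimesh")

    d = MeshDistance(canal).signed(pts)
    worst = int(np.argmin(d))
    min_clear = float(d[worst])
    return ClearanceReport(
        min_clearance=min_clear,
        intersects=min_clear < 0,
        worst_location=float(frac[worst]),
    )
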