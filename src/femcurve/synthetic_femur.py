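"""Parametric femur-like meshes and cohort tables with exact ground truth.

The generator emulates the geometry the measurement pipeline is built for: a
medullary canal whose centerline is a circular arc of radius R (the radius of
femoral curvature), tilted at a banking angle beta relative to the coronal
plane, swept with a parabolic radius profile whose interior minimum is the
isthmus; a cortical shell around it carrying a femoral-head sphere and
hemispherically protruding landmark bumps whose extremal points define the
standardized resting pose exactly.  Everything is deterministic given the
parameters, and the returned :class:`GroundTruth` is the oracle for all
downstream recovery tests.

Standard frame convention (the frame the meshes are generated in):
+z distal -> proximal (axial plane z = 0, bone in z >= 0), +y posterior ->
anterior (coronal plane y = 0, bone in y >= 0), medial = +x for left femurs
and -x for right.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh

from .errors import ParameterError

__all__ = [
    "FemurParams",
    "GroundTruth",
    "ArcSpec",
    "make_canal_arc",
    "make_femur_meshes",
    "make_cohort_table",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_NOISE_SD",
]

_SCHEMA_VERSION = "femcurve-truth-1"


@dataclass(frozen=True)
class FemurParams:
    """Parameters of one synthetic femur.  Lengths in mm, angles in degrees.

    ``R_curvature`` is the radius of the canal's virtual circle; ``banking``
    the inclination of its plane to the coronal plane, opening medially
    (90 = pure anterior bow); ``arc_span`` the subtended angle of the canal
    arc; ``apex_offset`` shifts the bow apex along the arc (0 = mid-arc);
    the canal radius profile runs from ``canal_radius_max`` at the ends to
    ``canal_radius_min`` at arc fraction ``isthmus_frac``.
    """

    R_curvature: float = 1000.0
    banking: float = 93.5
    arc_span: float = 16.0
    apex_offset: float = 0.0
    canal_radius_min: float = 5.25
    canal_radius_max: float = 8.0
    isthmus_frac: float = 0.55
    cortex_thickness: float = 5.0
    length_total: float = 428.0
    side: str = "left"
    mesh_resolution: tuple = (96, 160)
    seed: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right'")
        if not self.R_curvature > 0:
            raise ParameterError("R_curvature must be > 0")
        if not 0.0 < self.banking < 180.0:
            raise ParameterError("banking must lie in (0, 180) degrees")
        if not 0.0 < self.arc_span < 90.0:
            raise ParameterError("arc_span must lie in (0, 90) degrees")
        if not -0.5 < self.apex_offset < 0.5:
            raise ParameterError("apex_offset must lie in (-0.5, 0.5)")
        if not 0.0 < self.canal_radius_min <= self.canal_radius_max:
            raise ParameterError(
                "need 0 < canal_radius_min <= canal_radius_max"
            )
        if not 0.0 < self.isthmus_frac < 1.0:
            raise ParameterError("isthmus_frac must lie in (0, 1)")
        if not self.cortex_thickness > 0:
            raise ParameterError("cortex_thickness must be > 0")
        if not self.length_total > 0:
            raise ParameterError("length_total must be > 0")
        n_circ, n_ax = self.mesh_resolution
        if n_circ < 24 or n_ax < 60:
            raise ParameterError(
                "mesh_resolution needs >= 24 circumferential and >= 60 axial "
                "segments"
            )
        if self.chord_length > self.length_total:
            raise ParameterError(
                "arc chord implied by R_curvature and arc_span exceeds "
                "length_total"
            )

    @property
    def chord_length(self) -> float:
        return 2.0 * self.R_curvature * math.sin(math.radians(self.arc_span) / 2)

    @classmethod
    def for_study(
        cls,
        R_curvature: float,
        banking: float,
        isthmus_diameter: float,
        length_total: float = 428.0,
        chord_fraction: float = 0.62,
        **kwargs,
    ) -> "FemurParams":
        """Parameters with the arc span set so the canal chord is a fixed
        fraction of the femur length (the anatomical situation: the shaft
        between lesser trochanter and condylar flare)."""
        half = chord_fraction * length_total / (2.0 * R_curvature)
        if not 0 < half < 1:
            raise ParameterError("chord fraction incompatible with R and length")
        span = math.degrees(2.0 * math.asin(half))
        r_min = isthmus_diameter / 2.0
        return cls(
            R_curvature=R_curvature,
            banking=banking,
            arc_span=span,
            canal_radius_min=r_min,
            canal_radius_max=r_min + 2.75,
            length_total=length_total,
            **kwargs,
        )


@dataclass(frozen=True)
class ArcSpec:
    """Analytic description of the canal centerline arc.

    Points are ``center + R (cos(theta) d + sin(theta) axis)`` with
    ``theta(t) = span * (0.5 + apex_offset - t)`` for arc fraction
    t in [0, 1]; t = 0 is proximal.  ``d`` is the in-plane apex direction
    (transverse), ``axis`` the proximal axis (+z).
    """

    center: np.ndarray
    radius: float
    d: np.ndarray
    axis: np.ndarray
    span_rad: float
    apex_offset: float

    def theta(self, t):
        return self.span_rad * (0.5 + self.apex_offset - np.asarray(t, dtype=float))

    def point(self, t):
        th = self.theta(t)
        return (
            self.center
            + self.radius * np.cos(th)[..., None] * self.d
            + self.radius * np.sin(th)[..., None] * self.axis
        )

    def tangent(self, t):
        """Unit tangent in the direction of increasing t (proximal->distal)."""
        th = self.theta(t)
        return np.sin(th)[..., None] * self.d - np.cos(th)[..., None] * self.axis

    @property
    def plane_normal(self):
        n = np.cross(self.d, self.axis)
        return n / np.linalg.norm(n)

    def t_for_z(self, z: float) -> float:
        s = (z - self.center[2]) / self.radius
        if not -1.0 <= s <= 1.0:
            raise ParameterError("z outside the arc's circle")
        return 0.5 + self.apex_offset - math.asin(s) / self.span_rad

    def to_dict(self) -> dict:
        return {
            "center_mm": self.center.tolist(),
            "radius_mm": float(self.radius),
            "apex_direction": self.d.tolist(),
            "axis": self.axis.tolist(),
            "span_deg": math.degrees(self.span_rad),
            "apex_offset": float(self.apex_offset),
        }


@dataclass
class GroundTruth:
    """Exact generator values used as the oracle for recovery tests."""

    R_curvature: float
    banking: float
    isthmus_diameter: float
    isthmus_arc_fraction: float
    femoral_length: float
    side: str
    centerline_analytic: ArcSpec
    standard_pose: np.ndarray = field(
        default_factory=lambda: np.eye(4)
    )  # identity: generated in the standard frame
    canal_vertex_t: np.ndarray | None = None  # arc parameter per canal vertex

    def to_dict(self) -> dict:
        return {
            "schema": _SCHEMA_VERSION,
            "R_curvature_mm": float(self.R_curvature),
            "banking_deg": float(self.banking),
            "isthmus_diameter_mm": float(self.isthmus_diameter),
            "isthmus_arc_fraction": float(self.isthmus_arc_fraction),
            "femoral_length_mm": float(self.femoral_length),
            "side": self.side,
            "standard_pose": np.asarray(self.standard_pose).tolist(),
            "centerline_analytic": self.centerline_analytic.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _medial_sign(side: str) -> float:
    return 1.0 if side == "left" else -1.0


def _arc_for_params(params: FemurParams) -> ArcSpec:
    """Arc in the standard frame with its apex point at the origin."""
    b = math.radians(params.banking)
    d = np.array([_medial_sign(params.side) * math.cos(b), math.sin(b), 0.0])
    axis = np.array([0.0, 0.0, 1.0])
    center = -params.R_curvature * d
    return ArcSpec(
        center=center,
        radius=params.R_curvature,
        d=d,
        axis=axis,
        span_rad=math.radians(params.arc_span),
        apex_offset=params.apex_offset,
    )


def make_canal_arc(params: FemurParams, n_points: int) -> np.ndarray:
    """Points on the canal's circular arc (apex at the origin).

    The arc's plane contains the proximal-distal (+z) direction; its apex
    direction lies in the transverse plane at the banking angle from the
    medial direction.  Points are ordered proximal -> distal.
    """
    if n_points < 3:
        raise ParameterError("n_points must be >= 3")
    arc = _arc_for_params(params)
    t = np.linspace(0.0, 1.0, n_points)
    return arc.point(t)


def canal_radius_profile(params: FemurParams, t) -> np.ndarray:
    """Canal radius r(t): parabolic with minimum at the isthmus fraction,
    clipped at ``canal_radius_max``."""
    t = np.asarray(t, dtype=float)
    r = params.canal_radius_min + (
        params.canal_radius_max - params.canal_radius_min
    ) * ((t - params.isthmus_frac) / 0.5) ** 2
    return np.minimum(r, params.canal_radius_max)


def _swept_tube(
    arc: ArcSpec, radius_fn, t0: float, t1: float, n_circ: int, n_ax: int
):
    """Watertight tube swept along the arc; returns (mesh, vertex_t).

    Ring vertices sit exactly at distance radius_fn(t) from the arc point at
    their own parameter t; end caps are fans over the end rings (no extra
    vertices), keeping that invariant for every vertex.
    """
    t = np.linspace(t0, t1, n_ax + 1)
    centers = arc.point(t)
    th = arc.theta(t)
    e1 = np.cos(th)[:, None] * arc.d + np.sin(th)[:, None] * arc.axis  # radial
    e2 = np.broadcast_to(arc.plane_normal, e1.shape)
    radii = np.asarray(radius_fn(t), dtype=float)

    phi = np.linspace(0.0, 2.0 * np.pi, n_circ, endpoint=False)
    ring = (
        np.cos(phi)[None, :, None] * e1[:, None, :]
        + np.sin(phi)[None, :, None] * e2[:, None, :]
    )
    verts = centers[:, None, :] + radii[:, None, None] * ring
    vertex_t = np.repeat(t, n_circ)
    verts = verts.reshape(-1, 3)

    faces = []
    for i in range(n_ax):
        base0 = i * n_circ
        base1 = (i + 1) * n_circ
        for j in range(n_circ):
            jn = (j + 1) % n_circ
            faces.append([base0 + j, base1 + j, base1 + jn])
            faces.append([base0 + j, base1 + jn, base0 + jn])
    # caps: fans anchored at vertex 0 of each end ring
    for j in range(1, n_circ - 1):
        faces.append([0, j, j + 1])
    last = n_ax * n_circ
    for j in range(1, n_circ - 1):
        faces.append([last, last + j + 1, last + j])

    mesh = trimesh.Trimesh(
        vertices=verts, faces=np.asarray(faces), process=False
    )
    if mesh.volume < 0:
        mesh.invert()
    return mesh, vertex_t


def _pole_sphere(radius, center, pole_dir, count=(16, 16)) -> trimesh.Trimesh:
    """UV sphere with an exact vertex at ``center + radius * pole_dir``."""
    s = trimesh.creation.uv_sphere(radius=radius, count=count)
    pole = np.asarray(pole_dir, dtype=float)
    pole /= np.linalg.norm(pole)
    z = np.array([0.0, 0.0, 1.0])
    rot = trimesh.geometry.align_vectors(z, pole)
    s.apply_transform(rot)
    s.apply_translation(np.asarray(center, dtype=float))
    return s


def make_femur_meshes(params: FemurParams):
    """Build (cortex_mesh, canal_mesh, truth) in the standard frame.

    The cortex is a multi-body watertight mesh: shaft tube, head sphere, three
    posterior landmark bumps with exactly coplanar extremal points (the
    coronal support plane), two distal condylar bumps with coplanar extremal
    points (the axial plane), and a medial epicondyle marker.  The center of
    mass projects inside the posterior support triangle, so the standardized
    pose is the unique wide-base stable rest.
    """
    n_circ, n_ax = params.mesh_resolution
    arc_len = params.R_curvature * math.radians(params.arc_span)
    if arc_len / n_ax > 0.02 * arc_len:
        raise ParameterError("axial resolution too low to resolve the isthmus")

    # geometry is built for a left femur and mirrored at the end if needed
    p_left = params if params.side == "left" else replace(params, side="left")
    arc = _arc_for_params(p_left)

    L = params.length_total
    r_head = max(14.0, 0.042 * L)
    z_canal_lo = 0.14 * L
    # place the arc: distal canal end at z_canal_lo
    th1 = arc.theta(1.0)
    center = arc.center.copy()
    center[2] = z_canal_lo - arc.radius * math.sin(th1)
    arc = replace(arc, center=center)

    z_canal_hi = float(arc.point(0.0)[2])
    z_cort_hi = L - 2.0 * r_head
    if z_canal_hi > z_cort_hi - 2.0:
        raise ParameterError(
            "canal arc too long for length_total; reduce arc_span"
        )
    z_cort_lo = 6.0
    t_hi = arc.t_for_z(z_cort_lo)
    t_lo = arc.t_for_z(z_cort_hi)

    def cortex_radius(t):
        return canal_radius_profile(p_left, np.clip(t, 0.0, 1.0)) + params.cortex_thickness

    canal, canal_t = _swept_tube(arc, lambda t: canal_radius_profile(p_left, t), 0.0, 1.0, n_circ, n_ax)
    n_ax_cort = int(round(n_ax * (t_hi - t_lo)))
    shaft, _ = _swept_tube(arc, cortex_radius, t_lo, t_hi, n_circ, max(n_ax_cort, 60))

    x_d, y_d = arc.point(t_hi)[:2]
    x_p, y_p = arc.point(t_lo)[:2]

    head = _pole_sphere(
        r_head, [x_p, y_p, L - r_head], [0, 0, 1], count=(24, 24)
    )
    r_b = 4.0
    distal_bumps = [
        _pole_sphere(r_b, [x_d - 20.0, y_d, r_b], [0, 0, -1]),
        _pole_sphere(r_b, [x_d + 20.0, y_d, r_b], [0, 0, -1]),
    ]
    epicondyle = _pole_sphere(3.0, [x_d + 26.0, y_d, 16.0], [1, 0, 0])

    z_gt = 0.88 * L
    t_gt = arc.t_for_z(z_gt)
    x_gt = float(arc.point(t_gt)[0])

    rest = [shaft, head, *distal_bumps, epicondyle]
    y_min_rest = min(float(m.vertices[:, 1].min()) for m in rest)
    y_plane = y_min_rest - 1.5
    post_centers = [
        [x_d - 22.0, y_plane + r_b, 12.0],
        [x_d + 22.0, y_plane + r_b, 12.0],
        [x_gt, y_plane + r_b, z_gt],
    ]
    posterior_bumps = [
        _pole_sphere(r_b, c, [0, -1, 0]) for c in post_centers
    ]

    cortex = trimesh.util.concatenate(rest + posterior_bumps)
    shift = np.array([-x_d, -y_plane, 0.0])
    cortex.apply_translation(shift)
    canal.apply_translation(shift)
    arc = replace(arc, center=arc.center + shift)

    # stability guarantee: COM projects inside the posterior support triangle
    com = cortex.center_mass
    tri = np.array(
        [[-22.0, 12.0], [22.0, 12.0], [x_gt - x_d, z_gt]]
    )  # (x, z) support triangle after the shift
    if not _point_in_triangle(np.array([com[0], com[2]]), tri, margin=2.0):
        raise ParameterError(
            "center of mass falls outside the posterior support triangle; "
            "adjust parameters"
        )

    if params.side == "right":
        cortex = _mirror_x(cortex)
        canal = _mirror_x(canal)
        arc = replace(arc, center=arc.center * np.array([-1.0, 1.0, 1.0]),
                      d=arc.d * np.array([-1.0, 1.0, 1.0]))

    truth = GroundTruth(
        R_curvature=params.R_curvature,
        banking=params.banking,
        isthmus_diameter=2.0 * params.canal_radius_min,
        isthmus_arc_fraction=params.isthmus_frac,
        femoral_length=L,
        side=params.side,
        centerline_analytic=arc,
        canal_vertex_t=canal_t,
    )
    return cortex, canal, truth


def _mirror_x(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Exact reflection across the sagittal plane x = 0 (winding repaired)."""
    v = mesh.vertices.view(np.ndarray).copy()
    v[:, 0] *= -1.0
    f = mesh.faces.view(np.ndarray)[:, ::-1].copy()
    return trimesh.Trimesh(vertices=v, faces=f, process=False)


def _point_in_triangle(p, tri, margin=0.0) -> bool:
    """Is 2D point ``p`` inside ``tri`` with at least ``margin`` clearance."""
    d = []
    for i in range(3):
        a, b = tri[i], tri[(i + 1) % 3]
        e = b - a
        n = np.array([-e[1], e[0]])
        n /= np.linalg.norm(n)
        d.append(n @ (p - a))
    d = np.asarray(d)
    if np.all(d >= 0):
        return bool(np.min(d) >= margin)
    if np.all(d <= 0):
        return bool(np.min(-d) >= margin)
    return False


# ---------------------------------------------------------------------------
# cohort tables

#: Linear models used to generate per-femur morphometrics.  Binary codings:
#: gender female=1/male=0, laterality left=1/right=0.
DEFAULT_COEFFICIENTS = {
    "rfc_mm": {
        "intercept": 267.36,
        "length_mm": 2.23,
        "banking_deg": -2.88,
        "laterality": 57.49,
        "gender": -50.3,
    },
    "banking_deg": {
        "intercept": 59.69,
        "gender": 5.7,
        "age_y": 0.236,
        "weight_kg": 0.157,
    },
}

DEFAULT_NOISE_SD = {
    "rfc_mm": 190.0,
    "banking_deg": 10.0,
    "length_mm": 13.5,
    "isthmus_mm": 1.55,
}

_ALIASES = {
    "length": "length_mm",
    "banking": "banking_deg",
    "rfc": "rfc_mm",
    "isthmus": "isthmus_mm",
    "age": "age_y",
    "height": "height_m",
    "weight": "weight_kg",
}


def _canon(name: str) -> str:
    return _ALIASES.get(name, name)


def _normalize_coefficients(coefficients) -> dict:
    if coefficients is None:
        return {k: dict(v) for k, v in DEFAULT_COEFFICIENTS.items()}
    out = {k: dict(v) for k, v in DEFAULT_COEFFICIENTS.items()}
    if any(isinstance(v, dict) for v in coefficients.values()):
        for resp, terms in coefficients.items():
            out[_canon(resp)] = { _canon(k): float(v) for k, v in terms.items() }
    else:
        # flat mapping: terms of the RFC model
        model = {"intercept": DEFAULT_COEFFICIENTS["rfc_mm"]["intercept"]}
        for k, v in coefficients.items():
            model[_canon(k)] = float(v)
        out["rfc_mm"] = model
    return out


def make_cohort_table(
    n_subjects: int,
    coefficients: dict | None = None,
    noise_sd: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort table: two femurs (left/right) per subject.

    Demographics are drawn from per-gender normal distributions matching a
    large adult CT cohort; femoral length follows height; the banking angle
    and RFC follow the configured linear models plus Gaussian noise.  Codings:
    gender female=1/male=0, laterality left=1/right=0.
    """
    if n_subjects < 10:
        raise ParameterError("n_subjects must be >= 10")
    coeffs = _normalize_coefficients(coefficients)
    sds = dict(DEFAULT_NOISE_SD)
    if noise_sd is not None:
        for k, v in noise_sd.items():
            if float(v) < 0:
                raise ParameterError("noise_sd values must be >= 0")
            sds[_canon(k)] = float(v)

    rng = np.random.default_rng(seed)
    gender = (rng.random(n_subjects) < 132.0 / 426.0).astype(float)
    age = np.where(
        gender == 1,
        np.clip(rng.normal(69.68, 8.39, n_subjects), 50, 85),
        np.clip(rng.normal(64.49, 12.86, n_subjects), 15, 85),
    )
    height = np.where(
        gender == 1,
        rng.normal(1.58, 0.061, n_subjects),
        rng.normal(1.69, 0.058, n_subjects),
    )
    weight = np.where(
        gender == 1,
        rng.normal(62.03, 9.9, n_subjects),
        rng.normal(68.58, 9.77, n_subjects),
    )

    rows = []
    for side, lat in (("left", 1.0), ("right", 0.0)):
        df = pd.DataFrame(
            {
                "subject_id": np.arange(1, n_subjects + 1),
                "side": side,
                "laterality": lat,
                "gender": gender,
                "age_y": age,
                "height_m": height,
                "weight_kg": weight,
            }
        )
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    n = len(table)

    length_base = -28.4 + 275.0 * table["height_m"].to_numpy()
    table["length_mm"] = (
        length_base
        + 0.59 * (table["laterality"].to_numpy() - 0.5)
        + rng.normal(0.0, 1.0, n) * sds["length_mm"]
    )

    def predictor(model_key):
        model = coeffs[model_key]
        out = np.full(n, model.get("intercept", 0.0))
        for term, coef in model.items():
            if term == "intercept":
                continue
            if term not in table.columns:
                raise ParameterError(f"unknown model term {term!r}")
            out = out + coef * table[term].to_numpy()
        return out

    table["banking_deg"] = (
        predictor("banking_deg") + rng.normal(0.0, 1.0, n) * sds["banking_deg"]
    )
    table["rfc_mm"] = (
        predictor("rfc_mm") + rng.normal(0.0, 1.0, n) * sds["rfc_mm"]
    )

    k_shape = 8.4
    g = rng.gamma(k_shape, 1.0, n)
    table["isthmus_mm"] = 10.5 + (g - k_shape) / math.sqrt(k_shape) * sds["isthmus_mm"]

    table = table.sort_values(["subject_id", "side"], ignore_index=True)
    return table
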