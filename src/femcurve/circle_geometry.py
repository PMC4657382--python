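"""Plane and 3D circle fitting, projections, and apex-curvature closed forms.

The radius of femoral curvature (RFC) is the radius of a circle fitted to the
medullary-canal centerline in 3D.  Fitting proceeds in two stages: a
total-least-squares plane (smallest principal direction of the centered
points), then an in-plane circle fit initialized algebraically (linearized
circle equation) and refined by geometric least squares, minimizing the true
radial residuals sum((|p - c| - r)^2).  The geometric refinement matters for
the short arcs this package sees: a mid-shaft canal subtends only ~15-25
degrees of its virtual circle, where the algebraic fit is biased under noise.

Angles are degrees at the API boundary, radians internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegeneracyError, FitWarning, ParameterError

__all__ = [
    "Circle3D",
    "fit_plane",
    "fit_circle_3d",
    "fit_circle_2d",
    "project_points",
    "apex_projected_radius",
    "circumcircle_2d",
]


@dataclass(frozen=True)
class Circle3D:
    """A circle in 3D: center [mm], radius [mm], unit plane normal, fit rmse [mm]."""

    center: np.ndarray
    radius: float
    normal: np.ndarray
    rmse: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if not np.isfinite(nn) or nn < 1e-12:
            raise ParameterError("circle normal must be non-degenerate")
        object.__setattr__(self, "normal", n / nn)
        if not self.radius > 0:
            raise ParameterError("circle radius must be > 0")

    def to_dict(self) -> dict:
        return {
            "center_mm": self.center.tolist(),
            "radius_mm": float(self.radius),
            "normal": self.normal.tolist(),
            "rmse_mm": float(self.rmse),
        }


def _canonical_normal_sign(normal: np.ndarray) -> np.ndarray:
    """Fix the sign so the first non-negligible component of (x, y, z) is >= 0.

    In the standardized frame this makes the medial (x) component non-negative
    for left femurs, with the anterior (y) then axial (z) components breaking
    ties, so banking angles are reproducible across runs.
    """
    for comp in normal:
        if abs(comp) > 1e-9:
            return normal if comp > 0 else -normal
    return normal


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through >= 3 non-collinear points.

    Returns (centroid, unit normal).  The normal is the singular direction of
    the centered points with the smallest singular value; collinear input
    (second singular value < 1e-9 x first) raises :class:`DegeneracyError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ParameterError("fit_plane needs an (n>=3, 3) point array")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise DegeneracyError("points are collinear; no unique plane")
    return centroid, _canonical_normal_sign(vt[2])


def fit_circle_2d(
    xy: np.ndarray, tol: float = 1e-10, max_iter: int = 200
) -> tuple[np.ndarray, float, bool]:
    """Least-squares circle in the plane.

    Algebraic (Kasa) initialization solving the linearized circle equation,
    then Gauss-Newton on the true radial residuals with relative parameter
    tolerance ``tol``.  Returns (center, radius, converged).
    """
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r = math.sqrt(max(sol[2] + cx * cx + cy * cy, 1e-300))

    theta = np.array([cx, cy, r])
    converged = False
    for _ in range(max_iter):
        dx = x - theta[0]
        dy = y - theta[1]
        rho = np.hypot(dx, dy)
        rho_safe = np.maximum(rho, 1e-300)
        res = rho - theta[2]
        J = np.column_stack([-dx / rho_safe, -dy / rho_safe, -np.ones_like(rho)])
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        theta = theta + step
        if np.max(np.abs(step)) <= tol * max(1.0, np.max(np.abs(theta))):
            converged = True
            break
    return theta[:2], float(abs(theta[2])), converged


def fit_circle_3d(points: np.ndarray) -> Circle3D:
    """Fit a circle to >= 3 non-collinear 3D points (algebraic + geometric).

    Points are projected onto the total-least-squares plane, the in-plane
    circle is fitted, and the rmse is the root-mean-square in-plane radial
    residual.  Non-convergence of the geometric stage after 200 iterations
    emits :class:`FitWarning` and returns the last iterate.
    """
    pts = np.asarray(points, dtype=float)
    centroid, normal = fit_plane(pts)
    # in-plane orthonormal basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    rel = pts - centroid
    xy = np.column_stack([rel @ u, rel @ v])

    center2d, radius, converged = fit_circle_2d(xy)
    if not converged:
        warnings.warn(
            "geometric circle refinement did not converge after 200 "
            "iterations; returning last iterate",
            FitWarning,
        )
    center = centroid + center2d[0] * u + center2d[1] * v
    res = np.hypot(xy[:, 0] - center2d[0], xy[:, 1] - center2d[1]) - radius
    rmse = float(np.sqrt(np.mean(res**2)))
    return Circle3D(center=center, radius=radius, normal=normal, rmse=rmse)


def project_points(points: np.ndarray, plane: str) -> np.ndarray:
    """Orthographic projection in the standardized frame.

    ``sagittal`` drops the medial-lateral (x) coordinate and returns (y, z)
    pairs; ``coronal`` drops the anterior-posterior (y) coordinate and returns
    (x, z) pairs.
    """
    pts = np.asarray(points, dtype=float)
    if plane == "sagittal":
        return pts[..., [1, 2]].copy()
    if plane == "coronal":
        return pts[..., [0, 2]].copy()
    raise ParameterError(f"unknown projection plane {plane!r}")


def apex_projected_radius(R: float, beta: float, plane: str) -> float:
    """Radius of curvature at the bow apex of the projected arc.

    A canal circle of radius ``R`` whose plane is inclined at banking angle
    ``beta`` (degrees) to the coronal plane projects to an ellipse; at the bow
    apex its radius of curvature is ``R / sin(beta)`` on the sagittal plane
    and ``R / |cos(beta)|`` on the coronal plane.  At beta = 90 the coronal
    projection is a straight line (returns ``inf``), which is the exact form
    of the observation that the coronal radius grows as the banking angle
    approaches 90 degrees from either side.
    """
    if not R > 0:
        raise ParameterError("R must be > 0")
    if not 0.0 < beta < 180.0:
        raise ParameterError("beta must lie in (0, 180) degrees")
    b = math.radians(beta)
    if plane == "sagittal":
        s = math.sin(b)
        return math.inf if s < 1e-15 else R / s
    if plane == "coronal":
        c = abs(math.cos(b))
        return math.inf if c < 1e-12 else R / c
    raise ParameterError(f"unknown projection plane {plane!r}")


def circumcircle_2d(
    p1, p2, p3, collinear_tol: float = 1e-9
) -> tuple[np.ndarray, float]:
    """Circumcenter and circumradius of three points in the plane.

    Returns radius ``inf`` (center NaN) when the points are collinear: twice
    the signed triangle area below ``collinear_tol`` relative to the squared
    longest side.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    d = 2.0 * (
        p1[0] * (p2[1] - p3[1])
        + p2[0] * (p3[1] - p1[1])
        + p3[0] * (p1[1] - p2[1])
    )
    scale = max(
        np.sum((p2 - p1) ** 2), np.sum((p3 - p2) ** 2), np.sum((p1 - p3) ** 2)
    )
    if abs(d) <= collinear_tol * max(scale, 1e-300):
        return np.array([np.nan, np.nan]), math.inf
    s1 = p1 @ p1
    s2 = p2 @ p2
    s3 = p3 @ p3
    ux = (s1 * (p2[1] - p3[1]) + s2 * (p3[1] - p1[1]) + s3 * (p1[1] - p2[1])) / d
    uy = (s1 * (p3[0] - p2[0]) + s2 * (p1[0] - p3[0]) + s3 * (p2[0] - p1[0])) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(p1 - center))
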