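"""Screw axis reconstruction from digitized point clouds.

The proximal part of each inserted screw is digitized with a touch-probe
coordinate measuring machine (CMM) and fitted to a least-squares cylinder.
The probe reports the coordinates of its spherical tip centre, so points lie
on a cylinder whose radius is the screw radius plus the probe radius; the
compensation leaves the axis unchanged (exact for a cylinder) and is applied
to the reported radius only.

Fitting minimises sum_i (dist(p_i, axis) - r)^2 over the axis (anchor offset
in the plane orthogonal to the initial direction, plus two direction angles)
and, in free-radius mode, the radius.  Initialisation uses the principal axis
of the point covariance and the centroid; refinement uses
``scipy.optimize.least_squares``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import AmbiguousOrientationError, DegenerateGeometryError, FitError
from .geometry import Direction3, Point3, ScrewAxis, TrajectoryPlan, _check_frames

__all__ = ["PointCloud", "CylinderFitResult", "fit_cylinder_axis", "orient_axis_toward_tip"]


@dataclass(frozen=True)
class PointCloud:
    """An (n, 3) array of mm coordinates with a label and a frame tag."""

    points: np.ndarray
    label: str = "screw_proximal"  # or "vertebra_surface"
    frame: str = "CMM"

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if p.shape[0] < 3:
            raise ValueError("a point cloud needs at least 3 points")
        if not np.all(np.isfinite(p)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "points", p)

    def __len__(self):
        return self.points.shape[0]


@dataclass(frozen=True)
class CylinderFitResult:
    """Outcome of a least-squares cylinder fit.

    ``fitted_radius`` is probe-compensated (probe radius subtracted);
    ``extent`` is the (min, max) abscissa of the cloud projected on the axis,
    relative to the anchor.
    """

    axis: ScrewAxis
    fitted_radius: float
    rms_residual: float
    n_points: int
    converged: bool
    extent: tuple = field(default=(0.0, 0.0))


def _principal_axis(p: np.ndarray):
    c = p.mean(axis=0)
    q = p - c
    cov = q.T @ q / len(p)
    w, v = np.linalg.eigh(cov)  # ascending
    return c, w, v


def _dir_from_angles(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def fit_cylinder_axis(
    cloud: PointCloud,
    radius: float | None = None,
    probe_radius: float = 0.0,
    max_nfev: int = 200,
) -> CylinderFitResult:
    """Fit a least-squares cylinder to a digitized screw cloud.

    Parameters
    ----------
    cloud:
        Probe-centre coordinates on the proximal screw surface (n >= 5 for a
        fixed radius, n >= 6 for a free radius; >= 20 recommended).
    radius:
        Known cylinder radius in mm (fixed-radius mode, the default workflow
        with 5 mm screws uses 2.5).  ``None`` frees the radius.
    probe_radius:
        Radius of the spherical CMM sensor tip (mm); the points lie one probe
        radius outside the physical surface, so the fitted radius is reduced
        by this amount before reporting.  The axis is unaffected.

    Raises
    ------
    DegenerateGeometryError
        if the cloud is collinear or coplanar within tolerance.
    FitError
        if there are too few points.
    """
    p = cloud.points
    n = len(p)
    free = radius is None
    if n < (6 if free else 5):
        raise FitError(f"need at least {'6' if free else '5'} points, got {n}")

    c0, w, v = _principal_axis(p)
    scale = max(w[2], 1e-30)
    if w[1] / scale < 1e-12:
        raise DegenerateGeometryError("point cloud is collinear; cylinder fit is ill-posed")
    if w[0] / scale < 1e-10:
        raise DegenerateGeometryError("point cloud is coplanar; cylinder fit is ill-posed")

    target_r = None if free else radius + probe_radius

    # multi-start over the covariance eigenvectors: on short digitized
    # segments the largest-variance direction can be transverse to the true
    # axis, so every principal direction is tried and the best kept
    best = None
    for d0 in (v[:, 2], v[:, 1], v[:, 0]):
        theta0 = float(np.arccos(np.clip(d0[2], -1.0, 1.0)))
        phi0 = float(np.arctan2(d0[1], d0[0]))
        # anchor offset parametrised in a fixed basis orthogonal to d0
        # (removes the gauge freedom of sliding the anchor along the axis)
        e1 = np.cross(d0, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(d0, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d0, e1)

        def unpack(x, e1=e1, e2=e2):
            a = c0 + x[0] * e1 + x[1] * e2
            d = _dir_from_angles(x[2], x[3])
            r = x[4] if free else target_r
            return a, d, r

        def residuals(x, unpack=unpack):
            a, d, r = unpack(x)
            dist = np.linalg.norm(np.cross(p - a, d), axis=1)
            return dist - r

        if free:
            r0 = float(np.mean(np.linalg.norm(np.cross(p - c0, d0), axis=1)))
            x0 = np.array([0.0, 0.0, theta0, phi0, max(r0, 1e-3)])
        else:
            x0 = np.array([0.0, 0.0, theta0, phi0])

        obj0 = float(np.sum(residuals(x0) ** 2))
        sol = least_squares(
            residuals, x0, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=max_nfev
        )
        obj = float(np.sum(sol.fun**2))
        if obj > obj0 + 1e-12:  # descent guard: never worse than the start
            sol.x, sol.fun, obj = x0, residuals(x0), obj0  # pragma: no cover
        if best is None or obj < best[0]:
            best = (obj, sol, unpack)
    _, sol, unpack = best

    a, d, r = unpack(sol.x)
    t = (p - a) @ d
    t_min, t_max = float(t.min()), float(t.max())
    anchor = a + t_min * d
    axis = ScrewAxis(
        Point3.from_array(anchor, cloud.frame),
        Direction3.from_array(d),
        length=max(t_max - t_min, 1e-6),
        radius=max(r - probe_radius, 1e-6),
    )
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return CylinderFitResult(
        axis=axis,
        fitted_radius=float(r - probe_radius),
        rms_residual=rms,
        n_points=n,
        converged=bool(sol.success),
        extent=(0.0, t_max - t_min),
    )


def orient_axis_toward_tip(
    fit: CylinderFitResult, plan: TrajectoryPlan, screw_length: float | None = None
) -> ScrewAxis:
    """Disambiguate the entry-to-tip sign of a fitted axis using the plan.

    The returned direction has a positive dot product with the planned
    direction; the anchor is relocated to the entry-side end of the measured
    extent.  ``screw_length`` overrides the axis length (e.g. the nominal
    45 mm screw length rather than the digitized proximal extent).
    """
    axis = fit.axis
    _check_frames(axis.frame, plan.frame)
    dot = float(axis.direction.array @ plan.direction.array)
    if abs(dot) < 1e-6:
        raise AmbiguousOrientationError(
            "fitted axis is orthogonal to the planned direction; cannot orient"
        )
    length = screw_length if screw_length is not None else axis.length
    if dot > 0:
        return ScrewAxis(axis.anchor, axis.direction, length=length, radius=axis.radius)
    # flip: the anchor moves to the other end of the measured extent
    far = axis.point_at(axis.length)
    return ScrewAxis(
        Point3.from_array(far, axis.frame),
        Direction3.from_array(-axis.direction.array),
        length=length,
        radius=axis.radius,
    )
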