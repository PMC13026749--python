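"""Signed pedicle-wall distance (dpw), breach detection and clinical grading.

The pedicle is the corridor the screw must traverse.  The pedicle wall
distance ``dpw`` is the minimal signed distance (mm) between the screw axis
and the pedicle cortical wall, evaluated over the axis stations inside the
pedicle's longitudinal extent.  Sign convention: positive when the
minimizing axis point lies inside the pedicle cross-section, negative
outside.  With screw radius R:

* ``dpw >= R``            no breach (axis clears the wall by at least R);
* ``0 <= dpw < R``        breach, axis still inside the canal;
* ``dpw < 0, |dpw| < R``  breach, axis outside but screw still in contact;
* ``dpw < 0, |dpw| >= R`` fully malpositioned (extra-pedicular) screw.

Breach depth is ``R - dpw`` (mm of screw beyond the wall).  The breach
direction (medial / lateral / superior / inferior) is the 90-degree angular
sector of the cross-section containing the vector from the centerline to the
nearest wall point.  The depth and direction feed two clinical graders:

* Gertzbein(-Robbins): 0 (contained), 1/2/3 for medial breaches in 2 mm
  increments, 4 for lateral breaches; directions outside the scheme
  (superior, inferior, anterior) map to the reserved label ``"/"``.
* Heary: I (contained), II (pedicle violated, tip within the vertebral
  body), III (tip beyond the body anteriorly/laterally), IV (medial or
  inferior breach), V (medial breach deep enough to endanger the canal —
  decided by a configurable threshold, not geometry alone); superior
  breaches map to ``"/"``.

Pedicle geometry is either a parametric straight elliptical tube (closed
form per station, default for simulation) or an oriented open triangle mesh
of the canal wall (sign recovered from outward face normals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateGeometryError, PedscrewError
from .geometry import Point3, ScrewAxis

__all__ = [
    "PedicleModel",
    "VertebralBody",
    "WallDistanceResult",
    "ellipse_signed_distance",
    "pedicle_wall_distance",
    "classify_breach",
    "grade_gertzbein",
    "grade_heary",
    "GERTZBEIN_GRADES",
    "HEARY_GRADES",
    "NO_GRADE",
]

NO_GRADE = "/"
GERTZBEIN_GRADES = ("0", "1", "2", "3", "4", NO_GRADE)
HEARY_GRADES = ("I", "II", "III", "IV", "V", NO_GRADE)


def ellipse_signed_distance(x, y, a: float, b: float, iters: int = 60):
    """Signed distance from in-plane points to the ellipse (x/a)^2+(y/b)^2=1.

    Positive inside, negative outside.  Vectorised; the closest boundary
    point is found by bisection of the stationarity condition on the first
    quadrant (unique root there), which is robust for interior points and
    points near the axes.  Returns ``(sd, px, py)``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    sx = np.where(x >= 0, 1.0, -1.0)
    sy = np.where(y >= 0, 1.0, -1.0)
    ax_, ay_ = np.abs(x), np.abs(y)
    # nudge off the major axis so the bisection bracket is strict
    ay_ = np.maximum(ay_, 1e-9)

    d2 = a * a - b * b

    def g(theta):
        return d2 * np.cos(theta) * np.sin(theta) - ax_ * a * np.sin(theta) + ay_ * b * np.cos(theta)

    lo = np.zeros_like(ax_)
    hi = np.full_like(ax_, np.pi / 2)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        pos = g(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    theta = 0.5 * (lo + hi)
    px = a * np.cos(theta)
    py = b * np.sin(theta)
    d = np.hypot(ax_ - px, ay_ - py)
    inside = (x / a) ** 2 + (y / b) ** 2 < 1.0
    sd = np.where(inside, d, -d)
    return sd, sx * px, sy * py


@dataclass(frozen=True)
class PedicleModel:
    """Pedicle canal geometry with its cross-section frame.

    ``center`` is the isthmus centerline midpoint; ``axis`` the tube
    longitudinal unit direction; ``medial`` and ``superior`` the in-plane
    unit directions towards the midline and cranially; ``half_length`` half
    the longitudinal extent (mm).  ``representation`` is ``"parametric"``
    (elliptical cross-section, semi-axes ``a`` medial-lateral and ``b``
    cranio-caudal) or ``"mesh"`` (``mesh`` is an oriented open tube of the
    canal wall with outward normals).
    """

    center: np.ndarray
    axis: np.ndarray
    medial: np.ndarray
    superior: np.ndarray
    half_length: float
    a: float = 0.0
    b: float = 0.0
    representation: str = "parametric"
    mesh: object = None
    level: str = ""
    side: str = "left"
    frame: str = "R0"

    def __post_init__(self):
        for name in ("center", "axis", "medial", "superior"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if self.representation == "parametric" and (self.a <= 0 or self.b <= 0):
            raise ValueError("parametric pedicle needs positive semi-axes")
        if self.representation == "mesh" and self.mesh is None:
            raise ValueError("mesh representation needs a mesh")
        if self.half_length <= 0:
            raise ValueError("half_length must be > 0")

    def to_mesh(self, n_theta: int = 64, n_z: int = 16):
        """Triangulate the parametric tube wall (open tube, outward normals)."""
        import trimesh

        if self.representation != "parametric":
            return self.mesh
        th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        zz = np.linspace(-self.half_length, self.half_length, n_z)
        verts = []
        for z in zz:
            ring = (
                self.center
                + np.outer(self.a * np.cos(th), self.medial)
                + np.outer(self.b * np.sin(th), self.superior)
                + z * self.axis
            )
            verts.append(ring)
        verts = np.concatenate(verts, axis=0)
        faces = []
        for i in range(n_z - 1):
            for j in range(n_theta):
                j2 = (j + 1) % n_theta
                p00 = i * n_theta + j
                p01 = i * n_theta + j2
                p10 = (i + 1) * n_theta + j
                p11 = (i + 1) * n_theta + j2
                faces.append([p00, p01, p11])
                faces.append([p00, p11, p10])
        faces = np.array(faces)
        # orient every face outward: flip windings whose normal points
        # against the radial direction at the face centroid
        tri = verts[faces]
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        centroids = tri.mean(axis=1) - self.center
        radial = centroids - np.outer(centroids @ self.axis, self.axis)
        inward = np.einsum("ij,ij->i", normals, radial) < 0
        faces[inward] = faces[inward][:, ::-1]
        return trimesh.Trimesh(vertices=verts, faces=faces, process=False)

    def as_mesh_model(self, n_theta: int = 64, n_z: int = 16) -> "PedicleModel":
        """A mesh-representation copy of a parametric model (for cross-checks)."""
        return PedicleModel(
            center=self.center,
            axis=self.axis,
            medial=self.medial,
            superior=self.superior,
            half_length=self.half_length,
            representation="mesh",
            mesh=self.to_mesh(n_theta, n_z),
            level=self.level,
            side=self.side,
            frame=self.frame,
        )


@dataclass(frozen=True)
class VertebralBody:
    """Axis-aligned box volume of the vertebral body, in its local triad."""

    center: np.ndarray
    lateral: np.ndarray
    anterior: np.ndarray
    superior: np.ndarray
    half_extents: tuple  # (half width, half depth, half height) in mm

    def __post_init__(self):
        for name in ("center", "lateral", "anterior", "superior"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))

    def contains(self, point) -> bool:
        q = np.asarray(point, dtype=float).reshape(3) - self.center
        coords = np.abs([q @ self.lateral, q @ self.anterior, q @ self.superior])
        return bool(np.all(coords <= np.asarray(self.half_extents)))


@dataclass(frozen=True)
class WallDistanceResult:
    """Signed wall distance of one screw axis against one pedicle model."""

    dpw: float
    location: Point3  # minimizing point on the screw axis
    wall_point: Point3  # nearest point on the pedicle wall
    breach: bool
    depth: float  # max(0, R - dpw)
    direction: str  # medial | lateral | superior | inferior | anterior | none
    traverses: bool = True  # False when the axis misses the longitudinal slab


def _sector(x_med: float, y_sup: float) -> str:
    """90-degree sector of the cross-section containing (x_med, y_sup)."""
    if abs(x_med) >= abs(y_sup):
        return "medial" if x_med >= 0 else "lateral"
    return "superior" if y_sup >= 0 else "inferior"


def _mesh_signed(points: np.ndarray, model: PedicleModel):
    from .meshdist import closest_on_mesh

    closest, dist, tri = closest_on_mesh(points, model.mesh)
    normals = model.mesh.face_normals[tri]
    inside = np.einsum("ij,ij->i", points - closest, normals) < 0
    return np.where(inside, dist, -dist), closest


def pedicle_wall_distance(
    axis: ScrewAxis,
    model: PedicleModel,
    station_step: float = 0.1,
    slab_margin: float = 0.0,
) -> WallDistanceResult:
    """Minimal signed distance from the screw axis to the pedicle wall.

    Stations along the axis are restricted to the pedicle's longitudinal
    slab (``|projection on tube axis| <= half_length - slab_margin``),
    sampled every ``station_step`` mm and locally refined.  The breach flag
    uses the screw radius carried by ``axis``.

    When the axis does not traverse the slab the result is evaluated at the
    station nearest the slab and flagged (``traverses=False``,
    ``direction="none"``).
    """
    if axis.frame != model.frame:
        raise PedscrewError(f"axis frame {axis.frame!r} != model frame {model.frame!r}")
    anchor = axis.anchor.array
    d = axis.direction.array
    w = model.axis
    h = model.half_length - slab_margin
    q0 = float((anchor - model.center) @ w)
    qd = float(d @ w)

    traverses = True
    if abs(qd) < 1e-9:
        if abs(q0) <= h:
            t_lo, t_hi = 0.0, axis.length
        else:
            traverses = False
            t_lo = t_hi = float(-(anchor - model.center) @ d)  # station nearest tube center
    else:
        ta, tb = (-h - q0) / qd, (h - q0) / qd
        t_lo, t_hi = min(ta, tb), max(ta, tb)

    n = max(2, int(np.ceil((t_hi - t_lo) / station_step)) + 1)
    ts = np.linspace(t_lo, t_hi, n)
    pts = anchor[None, :] + ts[:, None] * d[None, :]

    if model.representation == "parametric":
        xm = (pts - model.center) @ model.medial
        ys = (pts - model.center) @ model.superior

        def signed_at(t):
            p = anchor + t * d
            x = float((p - model.center) @ model.medial)
            y = float((p - model.center) @ model.superior)
            sd, px, py = ellipse_signed_distance(x, y, model.a, model.b)
            return float(sd[0]), float(px[0]), float(py[0])

        sd, _, _ = ellipse_signed_distance(xm, ys, model.a, model.b)
        i = int(np.argmin(sd))
        t_best = float(ts[i])
        if traverses and n > 2:
            lo = max(t_lo, t_best - station_step)
            hi = min(t_hi, t_best + station_step)
            res = minimize_scalar(
                lambda t: signed_at(t)[0], bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            if res.fun < sd[i]:
                t_best = float(res.x)
        dpw, px, py = signed_at(t_best)
        p_best = anchor + t_best * d
        z = float((p_best - model.center) @ w)
        wall = model.center + px * model.medial + py * model.superior + z * w
        x_med, y_sup = px, py
    else:
        sd, closest = _mesh_signed(pts, model)
        i = int(np.argmin(sd))
        t_best = float(ts[i])
        if traverses and n > 2:  # refine on a finer local grid
            lo = max(t_lo, t_best - station_step)
            hi = min(t_hi, t_best + station_step)
            tf = np.linspace(lo, hi, 41)
            pf = anchor[None, :] + tf[:, None] * d[None, :]
            sf, cf = _mesh_signed(pf, model)
            j = int(np.argmin(sf))
            if sf[j] < sd[i]:
                t_best, dpw, wall = float(tf[j]), float(sf[j]), cf[j]
            else:
                dpw, wall = float(sd[i]), closest[i]
        else:
            dpw, wall = float(sd[i]), closest[i]
        p_best = anchor + t_best * d
        rel = wall - model.center
        x_med = float(rel @ model.medial)
        y_sup = float(rel @ model.superior)

    R = axis.radius
    breach = bool(dpw < R)
    depth = float(max(0.0, R - dpw))
    direction = "none" if not traverses else _sector(x_med, y_sup)
    return WallDistanceResult(
        dpw=float(dpw),
        location=Point3.from_array(p_best, model.frame),
        wall_point=Point3.from_array(wall, model.frame),
        breach=breach,
        depth=depth,
        direction=direction,
        traverses=traverses,
    )


def classify_breach(dpw: float, R: float) -> str:
    """Four-regime classification of a signed wall distance against radius R.

    ``no_breach`` (dpw >= R), ``breach_inside`` (0 <= dpw < R),
    ``breach_outside`` (dpw < 0, |dpw| < R), ``fully_outside``
    (dpw < 0, |dpw| >= R).
    """
    if hasattr(dpw, "dpw"):  # accept a WallDistanceResult
        dpw = dpw.dpw
    if dpw >= R:
        return "no_breach"
    if dpw >= 0:
        return "breach_inside"
    if -dpw < R:
        return "breach_outside"
    return "fully_outside"


def grade_gertzbein(
    result: WallDistanceResult, R: float, boundaries: tuple = (2.0, 4.0)
) -> str:
    """Gertzbein grade from a wall-distance result.

    No breach -> "0"; medial breach graded by depth = R - dpw with cut
    points at ``boundaries`` (lower bounds inclusive: depth 2.0 -> "2",
    depth 4.0 -> "3"); lateral breach -> "4" regardless of depth; breach
    directions with no grade in the scheme -> "/".
    """
    if not result.breach:
        return "0"
    b1, b2 = boundaries
    if result.direction == "medial":
        depth = R - result.dpw
        if depth < b1:
            return "1"
        if depth < b2:
            return "2"
        return "3"
    if result.direction == "lateral":
        return "4"
    return NO_GRADE


def grade_heary(
    result: WallDistanceResult,
    tip: Point3 | None = None,
    body: VertebralBody | None = None,
    R: float = 2.5,
    canal_threshold: float = 4.0,
) -> str:
    """Heary grade from a wall-distance result, the screw tip and the body volume.

    I when no breach; lateral violations are II when the tip stays inside
    the vertebral body and III when it exits anteriorly/laterally; medial or
    inferior breaches are IV, escalated to V when the medial depth exceeds
    ``canal_threshold`` (a severity convention — canal endangerment is not
    geometrically decidable); superior breaches have no counterpart -> "/".
    """
    if not result.breach:
        return "I"
    if result.direction == "medial":
        return "V" if (R - result.dpw) > canal_threshold else "IV"
    if result.direction == "inferior":
        return "IV"
    if result.direction == "superior":
        return NO_GRADE
    if result.direction in ("lateral", "anterior"):
        if tip is None or body is None:
            raise PedscrewError(
                "Heary grades II/III need the screw tip and a vertebral body volume"
            )
        return "II" if body.contains(tip.array) else "III"
    raise DegenerateGeometryError(f"cannot grade breach direction {result.direction!r}")
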