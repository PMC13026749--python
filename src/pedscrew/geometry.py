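"""Reference frames, rigid transforms, and trajectory accuracy metrics.

A planned screw trajectory is defined by two independent points stated in the
planning frame ``R0``: an entry point ``Pe`` on the posterior cortex and a
target point ``Pt`` inside the vertebral body.  The inserted screw is
represented by its fitted axis (an anchor point, a unit direction oriented
entry-to-tip, a length and a radius).  Placement accuracy is summarised by
four scalar parameters:

``ee``
    entry point error, the minimal distance (mm) from the planned entry point
    to the inserted screw axis;
``et``
    target point error, same for the planned target point;
``e_alpha``
    orientation angle error, the angle (degrees, in [0, 180]) between the
    planned direction and the screw axis direction;
``C``
    coaxiality, the maximum distance (mm) between the inserted screw axis and
    the planned trajectory over the planned segment ``[Pe, Pt]``.  Because the
    squared point-to-line distance is convex along a segment, the maximum is
    attained at an endpoint, hence ``C = max(ee, et)`` exactly.

All four metrics are invariant under a common rigid transform of plan and
axis.  Coordinates carry a frame tag (``"R0"``, ``"RL"``, ``"RN"``,
``"CMM"``); operations refuse to mix frames silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateGeometryError, FrameMismatchError

__all__ = [
    "Point3",
    "Direction3",
    "TrajectoryPlan",
    "ScrewAxis",
    "RigidTransform",
    "VertebraFrame",
    "InsertionErrors",
    "point_line_distance",
    "entry_point_error",
    "target_point_error",
    "orientation_angle_error",
    "coaxiality",
    "insertion_errors",
    "build_vertebra_frame",
    "apply_transform",
]

_ORTHO_TOL = 1e-9


def _vec(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError("coordinates must be finite")
    return a


def _check_frames(*tags: str) -> None:
    if len(set(tags)) > 1:
        raise FrameMismatchError(f"inconsistent coordinate frames: {tags}")


@dataclass(frozen=True)
class Point3:
    """A point in mm, tagged with the coordinate frame it is stated in."""

    x: float
    y: float
    z: float
    frame: str = "R0"

    def __post_init__(self):
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("coordinates must be finite")

    @classmethod
    def from_array(cls, a, frame: str = "R0") -> "Point3":
        a = _vec(a)
        return cls(float(a[0]), float(a[1]), float(a[2]), frame)

    @property
    def array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class Direction3:
    """A unit direction vector (dimensionless, norm 1 within 1e-9)."""

    ux: float
    uy: float
    uz: float

    def __post_init__(self):
        n = float(np.linalg.norm([self.ux, self.uy, self.uz]))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit length, got norm {n}")

    @classmethod
    def from_array(cls, a) -> "Direction3":
        a = _vec(a)
        n = np.linalg.norm(a)
        if n < 1e-12:
            raise DegenerateGeometryError("cannot normalise a zero vector")
        a = a / n
        return cls(float(a[0]), float(a[1]), float(a[2]))

    @property
    def array(self) -> np.ndarray:
        return np.array([self.ux, self.uy, self.uz], dtype=float)


@dataclass(frozen=True)
class TrajectoryPlan:
    """Planned trajectory: entry point ``Pe`` and target point ``Pt``.

    The planned direction is the unit vector from ``Pe`` to ``Pt``; the
    planned length is their separation (mm).
    """

    entry: Point3
    target: Point3

    def __post_init__(self):
        _check_frames(self.entry.frame, self.target.frame)
        if np.linalg.norm(self.target.array - self.entry.array) < 1e-12:
            raise DegenerateGeometryError("entry and target points coincide")

    @property
    def frame(self) -> str:
        return self.entry.frame

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.target.array - self.entry.array))

    @property
    def direction(self) -> Direction3:
        return Direction3.from_array(self.target.array - self.entry.array)


@dataclass(frozen=True)
class ScrewAxis:
    """Oriented axis of an inserted screw (the carrier of frame ``RN``).

    ``anchor`` is an entry-side point on the axis; ``direction`` is oriented
    entry-to-tip; ``radius`` is the screw radius R (mm).
    """

    anchor: Point3
    direction: Direction3
    length: float = 45.0
    radius: float = 2.5

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    @property
    def frame(self) -> str:
        return self.anchor.frame

    def point_at(self, t: float) -> np.ndarray:
        """Point on the axis at signed abscissa ``t`` (mm) from the anchor."""
        return self.anchor.array + t * self.direction.array

    @property
    def tip(self) -> Point3:
        return Point3.from_array(self.point_at(self.length), self.frame)


class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation orthonormal, det +1)."""

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation, translation):
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        t = np.asarray(translation, dtype=float).reshape(3)
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-7:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-7:
            raise ValueError("rotation must be proper (det +1)")
        self.rotation = R
        self.translation = t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 3) or (3,) array of coordinates."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Map direction vectors (rotation only)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (other applied first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def __repr__(self):  # pragma: no cover
        return f"RigidTransform(t={self.translation}, angle={self.rotation_angle_deg():.3f}°)"


@dataclass(frozen=True)
class VertebraFrame:
    """Vertebra-fixed anatomical frame ``RL`` built from three landmarks.

    Axes are an orthonormal right-handed triad (lateral, anterior, superior);
    ``side`` records which pedicle the frame contextualises, which fixes the
    medial direction (towards the midline).
    """

    origin: Point3
    lateral: Direction3
    anterior: Direction3
    superior: Direction3
    side: str = "left"

    def __post_init__(self):
        L, A, S = self.lateral.array, self.anterior.array, self.superior.array
        g = np.abs([L @ A, L @ S, A @ S])
        if np.max(g) > 1e-9:
            raise ValueError("frame axes must be pairwise orthogonal")
        if np.linalg.norm(np.cross(L, A) - S) > 1e-9:
            raise ValueError("frame must be right-handed (lateral x anterior = superior)")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def medial_direction(self) -> np.ndarray:
        """Unit vector pointing from the pedicle towards the midline."""
        return self.lateral.array if self.side == "left" else -self.lateral.array


@dataclass(frozen=True)
class InsertionErrors:
    """The four trajectory accuracy parameters of one inserted screw."""

    ee: float
    et: float
    e_alpha: float
    coaxiality: float

    def __post_init__(self):
        if self.ee < 0 or self.et < 0:
            raise ValueError("distance errors must be >= 0")
        if not 0.0 <= self.e_alpha <= 180.0:
            raise ValueError("orientation error must lie in [0, 180] degrees")
        if self.coaxiality < max(self.ee, self.et) - 1e-9:
            raise ValueError("coaxiality cannot be smaller than max(ee, et)")


# ---------------------------------------------------------------------------
# operations


def point_line_distance(p: Point3, axis: ScrewAxis) -> float:
    """Minimal Euclidean distance (mm) from ``p`` to the infinite line of ``axis``."""
    _check_frames(p.frame, axis.frame)
    d = axis.direction.array
    return float(np.linalg.norm(np.cross(p.array - axis.anchor.array, d)))


def _planned_axis(plan: TrajectoryPlan) -> ScrewAxis:
    return ScrewAxis(plan.entry, plan.direction, length=plan.length)


def entry_point_error(
    plan: TrajectoryPlan, actual: ScrewAxis, error_direction: str = "plan_to_actual"
) -> float:
    """Entry point error ``ee`` (mm).

    Default convention measures from the planned entry point to the fitted
    screw axis; ``error_direction="actual_to_plan"`` measures from the actual
    screw entry point (the axis anchor) to the planned axis instead.
    """
    if error_direction == "plan_to_actual":
        return point_line_distance(plan.entry, actual)
    if error_direction == "actual_to_plan":
        return point_line_distance(actual.anchor, _planned_axis(plan))
    raise ValueError(f"unknown error_direction {error_direction!r}")


def target_point_error(
    plan: TrajectoryPlan, actual: ScrewAxis, error_direction: str = "plan_to_actual"
) -> float:
    """Target point error ``et`` (mm), conventions as for :func:`entry_point_error`."""
    if error_direction == "plan_to_actual":
        return point_line_distance(plan.target, actual)
    if error_direction == "actual_to_plan":
        return point_line_distance(actual.tip, _planned_axis(plan))
    raise ValueError(f"unknown error_direction {error_direction!r}")


def orientation_angle_error(plan: TrajectoryPlan, actual: ScrewAxis) -> float:
    """Angle (degrees, [0, 180]) between the planned direction and the screw axis.

    The axis direction must be oriented entry-to-tip upstream (see
    :func:`pedscrew.cylinder.orient_axis_toward_tip`); no folding to [0, 90]
    is applied.  Invariant to translating either input.
    """
    _check_frames(plan.frame, actual.frame)
    c = float(np.clip(plan.direction.array @ actual.direction.array, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def coaxiality(
    plan: TrajectoryPlan,
    actual: ScrewAxis,
    error_direction: str = "plan_to_actual",
    report_diameter: bool = False,
) -> float:
    """Coaxiality ``C`` (mm): maximum axis-to-trajectory distance over the segment.

    Evaluated over the planned segment [Pe, Pt] (default convention) or over
    the measured screw segment (``actual_to_plan``).  The squared distance
    from a line to a point moving along a segment is a convex quadratic, so
    the maximum sits at an endpoint and ``C = max(ee, et)``.  With
    ``report_diameter=True`` the doubled (tolerance-zone diameter) value is
    returned instead of the maximum distance itself.
    """
    c = max(
        entry_point_error(plan, actual, error_direction),
        target_point_error(plan, actual, error_direction),
    )
    return 2.0 * c if report_diameter else c


def insertion_errors(
    plan: TrajectoryPlan, actual: ScrewAxis, error_direction: str = "plan_to_actual"
) -> InsertionErrors:
    """Compute all four accuracy parameters for one screw."""
    ee = entry_point_error(plan, actual, error_direction)
    et = target_point_error(plan, actual, error_direction)
    ea = orientation_angle_error(plan, actual)
    return InsertionErrors(ee=ee, et=et, e_alpha=ea, coaxiality=max(ee, et))


def build_vertebra_frame(
    spinous: Point3,
    left_tp: Point3,
    right_tp: Point3,
    side: str = "left",
    superior_hint=(0.0, 0.0, 1.0),
) -> VertebraFrame:
    """Anatomical frame ``RL`` from the spinous process and transverse processes.

    The lateral axis runs left-to-right along the transverse processes; the
    superior axis is the landmark-plane normal oriented along
    ``superior_hint`` (cranially); the anterior axis completes the
    right-handed triad.  Origin at the midpoint of the transverse processes.
    """
    _check_frames(spinous.frame, left_tp.frame, right_tp.frame)
    s, lt, rt = spinous.array, left_tp.array, right_tp.array
    lat = rt - lt
    if np.linalg.norm(lat) < 1e-9:
        raise DegenerateGeometryError("transverse process landmarks coincide")
    lat = lat / np.linalg.norm(lat)
    mid = (lt + rt) / 2.0
    v = s - mid
    n = np.cross(lat, v)
    if np.linalg.norm(n) < 1e-9:
        raise DegenerateGeometryError("landmarks are collinear")
    sup = n / np.linalg.norm(n)
    if sup @ _vec(superior_hint) < 0:
        sup = -sup
    ant = np.cross(sup, lat)
    return VertebraFrame(
        origin=Point3.from_array(mid, spinous.frame),
        lateral=Direction3.from_array(lat),
        anterior=Direction3.from_array(ant),
        superior=Direction3.from_array(sup),
        side=side,
    )


def apply_transform(T: RigidTransform, obj, new_frame: str | None = None):
    """Apply a rigid transform to a geometric object, returning the same type.

    Points map as x -> R x + t, directions by the rotation only; lengths and
    radii are unchanged.  ``new_frame`` relabels the frame tag of the result
    (defaults to keeping the input tag).
    """
    if isinstance(obj, Point3):
        return Point3.from_array(T.apply(obj.array), new_frame or obj.frame)
    if isinstance(obj, Direction3):
        return Direction3.from_array(T.rotate(obj.array))
    if isinstance(obj, TrajectoryPlan):
        return TrajectoryPlan(
            apply_transform(T, obj.entry, new_frame),
            apply_transform(T, obj.target, new_frame),
        )
    if isinstance(obj, ScrewAxis):
        return ScrewAxis(
            apply_transform(T, obj.anchor, new_frame),
            apply_transform(T, obj.direction),
            length=obj.length,
            radius=obj.radius,
        )
    if isinstance(obj, VertebraFrame):
        return VertebraFrame(
            origin=apply_transform(T, obj.origin, new_frame),
            lateral=apply_transform(T, obj.lateral),
            anterior=apply_transform(T, obj.anterior),
            superior=apply_transform(T, obj.superior),
            side=obj.side,
        )
    if hasattr(obj, "points") and hasattr(obj, "frame"):  # PointCloud, duck-typed
        return replace(obj, points=T.apply(obj.points), frame=new_frame or obj.frame)
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")
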