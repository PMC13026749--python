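"""Trajectory accuracy parameters: oracles, examples and invariances."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from pedscrew import (
    Direction3,
    FrameMismatchError,
    Point3,
    RigidTransform,
    ScrewAxis,
    TrajectoryPlan,
    apply_transform,
    build_vertebra_frame,
    coaxiality,
    entry_point_error,
    insertion_errors,
    orientation_angle_error,
    point_line_distance,
    target_point_error,
)
from pedscrew.errors import DegenerateGeometryError

from .conftest import random_rigid_transform


def _axis(anchor, direction, **kw):
    return ScrewAxis(Point3.from_array(anchor), Direction3.from_array(direction), **kw)


def _plan(pe, pt):
    return TrajectoryPlan(Point3.from_array(pe), Point3.from_array(pt))


def _brute_point_line(p, axis):
    """Independent oracle: scalar minimisation of |p - (a + t d)| over t."""
    a, d = axis.anchor.array, axis.direction.array
    res = minimize_scalar(lambda t: np.linalg.norm(p - (a + t * d)), bounds=(-1e4, 1e4),
                          method="bounded", options={"xatol": 1e-10})
    return res.fun


class TestPointLineDistance:
    @pytest.mark.parametrize(
        "p, anchor, direction, expected",
        [
            ((0, 2, 0), (0, 0, 0), (1, 0, 0), 2.0),
            ((3, 0, 0), (0, 0, 0), (1, 0, 0), 0.0),  # point on the axis
            ((0, 0, 0), (1, 1, 5), (0, 0, 1), np.sqrt(2.0)),
        ],
    )
    def test_examples(self, p, anchor, direction, expected):
        d = point_line_distance(Point3.from_array(p), _axis(anchor, direction))
        assert d == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_minimisation(self, rng):
        for _ in range(30):
            p = rng.uniform(-20, 20, 3)
            ax = _axis(rng.uniform(-20, 20, 3), rng.normal(size=3))
            assert point_line_distance(Point3.from_array(p), ax) == pytest.approx(
                _brute_point_line(p, ax), abs=1e-6
            )

    def test_frame_mismatch_is_an_error(self):
        with pytest.raises(FrameMismatchError):
            point_line_distance(Point3(0, 0, 0, "CMM"), _axis((0, 0, 0), (1, 0, 0)))


class TestEntryTargetErrors:
    def test_coincident_trajectory_zero(self):
        plan = _plan((0, 0, 0), (40, 0, 0))
        ax = _axis((0, 0, 0), (1, 0, 0))
        assert entry_point_error(plan, ax) == 0.0
        assert target_point_error(plan, ax) == 0.0

    def test_pure_entry_offset(self):
        plan = _plan((0, 0, 0), (40, 0, 0))
        ax = _axis((0, 3.4, 0), (1, 0, 0))
        assert entry_point_error(plan, ax) == pytest.approx(3.4)

    def test_target_error_from_angular_deviation(self):
        # axis through the planned entry, tilted in-plane with sin(theta)=0.1
        plan = _plan((0, 0, 0), (40, 0, 0))
        s = 0.1
        ax = _axis((0, 0, 0), (np.sqrt(1 - s * s), s, 0))
        assert target_point_error(plan, ax) == pytest.approx(40 * s, abs=1e-9)

    def test_parallel_translation_symmetry(self, rng):
        plan = _plan((0, 0, 0), (40, 0, 0))
        for _ in range(10):
            off = rng.uniform(-5, 5, 2)
            ax = _axis((0, off[0], off[1]), (1, 0, 0))
            d = np.hypot(*off)
            assert entry_point_error(plan, ax) == pytest.approx(d)
            assert target_point_error(plan, ax) == pytest.approx(d)
            assert coaxiality(plan, ax) == pytest.approx(d)

    def test_actual_to_plan_convention(self):
        plan = _plan((0, 0, 0), (40, 0, 0))
        ax = _axis((0, 2, 0), (1, 0, 0), length=40)
        # distances now measured from the actual screw points to the planned axis
        assert entry_point_error(plan, ax, "actual_to_plan") == pytest.approx(2.0)
        assert target_point_error(plan, ax, "actual_to_plan") == pytest.approx(2.0)


class TestOrientationAngle:
    @pytest.mark.parametrize(
        "direction, expected",
        [((1, 0, 0), 0.0), ((0, 1, 0), 90.0), ((1, 1, 0), 45.0), ((-1, 0, 0), 180.0)],
    )
    def test_examples(self, direction, expected):
        plan = _plan((0, 0, 0), (40, 0, 0))
        ax = _axis((5, 5, 5), direction)
        assert orientation_angle_error(plan, ax) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_translation_invariance(self, rng):
        for _ in range(20):
            pe, d1 = rng.uniform(-10, 10, 3), rng.normal(size=3)
            plan = _plan(pe, pe + 30 * d1 / np.linalg.norm(d1))
            ax = _axis(rng.uniform(-10, 10, 3), rng.normal(size=3), length=30)
            a1 = orientation_angle_error(plan, ax)
            # swap roles: the angle between the two directions is symmetric
            plan2 = TrajectoryPlan(ax.anchor, ax.tip)
            ax2 = ScrewAxis(plan.entry, plan.direction, length=plan.length)
            assert a1 == pytest.approx(orientation_angle_error(plan2, ax2), abs=1e-9)


class TestCoaxiality:
    def test_equals_segment_maximum_oracle(self, rng):
        """C = max over the planned segment of the point-to-axis distance."""
        for _ in range(20):
            pe, d = rng.uniform(-10, 10, 3), rng.normal(size=3)
            plan = _plan(pe, pe + rng.uniform(20, 50) * d / np.linalg.norm(d))
            ax = _axis(rng.uniform(-10, 10, 3), rng.normal(size=3))
            ts = np.linspace(0, 1, 10_001)
            seg = plan.entry.array[None] + ts[:, None] * (
                plan.target.array - plan.entry.array
            )[None]
            dd = np.linalg.norm(
                np.cross(seg - ax.anchor.array, ax.direction.array), axis=1
            )
            assert coaxiality(plan, ax) == pytest.approx(dd.max(), abs=1e-6)

    def test_max_of_endpoint_errors(self, rng):
        for _ in range(200):
            pe, d = rng.uniform(-10, 10, 3), rng.normal(size=3)
            plan = _plan(pe, pe + 40 * d / np.linalg.norm(d))
            ax = _axis(rng.uniform(-10, 10, 3), rng.normal(size=3))
            e = insertion_errors(plan, ax)
            assert e.coaxiality == max(e.ee, e.et)

    def test_report_diameter_doubles(self):
        plan = _plan((0, 0, 0), (40, 0, 0))
        ax = _axis((0, 3, 0), (1, 0, 0))
        assert coaxiality(plan, ax, report_diameter=True) == pytest.approx(6.0)


class TestRigidInvariance:
    def test_metrics_invariant_under_common_transform(self, rng):
        plan = _plan((1, 2, 3), (35, 8, -4))
        ax = _axis((2, 1, 4), (0.95, 0.2, 0.24), length=45, radius=2.5)
        e0 = insertion_errors(plan, ax)
        for _ in range(50):
            T = random_rigid_transform(rng)
            e1 = insertion_errors(apply_transform(T, plan), apply_transform(T, ax))
            assert e1.ee == pytest.approx(e0.ee, abs=1e-9)
            assert e1.et == pytest.approx(e0.et, abs=1e-9)
            assert e1.e_alpha == pytest.approx(e0.e_alpha, abs=1e-9)
            assert e1.coaxiality == pytest.approx(e0.coaxiality, abs=1e-9)


class TestVertebraFrame:
    def test_canonical_landmarks(self):
        f = build_vertebra_frame(
            Point3(0, -30, 0), Point3(-25, 0, 0), Point3(25, 0, 0), side="left"
        )
        assert f.lateral.array == pytest.approx([1, 0, 0])
        assert abs(f.lateral.array @ f.superior.array) < 1e-9
        assert np.cross(f.lateral.array, f.anterior.array) == pytest.approx(
            f.superior.array, abs=1e-9
        )
        assert f.medial_direction() == pytest.approx([1, 0, 0])

    def test_rotation_equivariance(self, rng):
        pts = [Point3(0, -30, 0), Point3(-25, 0, 0), Point3(25, 0, 0)]
        f0 = build_vertebra_frame(*pts)
        T = random_rigid_transform(rng)
        moved = [apply_transform(T, p) for p in pts]
        f1 = build_vertebra_frame(*moved, superior_hint=T.rotate([0, 0, 1]))
        assert f1.lateral.array == pytest.approx(T.rotate(f0.lateral.array), abs=1e-9)
        assert f1.superior.array == pytest.approx(T.rotate(f0.superior.array), abs=1e-9)

    def test_collinear_landmarks_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            build_vertebra_frame(Point3(0, 0, 0), Point3(1, 0, 0), Point3(2, 0, 0))


class TestApplyTransform:
    def test_identity_and_translation(self):
        p = Point3(0, 0, 0)
        assert apply_transform(RigidTransform.identity(), p).array == pytest.approx([0, 0, 0])
        T = RigidTransform(np.eye(3), [1, 2, 3])
        assert apply_transform(T, p).array == pytest.approx([1, 2, 3])

    def test_lengths_and_radii_preserved(self, rng):
        ax = _axis((1, 2, 3), (0, 0, 1), length=45, radius=2.5)
        T = random_rigid_transform(rng)
        out = apply_transform(T, ax)
        assert out.length == ax.length and out.radius == ax.radius

    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
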