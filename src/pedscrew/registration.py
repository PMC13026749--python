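"""Rigid registration of digitized vertebral surfaces to the planning model.

The digitized surface cloud lives in the CMM frame; the preoperative model
lives in the planning frame R0.  Registration recovers the rigid transform
R0 <- CMM so fitted screw axes can be expressed in R0.  The workhorse is a
trimmed point-to-point iterative closest point (ICP) loop: alternate nearest
neighbour correspondence (nearest mesh surface point when the target is a
mesh) and a closed-form Kabsch alignment on the best (1 - trim) fraction of
correspondences.  Coarse initialisation normally comes from a Kabsch fit of
the three digitized anatomical landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cylinder import PointCloud
from .errors import DegenerateGeometryError
from .geometry import RigidTransform

__all__ = ["RegistrationResult", "kabsch_align", "icp_register"]


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms: float
    n_iterations: int
    converged: bool
    inlier_fraction: float
    rms_history: tuple = field(default=())


def _points_of(x) -> np.ndarray:
    if isinstance(x, PointCloud):
        return x.points
    return np.asarray(x, dtype=float)


def kabsch_align(source, target) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``source`` onto ``target``.

    Point correspondence is by index; reflections are suppressed (det +1).
    Raises :class:`DegenerateGeometryError` for < 3 points or collinear
    geometry (rank-deficient cross-covariance).
    """
    s = _points_of(source)
    t = _points_of(target)
    if s.shape != t.shape or s.shape[0] < 3:
        raise DegenerateGeometryError("need matching clouds of at least 3 points")
    cs, ct = s.mean(axis=0), t.mean(axis=0)
    H = (s - cs).T @ (t - ct)
    if np.linalg.matrix_rank(H, tol=1e-9 * max(np.linalg.norm(H), 1e-30)) < 2:
        raise DegenerateGeometryError("degenerate (collinear) geometry in Kabsch alignment")
    rot, _ = Rotation.align_vectors(t - ct, s - cs)  # proper rotation by construction
    R = rot.as_matrix()
    return RigidTransform(R, ct - R @ cs)


class _CloudTarget:
    def __init__(self, points: np.ndarray):
        self._tree = cKDTree(points)
        self._points = points

    def nearest(self, q: np.ndarray):
        d, i = self._tree.query(q)
        return self._points[i], d


class _MeshTarget:
    def __init__(self, mesh):
        self._mesh = mesh

    def nearest(self, q: np.ndarray):
        from .meshdist import closest_on_mesh

        closest, d, _ = closest_on_mesh(q, self._mesh)
        return closest, d


def icp_register(
    source,
    target,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    trim_fraction: float = 0.1,
) -> RegistrationResult:
    """Trimmed point-to-point ICP of ``source`` onto ``target``.

    Parameters
    ----------
    source:
        Digitized cloud ((n, 3) array or :class:`PointCloud`), n >= 10.
    target:
        Reference model: an (m, 3) array / :class:`PointCloud` (nearest
        neighbour correspondence) or a ``trimesh.Trimesh`` (nearest surface
        point correspondence).
    init:
        Coarse initial transform (identity if omitted); use
        :func:`kabsch_align` on digitized landmarks when available.
    trim_fraction:
        Worst fraction of correspondences dropped at each iteration, which
        tolerates partial overlap of the digitized patch.

    Returns a :class:`RegistrationResult`; ``converged`` is False when the
    RMS change never fell below ``tol`` (the result is still returned).
    """
    s = _points_of(source)
    if s.shape[0] < 10:
        raise DegenerateGeometryError("ICP needs a source cloud of at least 10 points")
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must lie in [0, 1)")
    import trimesh

    if isinstance(target, trimesh.Trimesh):
        tgt = _MeshTarget(target)
    else:
        tp = _points_of(target)
        if tp.shape[0] < 3:
            raise DegenerateGeometryError("target is degenerate")
        tgt = _CloudTarget(tp)

    T = init if init is not None else RigidTransform.identity()
    n_keep = max(3, int(np.ceil((1.0 - trim_fraction) * s.shape[0])))
    rms_prev = np.inf
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = T.apply(s)
        matched, dist = tgt.nearest(moved)
        keep = np.argsort(dist)[:n_keep]
        T = kabsch_align(s[keep], matched[keep])
        moved = T.apply(s[keep])
        rms = float(np.sqrt(np.mean(np.sum((moved - matched[keep]) ** 2, axis=1))))
        history.append(rms)
        if abs(rms_prev - rms) < tol:
            converged = True
            break
        rms_prev = rms
    return RegistrationResult(
        transform=T,
        rms=history[-1],
        n_iterations=it,
        converged=converged,
        inlier_fraction=n_keep / s.shape[0],
        rms_history=tuple(history),
    )
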