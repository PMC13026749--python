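"""Synthetic lumbar phantom, simulated insertions and digitizations.

This module emulates the full bench experiment so every stage of the
measurement chain can be exercised against known ground truth:

* five lumbar vertebrae (L1-L5), each with a left and right pedicle modelled
  as a straight elliptical tube at the isthmus, a box vertebral-body volume,
  a digitizable posterior surface built from primitive solids, and three
  anatomical landmarks (spinous process, left/right transverse processes);
* ten planned trajectories per phantom (one per pedicle, through the tube
  centerline);
* simulated insertions: the planned axis perturbed by a half-normal entry
  offset in a uniformly random transverse direction plus a half-normal
  angular tilt, with per-technique scales calibrated so the large-sample
  mean entry error and mean orientation error match the per-technique
  calibration table (scale = target mean * sqrt(pi/2));
* simulated CMM digitization: probe-centre points on the proximal screw
  (offset outward by the probe radius) and surface points, both expressed in
  a randomly posed CMM frame with isotropic Gaussian noise at the digitizer
  precision;
* the full estimation pipeline (cylinder fit -> landmark + ICP registration
  -> accuracy metrics -> wall distance -> grading) and a factorial virtual
  study of N = techniques x groups x operators x screws insertions.

Everything is deterministic per seed, with independent substreams per screw.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .agreement import CrossTab, mann_whitney_u, spearman_rho
from .breach import PedicleModel, VertebralBody, WallDistanceResult, grade_gertzbein, grade_heary, pedicle_wall_distance
from .config import TECHNIQUE_CALIBRATION, AnalysisConfig
from .cylinder import PointCloud, fit_cylinder_axis, orient_axis_toward_tip
from .geometry import (
    Direction3,
    InsertionErrors,
    Point3,
    RigidTransform,
    ScrewAxis,
    TrajectoryPlan,
    apply_transform,
    insertion_errors,
)
from .registration import icp_register, kabsch_align

__all__ = [
    "PhantomSpec",
    "Vertebra",
    "Phantom",
    "OperatorProfile",
    "technique_profile",
    "SimulatedInsertion",
    "StudyDesign",
    "StudyResult",
    "generate_phantom",
    "plan_trajectories",
    "simulate_insertion",
    "simulate_digitization",
    "estimate_insertion",
    "run_virtual_study",
]

LEVELS = ("L1", "L2", "L3", "L4", "L5")


@dataclass(frozen=True)
class PhantomSpec:
    """Dimensions of the synthetic lumbar phantom (all mm / degrees).

    Pedicle semi-axes grow from L1 to L5 as lumbar pedicles do; the values
    are chosen so that, under the calibrated insertion-error magnitudes, the
    achieved wall distances average ~4-5 mm with a breach prevalence of
    roughly one screw in ten — the regime the measurement chain is meant to
    operate in.
    """

    levels: tuple = LEVELS
    pedicle_a: tuple = (7.5, 8.0, 8.5, 9.5, 10.5)  # medial-lateral semi-axis
    pedicle_b: tuple = (8.0, 8.0, 8.5, 9.0, 9.5)  # cranio-caudal semi-axis
    pedicle_length: float = 12.0
    pedicle_x: float = 13.0  # isthmus centre lateral offset
    transverse_angle: tuple = (10.0, 12.0, 15.0, 18.0, 22.0)  # medial convergence, deg
    body_half_extents: tuple = (21.0, 15.0, 13.0)  # half width / depth / height
    entry_offset: float = 4.0  # planned entry behind the pedicle mouth
    plan_length: float = 40.0  # planned entry-to-target distance
    level_spacing: float = 35.0
    n_surface_samples: int = 4000
    seed: int = 0

    def __post_init__(self):
        dims = self.pedicle_a + self.pedicle_b + (
            self.pedicle_length, self.plan_length, self.level_spacing,
        ) + self.body_half_extents
        if min(dims) <= 0:
            raise ValueError("phantom dimensions must be positive")


@dataclass(frozen=True)
class Vertebra:
    level: str
    origin: np.ndarray  # level origin in R0
    landmarks: dict  # name -> Point3 in R0
    surface_mesh: object
    surface_samples: np.ndarray  # dense (m, 3) surface cloud in R0
    pedicles: dict  # side -> PedicleModel
    body: VertebralBody


@dataclass(frozen=True)
class Phantom:
    spec: PhantomSpec
    vertebrae: tuple


def _boxes_for_level(origin: np.ndarray):
    """Primitive solids of one vertebra's digitizable surface."""
    import trimesh

    parts = [
        ((42.0, 30.0, 26.0), (0.0, 15.0, 0.0)),  # body
        ((10.0, 16.0, 10.0), (0.0, -26.0, -2.0)),  # spinous process
        ((16.0, 8.0, 8.0), (-30.0, -8.0, 0.0)),  # left transverse process
        ((16.0, 8.0, 8.0), (30.0, -8.0, 0.0)),  # right transverse process
        ((34.0, 8.0, 14.0), (0.0, -16.0, 0.0)),  # laminae
    ]
    meshes = []
    for extents, centre in parts:
        box = trimesh.creation.box(extents=extents)
        box.apply_translation(np.asarray(centre) + origin)
        meshes.append(box)
    return trimesh.util.concatenate(meshes)


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the synthetic phantom: meshes, pedicle tubes, landmarks.

    Deterministic for a given spec (surface sampling uses substreams of the
    spec seed).
    """
    import trimesh

    spec = spec or PhantomSpec()
    ss = np.random.SeedSequence([spec.seed, 0x9E3779B9])
    level_seeds = ss.generate_state(len(spec.levels))
    vertebrae = []
    for i, level in enumerate(spec.levels):
        origin = np.array([0.0, 0.0, i * spec.level_spacing])
        mesh = _boxes_for_level(origin)
        samples, _ = trimesh.sample.sample_surface(mesh, spec.n_surface_samples,
                                                   seed=int(level_seeds[i]))
        samples = np.asarray(samples, dtype=float)
        landmarks = {
            "spinous": Point3.from_array(origin + [0.0, -34.0, -2.0], "R0"),
            "left_tp": Point3.from_array(origin + [-38.0, -8.0, 0.0], "R0"),
            "right_tp": Point3.from_array(origin + [38.0, -8.0, 0.0], "R0"),
        }
        body = VertebralBody(
            center=origin + [0.0, 15.0, 0.0],
            lateral=[1.0, 0.0, 0.0],
            anterior=[0.0, 1.0, 0.0],
            superior=[0.0, 0.0, 1.0],
            half_extents=spec.body_half_extents,
        )
        tau = np.radians(spec.transverse_angle[i])
        pedicles = {}
        for side, s in (("left", -1.0), ("right", 1.0)):
            d = np.array([-s * np.sin(tau), np.cos(tau), 0.0])
            centre = origin + np.array([s * spec.pedicle_x, -8.0, 0.0])
            medial = np.array([-s, 0.0, 0.0])
            medial = medial - (medial @ d) * d
            medial /= np.linalg.norm(medial)
            pedicles[side] = PedicleModel(
                center=centre,
                axis=d,
                medial=medial,
                superior=np.array([0.0, 0.0, 1.0]),
                half_length=spec.pedicle_length / 2.0,
                a=spec.pedicle_a[i],
                b=spec.pedicle_b[i],
                level=level,
                side=side,
            )
        vertebrae.append(
            Vertebra(level, origin, landmarks, mesh, samples, pedicles, body)
        )
    return Phantom(spec, tuple(vertebrae))


def plan_trajectories(phantom: Phantom):
    """One planned trajectory per pedicle, through the tube centerline.

    Returns a list of ``(ids, TrajectoryPlan)`` with ids
    ``{"vertebra": ..., "side": ...}``; 10 plans for the default phantom.
    """
    spec = phantom.spec
    out = []
    for v in phantom.vertebrae:
        for side in ("left", "right"):
            ped = v.pedicles[side]
            mouth = ped.center - ped.half_length * ped.axis
            pe = mouth - spec.entry_offset * ped.axis
            pt = pe + spec.plan_length * ped.axis
            plan = TrajectoryPlan(Point3.from_array(pe, "R0"), Point3.from_array(pt, "R0"))
            out.append(({"vertebra": v.level, "side": side}, plan))
    return out


@dataclass(frozen=True)
class OperatorProfile:
    """Error magnitudes of one operator/technique combination.

    ``entry_sd`` and ``angle_sd`` are the scales of the half-normal entry
    offset (mm) and angular tilt (degrees); ``depth_sd`` jitters the
    insertion depth along the axis (mm); ``bias`` is a systematic 3-vector
    offset (mm, zero by default).
    """

    technique: str = "conventional"
    group: str = "senior"
    entry_sd: float = 4.262
    angle_sd: float = 9.902
    depth_sd: float = 1.0
    bias: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if min(self.entry_sd, self.angle_sd, self.depth_sd) < 0:
            raise ValueError("error scales must be >= 0")


# angular-skill multipliers: seniors steer slightly truer trajectories;
# the pooled mean over both groups equals the per-technique calibration.
GROUP_ANGLE_MULT = {"senior": 0.9, "junior": 1.1}

_HALF_NORMAL = float(np.sqrt(np.pi / 2.0))


def technique_profile(
    technique: str, group: str = "senior", group_angle_mult: dict | None = None
) -> OperatorProfile:
    """Profile calibrated to the per-technique mean error targets."""
    cal = TECHNIQUE_CALIBRATION[technique]
    mult = (group_angle_mult or GROUP_ANGLE_MULT)[group]
    return OperatorProfile(
        technique=technique,
        group=group,
        entry_sd=cal["mean_ee"] * _HALF_NORMAL,
        angle_sd=cal["mean_e_alpha"] * _HALF_NORMAL * mult,
    )


@dataclass(frozen=True)
class SimulatedInsertion:
    plan: TrajectoryPlan
    true_axis: ScrewAxis
    ground_truth_errors: InsertionErrors
    ground_truth_wall: WallDistanceResult | None
    ids: dict = field(default_factory=dict)
    digitized_screw: PointCloud | None = None
    digitized_surface: PointCloud | None = None
    digitized_landmarks: np.ndarray | None = None
    true_transform: RigidTransform | None = None  # R0 <- CMM


def _unit_perp(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        g = rng.normal(size=3)
        g -= (g @ d) * d
        n = np.linalg.norm(g)
        if n > 1e-9:
            return g / n


def _rodrigues(v: np.ndarray, k: np.ndarray, angle_rad: float) -> np.ndarray:
    return (
        v * np.cos(angle_rad)
        + np.cross(k, v) * np.sin(angle_rad)
        + k * (k @ v) * (1.0 - np.cos(angle_rad))
    )


def simulate_insertion(
    plan: TrajectoryPlan,
    profile: OperatorProfile,
    rng: np.random.Generator,
    pedicle: PedicleModel | None = None,
    config: AnalysisConfig | None = None,
    ids: dict | None = None,
) -> SimulatedInsertion:
    """Perturb a planned trajectory into a simulated inserted screw.

    The entry point shifts by a half-normal magnitude in a uniformly random
    transverse direction; the direction tilts by a half-normal angle about a
    uniformly random transverse rotation axis; insertion depth jitters along
    the axis.  Ground-truth accuracy parameters are computed analytically
    from plan and true axis; the ground-truth wall distance is computed when
    ``pedicle`` is given.
    """
    cfg = config or AnalysisConfig()
    d = plan.direction.array
    e_mag = abs(rng.normal(0.0, profile.entry_sd)) if profile.entry_sd > 0 else 0.0
    e_dir = _unit_perp(d, rng)
    angle = abs(rng.normal(0.0, profile.angle_sd)) if profile.angle_sd > 0 else 0.0
    tilt_axis = _unit_perp(d, rng)
    d_new = _rodrigues(d, tilt_axis, np.radians(angle))
    d_new /= np.linalg.norm(d_new)
    depth = rng.normal(0.0, profile.depth_sd) if profile.depth_sd > 0 else 0.0
    anchor = plan.entry.array + e_mag * e_dir + depth * d_new + np.asarray(profile.bias)
    axis = ScrewAxis(
        Point3.from_array(anchor, plan.frame),
        Direction3.from_array(d_new),
        length=cfg.screw_length,
        radius=cfg.screw_radius,
    )
    errors = insertion_errors(plan, axis, cfg.error_direction)
    wall = (
        pedicle_wall_distance(axis, pedicle, station_step=cfg.station_step)
        if pedicle is not None
        else None
    )
    return SimulatedInsertion(
        plan=plan,
        true_axis=axis,
        ground_truth_errors=errors,
        ground_truth_wall=wall,
        ids=dict(ids or {}),
    )


def _random_pose(rng: np.random.Generator) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(0, 2**31 - 1))).as_matrix()
    t = rng.uniform(-50.0, 50.0, size=3)
    return RigidTransform(R, t)


def simulate_digitization(
    insertion: SimulatedInsertion,
    vertebra: Vertebra,
    rng: np.random.Generator,
    config: AnalysisConfig | None = None,
    exposed_range: tuple = (-20.0, -1.0),
) -> SimulatedInsertion:
    """Simulate CMM digitization of the screw and the vertebral surface.

    Screw points are probe-centre coordinates on the exposed proximal
    cylinder (offset outward by the probe radius); surface points are drawn
    from the vertebra's surface; landmarks are digitized too (for coarse
    registration).  All are expressed in a random CMM pose and perturbed by
    isotropic Gaussian noise at the digitizer precision.  The true
    R0-from-CMM transform is recorded.
    """
    cfg = config or AnalysisConfig()
    if cfg.n_screw_points < 5:
        raise ValueError("need at least 5 screw points for a cylinder fit")
    axis = insertion.true_axis
    d = axis.direction.array
    e1 = _unit_perp(d, rng)
    e2 = np.cross(d, e1)

    t = rng.uniform(exposed_range[0], exposed_range[1], size=cfg.n_screw_points)
    # stratified angles: full circumference coverage even for small n
    phi = (np.arange(cfg.n_screw_points) + rng.uniform(0, 1, cfg.n_screw_points)) * (
        2.0 * np.pi / cfg.n_screw_points
    )
    radial = np.outer(np.cos(phi), e1) + np.outer(np.sin(phi), e2)
    r_out = cfg.screw_radius + cfg.probe_radius
    screw_pts = axis.anchor.array + np.outer(t, d) + r_out * radial

    idx = rng.choice(len(vertebra.surface_samples), size=cfg.n_surface_points, replace=False)
    surf_pts = vertebra.surface_samples[idx]
    lm = np.array([vertebra.landmarks[k].array for k in ("spinous", "left_tp", "right_tp")])

    cmm_from_r0 = _random_pose(rng)
    sd = cfg.digitizer_noise_sd

    def digitize(pts):
        out = cmm_from_r0.apply(pts)
        if sd > 0:
            out = out + rng.normal(0.0, sd, size=out.shape)
        return out

    return replace(
        insertion,
        digitized_screw=PointCloud(digitize(screw_pts), "screw_proximal", "CMM"),
        digitized_surface=PointCloud(digitize(surf_pts), "vertebra_surface", "CMM"),
        digitized_landmarks=digitize(lm),
        true_transform=cmm_from_r0.inverse(),
    )


@dataclass(frozen=True)
class EstimatedInsertion:
    axis: ScrewAxis  # in R0, oriented entry-to-tip
    errors: InsertionErrors
    wall: WallDistanceResult | None
    gertzbein: str | None
    heary: str | None
    transform: RigidTransform  # estimated R0 <- CMM
    fit_rms: float
    icp_rms: float


def estimate_insertion(
    insertion: SimulatedInsertion,
    vertebra: Vertebra,
    config: AnalysisConfig | None = None,
    pedicle: PedicleModel | None = None,
) -> EstimatedInsertion:
    """Run the full measurement chain on a digitized insertion.

    Cylinder fit of the screw cloud (CMM frame), landmark-initialised
    trimmed ICP of the surface cloud against the model surface, mapping of
    the fitted axis into R0, accuracy metrics against the plan, wall
    distance and grading.
    """
    cfg = config or AnalysisConfig()
    if insertion.digitized_screw is None:
        raise ValueError("insertion has not been digitized")
    radius = cfg.screw_radius if cfg.radius_mode == "fixed" else None
    fit = fit_cylinder_axis(
        insertion.digitized_screw, radius=radius, probe_radius=cfg.probe_radius
    )
    lm_model = np.array(
        [vertebra.landmarks[k].array for k in ("spinous", "left_tp", "right_tp")]
    )
    init = kabsch_align(insertion.digitized_landmarks, lm_model)
    reg = icp_register(
        insertion.digitized_surface,
        vertebra.surface_samples,
        init=init,
        max_iter=cfg.icp_max_iter,
        tol=cfg.icp_tol,
        trim_fraction=cfg.icp_trim_fraction,
    )
    fit_r0 = replace(fit, axis=apply_transform(reg.transform, fit.axis, new_frame="R0"))
    axis = orient_axis_toward_tip(fit_r0, insertion.plan, screw_length=cfg.screw_length)
    errors = insertion_errors(insertion.plan, axis, cfg.error_direction)
    wall = gert = heary = None
    if pedicle is not None:
        wall = pedicle_wall_distance(axis, pedicle, station_step=cfg.station_step)
        gert = grade_gertzbein(wall, cfg.screw_radius, cfg.gertzbein_boundaries)
        # estimated screw tip: entry taken as the projection of the planned
        # entry on the fitted axis, tip one screw length further
        d = axis.direction.array
        t_entry = (insertion.plan.entry.array - axis.anchor.array) @ d
        tip = Point3.from_array(axis.anchor.array + (t_entry + cfg.screw_length) * d, "R0")
        heary = grade_heary(
            wall, tip, vertebra.body, cfg.screw_radius, cfg.heary_canal_threshold
        )
    return EstimatedInsertion(
        axis=axis,
        errors=errors,
        wall=wall,
        gertzbein=gert,
        heary=heary,
        transform=reg.transform,
        fit_rms=fit.rms_residual,
        icp_rms=reg.rms,
    )


@dataclass(frozen=True)
class StudyDesign:
    """Balanced factorial design: techniques x groups x operators x screws."""

    techniques: tuple = ("conventional", "cbct", "navigation")
    groups: tuple = ("senior", "junior")
    operators_per_group: int = 4
    screws_per_operator_technique: int = 10

    @property
    def n_total(self) -> int:
        return (
            len(self.techniques)
            * len(self.groups)
            * self.operators_per_group
            * self.screws_per_operator_technique
        )


@dataclass
class StudyResult:
    table: object  # pandas DataFrame, one row per screw
    summaries: dict
    seed: int
    runtime_s: float


def run_virtual_study(
    design: StudyDesign | None = None,
    seed: int = 0,
    config: AnalysisConfig | None = None,
    spec: PhantomSpec | None = None,
    digitize: bool = True,
    compute_dpw: bool = True,
    group_angle_mult: dict | None = None,
) -> StudyResult:
    """Run the factorial virtual study end to end.

    With the default design this produces 240 screw insertions (3 techniques
    x 2 experience groups x 4 operators x 10 screws).  When ``digitize`` is
    true the full measurement chain is run per screw and the table carries
    both ground truth and pipeline estimates; otherwise only analytic ground
    truth (fast path for calibration studies).  Summaries include Spearman
    correlations of coaxiality against the component errors, Mann-Whitney
    senior-vs-junior comparisons, breach prevalence, and (when graded) the
    estimated-vs-true grade cross-tabulations.
    """
    import pandas as pd

    t0 = time.perf_counter()
    design = design or StudyDesign()
    cfg = config or AnalysisConfig()
    spec = spec or PhantomSpec(seed=seed)
    phantom = generate_phantom(spec)
    plans = plan_trajectories(phantom)
    verts = {v.level: v for v in phantom.vertebrae}

    ss = np.random.SeedSequence([seed, 0x5DEECE66])
    rows = []
    screw_id = 0
    n_ot = len(design.techniques) * design.operators_per_group * len(design.groups)
    streams = ss.spawn(n_ot)
    k = 0
    for technique in design.techniques:
        for group in design.groups:
            profile = technique_profile(technique, group, group_angle_mult)
            for op in range(design.operators_per_group):
                rng = np.random.default_rng(streams[k])
                k += 1
                operator = f"{group[:3]}{op + 1}"
                for j in range(design.screws_per_operator_technique):
                    ids, plan = plans[j % len(plans)]
                    v = verts[ids["vertebra"]]
                    ped = v.pedicles[ids["side"]]
                    sim = simulate_insertion(
                        plan, profile, rng,
                        pedicle=ped if compute_dpw else None,
                        config=cfg,
                        ids={"technique": technique, "group": group,
                             "operator": operator, **ids},
                    )
                    row = {
                        "screw": screw_id, "technique": technique, "group": group,
                        "operator": operator, "vertebra": ids["vertebra"],
                        "side": ids["side"],
                        "ee_true": sim.ground_truth_errors.ee,
                        "et_true": sim.ground_truth_errors.et,
                        "e_alpha_true": sim.ground_truth_errors.e_alpha,
                        "C_true": sim.ground_truth_errors.coaxiality,
                    }
                    if compute_dpw:
                        w = sim.ground_truth_wall
                        row.update(
                            dpw_true=w.dpw, breach_true=w.breach,
                            direction_true=w.direction,
                            gertzbein_true=grade_gertzbein(
                                w, cfg.screw_radius, cfg.gertzbein_boundaries),
                            heary_true=grade_heary(
                                w, sim.true_axis.tip, v.body,
                                cfg.screw_radius, cfg.heary_canal_threshold),
                        )
                    if digitize:
                        sim = simulate_digitization(sim, v, rng, cfg)
                        est = estimate_insertion(
                            sim, v, cfg, pedicle=ped if compute_dpw else None)
                        row.update(
                            ee_est=est.errors.ee, et_est=est.errors.et,
                            e_alpha_est=est.errors.e_alpha,
                            C_est=est.errors.coaxiality,
                            fit_rms=est.fit_rms, icp_rms=est.icp_rms,
                        )
                        if compute_dpw:
                            row.update(
                                dpw_est=est.wall.dpw, breach_est=est.wall.breach,
                                direction_est=est.wall.direction,
                                gertzbein_est=est.gertzbein, heary_est=est.heary,
                            )
                    rows.append(row)
                    screw_id += 1
    table = pd.DataFrame(rows)

    which = "est" if digitize else "true"
    summaries: dict = {"n_screws": len(table)}
    C = table[f"C_{which}"].to_numpy()
    for err in ("ee", "et", "e_alpha"):
        summaries[f"spearman_C_{err}"] = spearman_rho(C, table[f"{err}_{which}"].to_numpy())
    for param in ("ee", "et", "e_alpha", "C") + (("dpw",) if compute_dpw else ()):
        col = f"{param}_{which}" if f"{param}_{which}" in table else f"{param}_true"
        s = table.loc[table["group"] == "senior", col].to_numpy()
        jnr = table.loc[table["group"] == "junior", col].to_numpy()
        summaries[f"mw_senior_junior_{param}"] = mann_whitney_u(s, jnr)
    if compute_dpw:
        summaries["breach_prevalence_true"] = float(table["breach_true"].mean())
        if digitize:
            summaries["breach_prevalence_est"] = float(table["breach_est"].mean())
            summaries["gertzbein_crosstab"] = _grade_crosstab(
                table["gertzbein_est"], table["gertzbein_true"],
                ("0", "1", "2", "3", "4", "/"))
            summaries["heary_crosstab"] = _grade_crosstab(
                table["heary_est"], table["heary_true"],
                ("I", "II", "III", "IV", "V", "/"))
    return StudyResult(table, summaries, seed, time.perf_counter() - t0)


def _grade_crosstab(est, true, categories) -> CrossTab:
    k = len(categories)
    counts = np.zeros((k, k), dtype=int)
    idx = {c: i for i, c in enumerate(categories)}
    for e, t in zip(est, true):
        counts[idx[str(e)], idx[str(t)]] += 1
    return CrossTab(categories, counts)
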