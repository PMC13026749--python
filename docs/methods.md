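# Methods

This note documents the models, conventions and numerical choices behind
`pedscrew`, in the order of the measurement chain. It states no empirical
result that the test suite or `scripts/acceptance.py` do not themselves
compute.

## Accuracy model

A planned trajectory is the pair (Pe, Pt) in the planning frame R0; its
direction is the unit vector Pe→Pt. The inserted screw is an oriented axis
(anchor, unit direction entry→tip, length, radius R). The four accuracy
parameters are ee (distance Pe→axis), et (distance Pt→axis), eα (angle
between directions, degrees in [0, 180], no folding to [0, 90] — the axis
orientation is disambiguated upstream), and coaxiality C, the maximum
distance between the screw axis and the planned trajectory over the planned
segment. Because the squared distance from a fixed line to a point moving
along a segment is a convex quadratic in the segment parameter, the maximum
sits at an endpoint and C = max(ee, et) exactly; the test suite checks this
identity against a dense-sampling oracle. C is reported as a maximum
distance (radius-like); `report_diameter=True` doubles it for a
tolerance-zone-diameter convention.

**Direction of measurement.** Two conventions coexist for ee/et: from the
*planned* points to the *fitted* axis, or from the *actual* screw points to
the *planned* axis. The default is planned→fitted
(`error_direction="plan_to_actual"`), because the fitted axis is the
operational measurement result; the alternative is one switch away. All
metrics are invariant under a common rigid transform (tested at 1e-9).

**Frames.** Coordinates carry a frame tag (R0 planning, RL vertebra-fixed,
RN screw-fixed, CMM digitizer); operations refuse to mix tags silently. The
vertebra frame is built from three landmarks (spinous process, both
transverse processes): lateral = left→right transverse process, superior =
landmark-plane normal oriented by a cranial hint, anterior completes the
right-handed triad, origin at the transverse-process midpoint.

## Wall distance and grading

The pedicle corridor is either a parametric straight tube with elliptical
cross-section (semi-axes a medial-lateral, b cranio-caudal) or an oriented
open triangle mesh of the canal wall. dpw is the minimum over axis stations
inside the corridor's longitudinal slab of the signed in-plane distance to
the wall, positive inside. Stations are sampled every 0.1 mm and refined by
bounded scalar minimisation (parametric) or a 40-fold finer local grid
(mesh). The in-plane point-to-ellipse distance is solved by bisection of
the stationarity condition on the first quadrant (unique root; 60
iterations ≈ machine precision; validated against a polygonal oracle). For
meshes, closest points come from an exact vectorised point-to-triangle
query (barycentric region decomposition, brute force over faces — no
spatial-index dependency) and the sign from the outward face normal at the
closest triangle. Mesh and parametric results agree to < 0.05 mm at ~2000
faces and < 0.01 mm at ~20000 (tested). An axis that never enters the slab
is evaluated at the nearest station and flagged (`traverses=False`,
direction `none`).

Breach iff dpw < R; depth = R − dpw; regimes: no breach (dpw ≥ R), breach
with axis inside (0 ≤ dpw < R), breach with axis outside (−R < dpw < 0),
fully extra-pedicular (dpw ≤ −R). The breach direction is the 90° angular
sector (medial/lateral/superior/inferior) of the cross-section containing
the centerline→nearest-wall-point vector; the classifications name
directions but define no sector boundaries, so centered quadrants are a
package convention.

**Gertzbein:** 0 if no breach; medial breaches graded by depth with cut
points 2 and 4 mm, lower bounds inclusive (depth 2.0 → grade 2, 4.0 →
grade 3); any lateral breach → 4; other directions → "/". **Heary:** I if
no breach; medial/inferior → IV; lateral (and tip-past-body anterior) → II
when the screw tip stays inside the vertebral-body volume, III otherwise;
superior → "/". Grade V ("endangers neural/vascular structures") is not
geometrically decidable; it is implemented as a severity convention —
medial depth beyond a configurable canal threshold (default 4 mm, matching
the deepest Gertzbein class). The tip test uses a box vertebral-body volume
in the vertebra frame.

## Measurement chain

**Cylinder fit.** Probe-centre points on the proximal screw are fitted by
nonlinear least squares (Levenberg–Marquardt) minimising Σ(dist(p, axis) −
r)². Parameters: a 2-D anchor offset in a fixed plane orthogonal to the
initial direction (removing the slide-along-axis gauge), two direction
angles, and optionally the radius. Initialisation is the cloud centroid and
a principal covariance direction; because a short digitized section can
have its largest variance transverse to the true axis, all three
eigenvectors are tried and the lowest objective kept. Fixed-radius mode
(default, at the known 2.5 mm screw radius) stabilises shallow-coverage
fits; free mode serves QC. The 2 mm spherical probe reports its centre, so
the fit targets r = R + probe radius and reports the compensated radius
(the axis is unaffected — exact for a cylinder). Degenerate clouds
(collinear/coplanar by covariance-eigenvalue ratios) and undersized clouds
(< 5 fixed, < 6 free) are rejected. A descent guard never reports a
solution worse than its initialiser. The entry→tip sign is set by the
planned direction (error if orthogonal within 1e-6), with the anchor moved
to the entry-side end of the digitized extent.

**Registration.** The digitized surface patch (CMM frame) is registered to
the planning model by trimmed point-to-point ICP: alternate
nearest-neighbour correspondence (nearest surface point when the target is
a mesh; k-d tree for cloud targets) with a closed-form Kabsch step
(SVD-based, reflections suppressed) on the best (1 − trim) fraction of
correspondences. Defaults: trim 0.1 (tolerates partial overlap of the
digitized patch), tolerance 1e-6 mm on the RMS change, 100 iterations max;
non-convergence is reported, not hidden. Initialisation uses a Kabsch fit
of the three digitized anatomical landmarks. RMS descent is monotone with
trim 0 (tested); with trimming the kept set changes between iterations, so
only final-versus-initial improvement is guaranteed.

## Synthetic phantom and virtual study

The phantom emulates a five-level lumbar bench model: per level a box
vertebral body (42 × 30 × 26 mm), posterior elements assembled from
primitive solids (spinous process, transverse processes, laminae) as the
digitizable surface, three landmarks, and left/right pedicle corridors —
straight elliptical tubes, 12 mm long, isthmus centres ±13 mm lateral, with
medial convergence growing 10°→22° from L1 to L5. The surface mesh is a
concatenation of closed primitive solids; it is used for sampling and
registration only, never for containment queries. Planned trajectories run
along the corridor centerlines (entry 4 mm behind the corridor mouth,
length 40 mm), so the planned dpw equals min(a, b) by construction.

**Insertion error model.** The true axis perturbs the plan by (i) an entry
offset with half-normal magnitude in a uniformly random transverse
direction, (ii) an angular tilt with half-normal magnitude about a random
transverse axis, (iii) Gaussian depth jitter (1 mm) along the axis. A
half-normal with scale σ has mean σ·√(2/π), so scales are set from the
per-technique calibration table of mean errors — entry 3.4/2.5/2.4 mm and
orientation 7.9°/5.2°/5.9° for conventional / CBCT-assisted /
navigation-assisted insertion — as σ = mean·√(π/2). Experience enters as a
multiplier on the angular scale only (senior 0.9, junior 1.1, pooled mean
preserved): angular skill separates the groups on et, eα and C while ee and
dpw stay comparable, the pattern the framework is meant to resolve. Only
means are calibrated; the distribution family is a modelling choice.

**Corridor dimensions.** Semi-axes default to a = 7.5→10.5 mm
(medial-lateral) and b = 8.0→9.5 mm (cranio-caudal) from L1 to L5. These
are *effective corridor dimensions* of a foam phantom, deliberately chosen
so that, under the calibrated error magnitudes, achieved wall distances
average ≈ 5 mm and the true breach prevalence sits near one screw in seven
— the safety-margin regime the validation statistics are designed for. They
are larger than literal pedicle widths; with anatomical upper-lumbar widths
the calibrated entry errors would breach roughly every second conventional
screw, which is not the regime of interest.

**Digitization.** Screw: 30 probe-centre points (above the 20-point
minimum), stratified over the full circumference of a 19 mm proximal axis
section (head plus exposed shank of a polyaxial screw), offset outward by
the 1 mm probe radius. Surface: 200 points drawn from a dense (4000-point)
surface sample; landmarks digitized too. Everything is expressed in a
uniformly random CMM pose and perturbed by isotropic Gaussian noise at the
0.2 mm digitizer precision; the true pose is recorded for ground-truth
checks. The 19 mm section length matters: the chain's axis-direction error
scales inversely with this lever arm, and shorter sections (≈ 10 mm) double
the orientation error. Surface points carry no probe offset
(probe-tip-calibrated digitization assumed); the screw offset is
compensated exactly in the fit.

**Virtual study.** Balanced factorial design, by default 3 techniques × 2
experience groups × 4 operators × 10 screws = 240 insertions, independent
RNG substreams per operator-technique cell, fully deterministic per seed.
Each screw can run ground-truth-only (fast path for calibration studies) or
through the full chain. Summaries: Spearman correlations of C with ee, et,
eα; Mann–Whitney senior-vs-junior tests for all five parameters; breach
prevalence; and estimated-versus-true grade cross-tabulations.

## Agreement statistics

Cross-tabulations put dpw-based grades in rows and the image-based
reference in columns, with "/" as a reserved category for breach directions
outside the classification. Conventions, each chosen where the source
material is silent and kept configurable:

- **Binary reduction** drops screws graded "/" by either rater, then maps
  grades to breach/no-breach. This exclusion is the convention that
  reproduces all four published diagnostic values simultaneously.
- **Discordance** counts every off-diagonal screw *plus* the "/" screws:
  they represent findings the reference scheme cannot express, and this is
  the counting that matches the published discordance numbers.
- **Marginal breach counts** are asymmetric by the same logic: "/" is a
  detected breach for the dpw rater but carries no breach record for the
  reference rater.
- Cohen's kappa uses the standard product-marginal chance correction with
  large-sample SE and Wald CI (statsmodels); Gwet's AC1 uses chance
  agreement Σ πk(1−πk)/(K−1) with its linearised single-table variance
  estimator (hand-implemented; no installed package provides it).
- Diagnostic proportions get Wilson score CIs. Landis–Koch labels use cut
  points 0.205/0.405/0.605/0.81 (two-decimal rounding convention; the
  printed bins leave (0.80, 0.81) unassigned — assigned to "substantial").
- Mann–Whitney U is exact by enumeration when both groups have ≤ 8
  untied observations, otherwise the tie-corrected normal approximation;
  Spearman ρ uses mid-ranks with the t-approximation p-value.

The bundled Heary table's printed margins are internally inconsistent with
its own cells (row "/" and grand totals, two column totals); the fixture
preserves both verbatim and the loader exposes `margins_consistent=False`.
The published binary kappa is not exactly recoverable from the published
cells under any reduction convention (the four candidates span ≈
0.839–0.873); kappa is therefore validated against formula oracles and the
convention-specific values, not a single printed number.

## What the synthetic tests do and do not show

The phantom has rigid, exactly known geometry, straight corridors, ideal
landmark visibility, isotropic digitizer noise and no outliers, no
segmentation error, and no tissue or imaging artefacts. Passing tests
demonstrate that the measurement chain is unbiased and precise *under these
conditions* (exact at zero noise; ee within 0.5 mm and eα within 1° for ≥
90% of screws at 0.2 mm noise), and that the statistics are correctly
implemented and calibrated (Mann–Whitney type-I error, KS-uniform null
p-values). They do not establish accuracy on real vertebrae, where
registration faces segmentation error and partial, biased surface coverage,
and pedicle walls are neither elliptical nor straight. Scaled-down problem
sizes in the test suite (e.g. 500 replicate null studies at 60 screws
rather than 240) are chosen to keep the suite fast while exercising the
same code paths.

## Known limitations

- Heary grade V is a depth-threshold convention, not a geometric decision.
- In-out-in trajectories report the single global dpw minimum; multiple
  wall crossings are flagged only through the breach direction/depth, not
  enumerated.
- The ICP is point-to-point with fixed trimming; no global initialisation,
  so a grossly wrong landmark init can converge to a wrong basin (reported
  honestly via RMS, but not auto-detected).
- The corridor model is a straight extrusion at the isthmus; curved or
  hourglass pedicles are only approximated by the slab restriction.
- The estimated screw tip (for Heary II/III) anchors the nominal screw
  length at the projection of the planned entry onto the fitted axis, which
  assumes the achieved insertion depth matches the plan within the depth
  jitter.
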