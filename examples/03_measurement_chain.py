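"""The simulated measurement chain: digitize, fit, register, measure.

One screw is inserted (with realistic error magnitudes) into a synthetic
vertebra, digitized with a simulated touch-probe (0.2 mm noise, 2 mm
spherical sensor), the screw cloud is fitted to a least-squares cylinder,
the surface cloud is ICP-registered back to the model, and the accuracy
parameters are recomputed — then compared against the known ground truth.
"""

import numpy as np

from pedscrew import AnalysisConfig
from pedscrew.phantom import (
    PhantomSpec,
    estimate_insertion,
    generate_phantom,
    plan_trajectories,
    simulate_digitization,
    simulate_insertion,
    technique_profile,
)

cfg = AnalysisConfig()
phantom = generate_phantom(PhantomSpec(seed=1))
ids, plan = plan_trajectories(phantom)[4]  # L3 left
vertebra = next(v for v in phantom.vertebrae if v.level == ids["vertebra"])
pedicle = vertebra.pedicles[ids["side"]]

rng = np.random.default_rng(2)
sim = simulate_insertion(plan, technique_profile("cbct", "senior"), rng, pedicle=pedicle)
sim = simulate_digitization(sim, vertebra, rng, cfg)
est = estimate_insertion(sim, vertebra, cfg, pedicle=pedicle)

gt = sim.ground_truth_errors
pose_err = est.transform.compose(sim.true_transform.inverse())
print(f"screw: {ids['vertebra']} {ids['side']}  (cylinder fit on "
      f"{len(sim.digitized_screw)} probe points, ICP on {len(sim.digitized_surface)})")
print(f"{'parameter':>12} {'truth':>8} {'estimate':>9}")
for name, t, e in [
    ("ee / mm", gt.ee, est.errors.ee),
    ("et / mm", gt.et, est.errors.et),
    ("e_alpha/deg", gt.e_alpha, est.errors.e_alpha),
    ("C / mm", gt.coaxiality, est.errors.coaxiality),
    ("dpw / mm", sim.ground_truth_wall.dpw, est.wall.dpw),
]:
    print(f"{name:>12} {t:8.3f} {e:9.3f}")
print(f"\nCMM pose recovered to {pose_err.rotation_angle_deg():.3f} deg / "
      f"{np.linalg.norm(pose_err.translation):.3f} mm; "
      f"cylinder-fit rms {est.fit_rms:.3f} mm, ICP rms {est.icp_rms:.3f} mm")
print("Estimates track ground truth at the digitizer noise level: the chain,")
print("not the simulator, produces these numbers.")
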