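"""Accuracy parameters of a single screw against its planned trajectory.

A planned trajectory is two points (entry Pe, target Pt) in the planning
frame.  The inserted screw's axis deviates from it; four scalars summarise
the deviation: entry point error ee, target point error et, orientation
angle error e_alpha, and coaxiality C (the maximum axis-to-trajectory
distance over the planned segment, which equals max(ee, et)).
"""

import numpy as np

from pedscrew import Direction3, Point3, ScrewAxis, TrajectoryPlan, insertion_errors

# plan: a 40 mm trajectory along +x
plan = TrajectoryPlan(Point3(0.0, 0.0, 0.0), Point3(40.0, 0.0, 0.0))

# inserted screw: entry shifted 2 mm laterally, direction tilted 5 degrees
tilt = np.radians(5.0)
axis = ScrewAxis(
    Point3(0.0, 2.0, 0.0),
    Direction3.from_array([np.cos(tilt), np.sin(tilt), 0.0]),
    length=45.0,
    radius=2.5,
)

e = insertion_errors(plan, axis)
print(f"entry point error   ee      = {e.ee:6.3f} mm")
print(f"target point error  et      = {e.et:6.3f} mm")
print(f"orientation error   e_alpha = {e.e_alpha:6.3f} deg")
print(f"coaxiality          C       = {e.coaxiality:6.3f} mm")
print()
print("The 2 mm entry shift is read back as ee; the 5 degree tilt grows to")
print(f"~{40 * np.sin(tilt):.1f} mm of target deviation over the 40 mm trajectory, and the")
print("worst deviation along the planned segment (here at the target) is C.")
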