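"""Signed pedicle-wall distance and automatic clinical grading.

The pedicle is modelled as an elliptical corridor; dpw is the minimal
signed distance from the screw axis to its wall (positive inside).  With a
5 mm screw (radius R = 2.5 mm), dpw < R means the screw breaches the
cortex; the breach direction and depth map to Gertzbein and Heary grades.
"""

from pedscrew import (
    Direction3,
    PedicleModel,
    Point3,
    ScrewAxis,
    VertebralBody,
    classify_breach,
    grade_gertzbein,
    grade_heary,
    pedicle_wall_distance,
)

R = 2.5
pedicle = PedicleModel(
    center=[0, 0, 0], axis=[0, 1, 0], medial=[1, 0, 0], superior=[0, 0, 1],
    half_length=6.0, a=6.0, b=5.0, level="L3", side="left",
)
body = VertebralBody(
    center=[0, 15, 0], lateral=[1, 0, 0], anterior=[0, 1, 0], superior=[0, 0, 1],
    half_extents=(21, 15, 13),
)

print(f"{'medial offset':>14} {'dpw':>7} {'regime':>15} {'depth':>6} {'dir':>9} {'G':>2} {'H':>3}")
for offset in (0.0, 4.5, 7.0, 9.5):
    axis = ScrewAxis(Point3(offset, -20.0, 0.0), Direction3(0, 1, 0), length=45, radius=R)
    res = pedicle_wall_distance(axis, pedicle)
    g = grade_gertzbein(res, R)
    h = grade_heary(res, axis.tip, body, R)
    print(
        f"{offset:14.1f} {res.dpw:7.2f} {classify_breach(res, R):>15} "
        f"{res.depth:6.2f} {res.direction:>9} {g:>2} {h:>3}"
    )

print()
print("Sliding the axis towards the medial wall walks through the four")
print("regimes: clear of the wall (dpw >= R), breach with the axis still in")
print("the canal, breach with the axis outside, and a fully extra-pedicular")
print("screw; grades escalate with depth (Gertzbein 2 mm steps, Heary IV/V).")
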