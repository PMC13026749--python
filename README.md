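# pedscrew

Dual-metric assessment of pedicle screw placement accuracy: standardized
trajectory error metrics for engineering comparison, and a signed
pedicle-wall distance for clinically actionable breach detection — plus the
full measurement chain and the statistics needed to validate one against the
other.

## Who this is for

Pedicle screws anchor spinal instrumentation through the pedicle, a narrow
bony corridor next to the spinal canal. Whether a screw is "accurate" is
usually judged qualitatively on CT-like images (Gertzbein–Robbins and Heary
grades), which is semi-quantitative and observer-dependent. This package is
for surgical-navigation researchers and metrology-minded surgeons who want
continuous, reproducible numbers instead: it computes trajectory deviations
in the spirit of ISO geometrical tolerancing, derives breach grades
automatically from geometry, and quantifies how well the geometric grading
agrees with image-based grading.

## The metrics

A planned trajectory is an entry point **Pe** and target point **Pt** in the
planning frame R0; the inserted screw is its fitted axis (frame RN, radius
R). The package computes:

- **ee** — entry point error: minimal distance (mm) from Pe to the screw axis;
- **et** — target point error: same for Pt;
- **eα** — orientation angle error (degrees) between planned direction and axis;
- **C** — coaxiality: maximum distance between screw axis and planned
  trajectory over the segment [Pe, Pt]. Squared point-to-line distance is
  convex along a segment, so C = max(ee, et) exactly;
- **dpw** — pedicle wall distance: minimal *signed* distance (mm) from the
  screw axis to the pedicle cortical wall (positive inside the corridor).
  With screw radius R: dpw ≥ R → no breach; 0 ≤ dpw < R → breach, axis inside;
  −R < dpw < 0 → breach, axis outside; dpw ≤ −R → fully extra-pedicular.
  Breach depth R − dpw and direction (medial/lateral/superior/inferior) map
  to Gertzbein grades 0–4 and Heary grades I–V, with "/" reserved for breach
  directions the classifications cannot express.

The measurement chain turns bench data into these numbers: touch-probe
point clouds of the proximal screw are fitted to a least-squares cylinder
(probe-radius compensated), digitized vertebral surfaces are registered to
the planning model by landmark-initialised trimmed ICP, and the fitted axis
is expressed in R0.

Validation statistics: Cohen's kappa and Gwet's AC1 (with 95% CIs and
Landis–Koch labels), sensitivity/specificity/PPV/NPV with Wilson CIs,
Mann–Whitney U and Spearman correlation. A synthetic lumbar phantom module
(L1–L5, elliptical pedicle corridors, simulated insertions and CMM
digitization with known ground truth) makes every stage testable end to end,
including a balanced factorial virtual study
(3 techniques × 2 experience groups × 4 operators × 10 screws = 240).

## Worked example

`examples/02_wall_distance_grading.py` slides a 5 mm screw axis medially
across an elliptical pedicle corridor (semi-axes 6 × 5 mm):

```
 medial offset     dpw          regime  depth       dir  G   H
           0.0    5.00       no_breach   0.00  superior  0   I
           4.5    1.50   breach_inside   1.00    medial  1  IV
           7.0   -1.00  breach_outside   3.50    medial  2  IV
           9.5   -3.50   fully_outside   6.00    medial  3   V
```

Centered, the axis clears the nearest wall by 5 mm (> R = 2.5 mm, no
breach, Gertzbein 0 / Heary I). At 4.5 mm offset the wall distance drops to
1.5 mm < R: a 1 mm medial breach (Gertzbein 1, Heary IV). Further out the
axis crosses the wall (dpw negative) and finally the whole screw leaves the
pedicle (Gertzbein 3, Heary V at > 4 mm medial depth).

`examples/04_agreement_tables.py` validates dpw grading against image-based
grading on the bundled 236-screw table:

```
binary reduction: TP=22 FP=6 FN=1 TN=202
  sensitivity  0.957  (95% CI 0.790-0.992)
  specificity  0.971  (95% CI 0.939-0.987)
  ppv          0.786  (95% CI 0.605-0.898)
  npv          0.995  (95% CI 0.973-0.999)
  Cohen kappa  0.846  (0.735-0.957) -> almost perfect
  Gwet AC1     0.962  (0.934-0.991) -> almost perfect
```

dpw missed a single image-detected breach (FN = 1) while flagging 10
additional breaches the qualitative grading did not record — the expected
behaviour of a continuous metric against a coarse scale.

The other examples cover single-screw error metrics (`01`), the full
digitize → fit → register → measure chain on one screw (`03`) and a
scaled-down virtual study (`05`). A thin CLI mirrors the chain for file-based
work: `pedscrew simulate | fit | register | metrics | grade | agree | report`.

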