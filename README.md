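# gulpflow

Intraoral food transport is hard to study because it happens where you
cannot see it: inside the mouth. Biplanar X-ray video of radiopaque
markers (XROMM) gets around this by reconstructing the 3D motion of a
marked food item and of the skeletal elements of a fish's head during a
feeding event. `gulpflow` is an analysis pipeline for such data, built
around the feeding behavior of suction-feeding fishes (the motivating
system is the channel catfish): it reconstructs the food's trajectory in
a skull-fixed anatomical frame, splits each feeding event into capture,
handling and swallowing phases, quantifies the kinematics of each phase,
and asks whether food transport is synchronized with cranial expansion
("gulping") motions of the head.

Because the original X-ray recordings are not redistributable, the
package ships a seeded synthetic feeding-event generator that emulates
the study conditions with ground truth for every stage, so every part of
the pipeline is testable end to end.

## The analysis

**Anatomical frame.** Rigid-body motion of each marked cranial element is
estimated from ≥3 markers by orthogonal Procrustes superposition (SVD of
the cross-covariance with reflection correction). All motion, and the
food point, is re-expressed relative to the neurocranium; the origin is
the rostral-most midline tip of the neurocranium with rostrocaudal (rc),
dorsoventral and mediolateral axes. The esophageal sphincter is located
by a total-least-squares plane through CT landmark points; the distance
from the origin to the point where the rc axis pierces that plane defines
the normalization: food at the jaws has rc_norm = 0, food at the
esophagus rc_norm = 1. Distances scale to head lengths (HL), speeds to
HL/s.

**Phase segmentation.** The capture→handling transition is a structural
change in food velocity: for a series *y₁…yₙ* and a candidate split after
*k* observations,

F(k) = (RSS₀ − RSSₖ) / (RSSₖ / (n − 2)),

where RSS₀ is the residual sum of squares about one mean and RSSₖ about
separate means of the two segments. The breakpoint estimate is the argmax
of F over a trimmed candidate window, and significance of sup F comes
from a seeded permutation test (an asymptotic Brownian-bridge mode is
available). A trial is segmented only when p < 10⁻³ (half a
Bonferroni-corrected 0.05 over 25 trials). Capture is [0, breakpoint),
handling runs to the first frame with rc_norm ≥ 1, swallowing is the
rest.

**Phase kinematics.** Per phase: duration, mean per-frame speed, net rc
progress, and path complexity — total distance traveled divided by net
displacement (1 for straight paths). Across trials, statistics are pooled
unweighted (each trial contributes its phase mean once) and
handling/capture fold changes are ratios of the pooled grand means. Speed
and axis-proportion profiles are binned over ten 10% increments of
rc_norm.

**Synchrony.** Per phase, the food's rc velocity is cross-correlated with
each cranial degree-of-freedom velocity (hyoid retraction, girdle
retraction, hypaxial shortening, mouth opening) over lags −L…L. Trials
are z-scored per phase and concatenated with missing-value spacers ≥ L so
no lagged product spans two trials, which constrains all trials to share
one common lag. Positive lag means food follows cranial motion. The
breakpoint locations are also regressed on individual and food type
(dummy-coded OLS, partial F-tests).

## Worked example

Generate a synthetic 25-trial study and run the pipeline:

```sh
gulpflow simulate --n 25 --seed 5 --out scratch/study
gulpflow run --config scratch/study/study.yaml --out results/run
```

or run the numbered analyses (`analysis/01_simulate_study.py` …
`05_breakpoint_regression.py`), which print, for seed 5:

```
25 trials segmented, 0 failed
all breakpoints significant at p < 1e-3: True
breakpoint within 15 frames (50 ms) of truth: 25/25
   capture (n=25):      91 ±    25 ms,  9.83 ± 3.37 HL/s, complexity 1.00 ± 0.01
  handling (n=25):    1104 ±   552 ms,  0.84 ± 0.07 HL/s, complexity 2.98 ± 0.49
swallowing (n=16):     923 ±   283 ms,  0.26 ± 0.01 HL/s, complexity 1.07 ± 0.02
swallowing:
  hyoid_retraction       best lag  +8 frames ( +26.7 ms), R^2 = 0.976
```

Reading this: food enters the mouth fast and nearly straight (capture:
~0.09 s at ~10 HL/s, complexity ≈ 1), then spends over a second winding
slowly toward the esophagus (handling: ~0.8 HL/s, complexity ≈ 3), and
once in the esophagus its velocity pulses track hyoid retraction with a
~27 ms delay — the generator's planted 25 ms lag quantized to 8 frames at
300 frames/s. The breakpoint regression finds no individual or food-type
effect on breakpoint location, as none was planted.

Single-trial use: `gulpflow segment --trial t001_food.csv --head-length 70
--esophagus-distance 56`.

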