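# Methods

## Coordinate systems and units

Raw inputs are marker coordinates in millimetres at a fixed frame rate
(default 300 frames/s). Rigid transforms map a body's
reference-configuration marker positions to their current positions,
`x_cur = R x_ref + t`; the reference configuration is the marker layout
at a chosen reference frame (default: the first frame with all of the
body's markers visible — the original pose of the study animal is not
recoverable, so any fully visible frame serves). Body motion is estimated
per frame by orthogonal Procrustes superposition: SVD of the
cross-covariance of centered point sets, with the determinant-corrected
rotation so reflections are never returned. Frames with fewer than three
visible markers are gaps; gaps propagate through relative-motion
composition and into the food trajectory.

The anatomical frame is fixed in the neurocranium: origin at the
rostral-most midline tip, axes (rostrocaudal positive caudal,
dorsoventral, mediolateral) supplied per individual as an orientation in
the neurocranium's reference pose. Deriving these axes from CT anatomy is
out of scope; they are configuration. Food position in this frame is
divided by head length (HL); the rostrocaudal coordinate is additionally
divided by the esophagus distance so that 0 is the jaws and 1 the
esophageal sphincter.

The esophagus distance is the distance from the origin to the point where
the rostrocaudal axis ray pierces the total-least-squares plane through
the esophageal landmark ring. The along-axis pierce point (rather than
the perpendicular point-to-plane distance) is the default because it is
the quantity consistent with normalizing rostrocaudal position along that
same axis; the perpendicular distance is available as a mode. For a plane
nearly perpendicular to the axis the two differ by a factor 1/cos(tilt),
well under 1% for tilts below 8°.

## Differentiation

Velocity is the discrete derivative of position: central differences on
interior frames, one-sided at segment ends, with gap-split segments
differentiated independently. No smoothing is applied by default — the
analysis should not silently alter the dynamics it measures; a
moving-average window can be configured upstream of differentiation.
Note one consequence used throughout: a central difference at frame *i*
equals the mean of the step velocities into and out of frame *i*, so
frame-to-frame jitter in the underlying motion is attenuated by the
measurement itself.

## Structural change (capture → handling)

Model: a single mean shift in a constant-mean regression of the velocity
series, i.e. the Chow F statistic

F(k) = (RSS₀ − RSSₖ) / (RSSₖ / (n − 2))

scanned over candidate first-segment sizes k in ⌈nh⌉ … n − ⌈nh⌉. The
implementation evaluates the numerator through the ANOVA between-group
identity RSS₀ − RSSₖ = k(m₁−m)² + (n−k)(m₂−m)² on the centered series;
this is exactly the same quantity but avoids catastrophic cancellation
for near-zero F, keeping the scan within ~1e-10 relative of a direct
brute-force evaluation. A constant series has F ≡ 0 (detected with a
scale-aware tolerance); an exact two-level split yields F = ∞. Ties at
the argmax break to the earliest candidate.

Significance is a permutation test: the series is randomly permuted
(seeded), sup F recomputed, and p = (1 + #{perm ≥ obs}) / (1 + n_perm),
with n_perm = 10,000 by default and an optional futility stop once the
threshold can no longer be reached. Permutation is exact under
exchangeability and assumption-light; the classical asymptotic reference
— sup over the trimmed interval of B(s)²/(s(1−s)) for a Brownian bridge
B — is provided as an alternative mode, with its tail probability
evaluated by seeded Monte-Carlo simulation of the limit process. The
output records which mode produced the p-value.

Trim fraction: the bare functions default to the conventional h = 0.15.
The study driver defaults to h = 0.02, because in a feeding trial the
capture phase occupies only a few per cent of the recorded frames
(~90 ms of several seconds), and a 15% trim would exclude the
capture-to-handling transition from the candidate window entirely. Both
are configurable.

Segmentation requires p < α (default 10⁻³: half of a
Bonferroni-corrected 0.05 over 25 trials; whether α should rescale with
trial count in other studies is left to configuration). The breakpoint is
computed on rostrocaudal velocity by default; the overall speed series is
run alongside as a concordance check and recorded. Trials failing the
threshold are excluded from phase pooling and reported.

## Phase statistics and pooling

Per phase: duration = frame count / frame rate; mean speed = mean of
per-frame speeds (net displacement / duration is reported as a secondary
column, since either reading of "average speed" is defensible); path
complexity = Σ step lengths / |last − first| over the phase's non-gap
positions, undefined (NaN, excluded from pooling of that parameter only)
when the endpoints coincide within 1e-9 HL. Phases with more than 10%
gap frames are flagged. Pooling is unweighted across trials — each trial
contributes its phase mean once — and fold changes are ratios of pooled
grand means (handling / capture), which is the arithmetic that reproduces
a fold change like 1397/89 = 15.7 from the phase means themselves.

Binned profiles use ten half-open bins over rc_norm ∈ [0, 1); a step is
assigned to the bin of its starting frame, rc_norm ≥ 1 clips into the
last bin, and frames rostral of the jaws (rc_norm < 0) are excluded.
Speeds are scaled to the trial's maximum; per-bin axis proportions are
Σ|Δcomponent| per axis over the three-axis total.

## Synchrony

Per phase and trial, food rostrocaudal velocity and each cranial
degree-of-freedom velocity are z-scored (correlation is scale-free, but a
common scale keeps the pooled, concatenated series from being dominated
by high-amplitude trials) and concatenated with NaN spacers at least as
long as the maximum lag, so no lagged product pairs samples from
different trials and all trials share a single common lag. r at lag ℓ is
the Pearson correlation of pairs (y_t, x_{t+ℓ}) over pairwise-complete
indices (x = food, y = cranial; positive ℓ = food follows cranial
motion). Lags with fewer than 10 complete pairs, or zero variance in
either member, are flagged and dropped. The best lag maximizes r²; ties
break to the smaller |lag|, then the smaller signed lag. Max lag defaults
to 30 frames (100 ms at 300 frames/s) — several times the ~25 ms scale of
interest. Groupings: pooled study plus each individual.

Breakpoint locations are regressed on individual and food type as
dummy-coded fixed-effect categoricals (no interaction), with partial
(type II) F-tests per term; single-level or confounded terms are flagged
untestable, and zero-residual fits return undefined p-values rather than
spurious ones.

## The synthetic generator

The generator emulates the study conditions — three transport phases at
300 frames/s, head length 70 mm, esophagus distance 0.8 HL — with every
stochastic choice drawn from one seeded generator, so identical
(config, seed) reproduce identical arrays.

**Capture.** Peak speed ~ N(17, 9²) HL/s truncated at 0, duration ~
N(89, 53²) ms, stop position ~ N(0.605, 0.155²) rc_norm truncated to
(0.05, 0.95) — a stop at or past the plane would leave no handling phase.
The tracked strike begins with the food slightly rostral of the jaws
(rc_norm −0.4 by default): the reported capture statistics (peak 17 HL/s
yet mean ≈ 11 HL/s over 89 ms ending at 60% of the way to the esophagus)
are mutually consistent only if the tracked capture path is longer than
the intraoral segment alone. The speed profile decelerates exponentially
toward a floor, v(t) = c + (v₀ − c)e^(−t/τ) with τ = duration/3 and the
floor c solved in closed form so the integral equals the required
displacement. The sampled (peak, duration, stop) triple is resampled
until 1.15 < v₀·d / displacement < 2.4: below that the profile cannot
cover the displacement, above it the floor collapses toward zero and the
"stop" smears over the whole capture instead of being the abrupt arrest
the phase definition requires. Velocities are sampled at step midpoints
so the discrete integral tracks the analytic displacement. With lateral
noise at 0 the capture path is exactly straight (path complexity 1).

**Handling.** A caudal drift plus Poisson-timed (4/s) half-cosine bursts
(120 ms) in uniformly random 3D directions plus white jitter. Two scalars
are solved numerically per trial on the realized walk: the burst/jitter
scale so the measured (central-difference) mean speed equals the 0.82
HL/s target, and the drift gain so the realized path complexity equals
the 3.25 target — the naive closed form drift = speed/complexity runs
short because lateral wander inflates the net displacement. The phase
ends when the walk reaches the esophageal plane. Trials without
esophageal transport stop 2% of the esophagus distance short of the
plane, so landmark-fit error in the measured plane location cannot flip
their classification.

**Swallowing.** Present with probability 16/25 (the study's accounting).
Cranial expansion is a periodic train (250 ms period) of half-cosine
pulses; the food's rostrocaudal velocity is a scaled, lag-shifted copy of
that signal plus noise, with the 25 ms lag quantized to whole frames
(8 at 300 frames/s) so the noise-free detected lag equals the construction
exactly. The scale is solved so the measured mean speed is 0.25 HL/s.
DOF signals carry one large coordinated excursion during capture,
baseline noise during handling, and amplitude-scaled copies of the
expansion train during swallowing; they are emitted under the same
half-frame discrete-derivative convention the food velocity acquires when
the analysis differentiates the trajectory, so the two series are
phase-aligned. Calibrating speeds against the measured convention (not
the raw step velocities) is deliberate: the study's own speed statistics
were computed from discrete derivatives of tracked positions.

**Marker scenes.** Six bodies (neurocranium, suspensorium, operculum,
lower jaw, hyoid, pectoral girdle) with four markers each over ~30 mm
spreads; the neurocranium swims while the others oscillate relative to
it, all motions the identity at frame 0 so truth transforms compare
directly to estimates; Gaussian coordinate noise (default 0.05 mm) and
optional occlusion windows.

What the generator does not emulate: marker dropout statistics of real
X-ray tracking, food rotation (single marker, translation only, as in the
motivating dataset), soft-tissue deformation, water flow, and any
anatomically realistic coupling among cranial degrees of freedom beyond
the shared expansion signal. During capture, food and cranial signals
share a single excursion whose shapes differ, so capture-phase
correlations and lags are emergent rather than planted — only the
swallowing-phase lag has configured truth. Passing tests therefore show
the pipeline recovers known structure under realistic magnitudes and
noise, not that it would be robust to every artifact of real recordings.

## Numerical choices and degenerate inputs

- Collinearity in the Procrustes fit and the plane fit is detected by the
  second singular value falling below 1e-8 of scale; such inputs raise
  degenerate-geometry errors rather than returning ill-conditioned fits.
- Plane normals are oriented deterministically (rostrocaudal component
  ≥ 0, ties broken by the next axes).
- CSV round-trips use 17-significant-digit formatting and round-trip
  float parsing, so written studies reload bit-exactly.
- Permutation p-values use the add-one form (1 + hits)/(1 + n), never
  exactly zero; the futility stop only ever makes the reported p more
  conservative.
- The pipeline derives per-trial permutation seeds from the study seed by
  seed-sequence hashing, keeping runs byte-identical for a given config.

## Problem sizes

Default analyses use 25-trial studies (~500-1300 frames per trial);
recovery checks use 100 trials for the breakpoint (10,000 permutations
with futility stopping), 50 phases for the lag, and 800 replicates at 199
permutations for the type-I-error calibration — sizes at which the Monte
Carlo error of each rate is a few per cent or less.

## Known limitations

- The single-breakpoint mean-shift model assumes one abrupt transition;
  gradual decelerations put the argmax inside the deceleration rather
  than at its end (multiple-breakpoint search is out of scope).
- The asymptotic p-value mode is itself Monte-Carlo (of the limiting
  process), not a table interpolation; it is an alternative reference,
  with permutation as the primary method.
- With non-integer true lags the correlogram can only bracket the truth
  between adjacent frames; lag resolution is one frame (3.3 ms here).
- Esophagus location error translates directly into the rc_norm scale;
  trials ending very near the plane are intrinsically ambiguous between
  "reached" and "entered".
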