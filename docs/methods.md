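# Methods

## The metric

A training session consists of a standard path S = {s_1, …, s_N} recorded
from an expert and M imitation repetitions T_m = {t_m1, …, t_mN}, all 3D
marker trajectories in centimetres. After arc-length resampling to a common
point count N, the pointwise deviation of repetition m at index n is the
Euclidean distance d_mn = ‖t_mn − s_n‖. Correspondence is strictly by index:
the metric deliberately contains no elastic (time-warping) alignment, since
it asks "was the instrument within tolerance of where it should be at this
stage of the gesture", not "did a similar shape occur at some other time".

For a tolerance radius d_j the *working-space volume* is the cylindrical
tube V_j = π d_j² h coaxial with the standard path; h is the standard
path's arc length by default (`h_mode="arclength"`), or a fixed workspace
height (`h_mode="fixed"`, default 2 cm, matching a cylindrical training
workspace of fixed height and variable radius). The *reliability* R_j is
the fraction of repetitions entirely contained in the tube: repetition m
conforms iff max_n d_mn ≤ d_j. Containment is worst-case by construction —
a single excursion leaves the tube — and no smoothing or outlier rejection
is applied, which is what makes the maximum-volume rung stable under
occasional large deviations while average-based summaries fluctuate.

Sweeping d_j over a descending *threshold ladder* yields the RV curve of
(d_j, V_j, R_j) triples. The default ladder is the set of distinct
per-repetition maxima, which is lossless: R(d) is a step function that can
only change at a per-path maximum, so the M-rung maxima ladder attains
every reliability value the full M·N multiset attains (R = 0 occurs only
strictly below the smallest maximum, where no rung is needed). The full
multiset ladder is available for completeness (`ladder_origin="full"`).
Duplicate thresholds collapse to a single rung. Attainable reliabilities
are multiples of 1/M, so a target of R = 0.95 requires all repetitions to
conform whenever M < 20.

The comparison baseline is the conventional *working volume*: per
repetition, a sphere whose radius is the mean distance of the path's
points from the path's own centroid (the central point is otherwise
unspecified in the literature; the per-path centroid is the deterministic
choice), with volumes (4/3)π r̄³ averaged arithmetically across
repetitions. It ignores the standard path entirely.

## Monitoring and the stopping rule

Skill evolution is evaluated on cumulative prefixes (repetitions 1..m),
not sliding windows, so the reliability denominator always equals the
repetition count at the checkpoint. Two traces are tracked at checkpoints
(default 10, 25, 50):

* reliability at a fixed volume V: the implied radius is d = √(V/(πh)) and
  the value at checkpoint m is n/m over the first m repetitions;
* volume at a fixed reliability target (default 0.95): the smallest rung
  volume whose reliability meets the target (weak inequality; the largest
  rung always has R = 1, so the scan always succeeds).

The stopping rule scans consecutive checkpoint pairs of a reliability
trace in order and triggers at the first pair whose change satisfies
|ΔR| ≥ threshold (default 0.05); training stops at the earlier member of
that pair, the last stable measurement. The trigger is on the *absolute*
change: a sudden improvement ends the scan exactly like a sudden decline,
because either means performance is no longer stable — and this is the
only reading that reproduces both published worked examples (one triggers
on an improvement at the first pair, the other on an improvement at the
second). Comparisons use a 10⁻¹² tolerance so that two-decimal printed
reliabilities (e.g. 0.96 − 0.90 = 0.06) compare exactly despite binary
float representation. Only the threshold rule is implemented; detection of
gradual drift is out of scope.

## Synthetic data generator

Real recordings of the knot-tying task are not redistributable, so the
generator emulates them with known statistical structure:

* **Standard path** — a two-loop helix (4π radians) of radius 1 cm and
  pitch 0.3 cm per loop, sampled at N = 200 arc-length-uniform points
  (arc length ≈ 12.6 cm). This approximates the geometry of a suture
  wound twice around an instrument without claiming fidelity to any
  particular recording. Circle and line paths are available for oracle
  tests with analytic arc lengths.
* **Noise** — repetition m adds i.i.d. isotropic Gaussian noise of
  per-axis scale σ_m to every point. The default flat scale σ = 0.8 cm
  places maximum tube volumes in the few-hundred cm³ range typical of
  trainee recordings. The *learning* schedule decays σ geometrically to
  half its starting value over the series; the *fatigue* schedule holds σ
  flat with one ×3 spike over 5 consecutive repetitions starting just
  past mid-series (repetition 26 of 50), so the default checkpoints
  bracket the episode. All randomness flows through one
  `numpy.random.default_rng(seed)` generator.

Under this model the pointwise deviation is σ·χ₃ (chi distribution, 3
degrees of freedom), giving two independent oracles: the containment
probability of an N-point repetition in a radius-d tube is
[F_χ₃(d/σ)]^N, and the mean deviation σ·2√(2/π) yields a
method-of-moments estimator of σ. The generator and metric are validated
against each other: empirical R(d) over 2000 simulated repetitions stays
within 3 binomial standard errors of the closed form, and the σ estimator
recovers the true scale within 5% at 10⁴ deviation samples.

What the generator does *not* model: temporal autocorrelation within a
repetition (the metric is pointwise, so smoothness is irrelevant to it),
velocity and task duration, biomechanical hand constraints, or
non-isotropic error structure. Passing tests therefore establish the
computational pipeline and its statistical calibration, not distributional
claims about human trainees.

## Numerical choices

* Resampling is linear interpolation along the piecewise-linear input at
  equal arc-length increments; endpoints are copied exactly. Resampling
  can only shorten the chord sum (corner cutting), by O((κΔs)²) relative
  for a curve of curvature κ sampled at spacing Δs; length is preserved to
  1e-6 relative only when the input polyline is dense relative to the
  output. Coincident-point (zero-length) inputs are rejected.
* Frame indices need not start at 0; ordering is by frame value with file
  order breaking ties (stable sort). Units are centimetres throughout;
  volumes come out in cm³; conversion is the caller's responsibility.
* Problem sizes in the test suite (M ≤ 2000 repetitions, N ≤ 200 points,
  100-seed dynamics sweeps) were chosen as the smallest at which the
  stochastic checks have comfortable margins; the whole suite runs in a
  few seconds.

## Limitations

* No elastic alignment: paths with correct shape but different pacing are
  penalised unless arc-length resampling happens to realign them.
* Reliability granularity is 1/M; fixed-volume traces at small m move in
  coarse steps, and the stopping threshold of 0.05 is below the step size
  at m ≤ 20 checkpoints, so early checkpoints can trigger on a single
  repetition's outcome.
* Whether published snapshot volumes used h = arc length or h = 2 cm is
  not recoverable; both modes are supported and the choice changes the
  radius implied by a fixed volume.
* The stopping rule reacts only to abrupt changes between checkpoints;
  slow monotone drift never triggers it.
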