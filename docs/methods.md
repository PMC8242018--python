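# Methods

## Pipeline overview

The system turns two synchronized camera exports into a statement of
the form "cluster k is a stimulus-specific behavior feature".  Stages:
LED-based temporal alignment and 3D fusion; fixed-duration phase-pure
segmentation; a raw spatiotemporal segment encoding; PCA; min-max
rescaling; FuzzyART clustering; exact binomial association screening;
and a frozen-model transfer evaluation on held-out segments.  Each
stage is importable on its own; `run_experiment` chains them.

## Synchronization and fusion

The LED detector thresholds on the baseline of the first
`baseline_window` frames (default 30) at mean + `k_sigma` × SD
(default 5).  It is a threshold detector rather than a general
change-point method because the event is a hardware step; `k_sigma`
absorbs sensor noise.  Detection fails loudly when no frame crosses the
threshold or when the onset lies inside the baseline window (degenerate
threshold).

Both views are re-indexed so frame 0 is their LED-on frame and
truncated to the common length.  Fusion takes x, y from the ventral
view and z from the lateral view; the lateral view's redundant x is
*not* averaged in — the two views have independent calibrations, and
mixing them would smear both — but its RMS disagreement with the
ventral x is logged as a rig-health diagnostic.  Pixel-to-cm
calibration is an affine map from config-supplied pixel bounds to the
tank extent; bounds are never inferred from the fish's excursion.

Gaps (missing tracking) are filled by per-axis linear interpolation up
to `max_gap_frames` (default 60 = 1 s at 60 fps); longer gaps raise an
error naming the interval, and observed frames are preserved
bit-exactly.  Smoothing is a centered moving average (default window
10 samples) with truncated edges; it is contractive per axis.
Coordinates: origin at a tank floor corner, z up, cm, frames 0-based;
"top" means z ≥ H/2.

## Segment encoding

Segments are anchored at each phase run's start and never straddle a
QT/ES boundary, so every segment has an unambiguous phase label; the
trailing remainder of a run is dropped.

The clustering input is the raw resampled path, not the six
traditional kinematic parameters: the parameters serve as an
after-the-fact validation of discovered clusters, and using them as
input would make that validation circular.  Encoding: linear resample
to `n_resample` = 50 equal-time points; concatenate the 49 per-interval
displacement triples with the 50 absolute z values (vector length
4·50 − 3 = 197).  Displacements make the encoding translation-invariant
in x and y; absolute z is kept because depth preference is behaviorally
meaningful.  The encoder is a plain function, swappable by users.

PCA is centered but not variance-scaled (all columns are cm), keeping
the smallest k with cumulative explained variance ≥ the target
(default 0.72).  Scores are min-max rescaled per column into [0, 1] as
FuzzyART requires; constant columns map to 0.5, and held-out rows are
clipped into [0, 1] with a logged clip count.  Fitted PCA/rescale
states transform held-out data without refitting.

## FuzzyART

Authored from scratch (complement coding, choice function
T = |I ∧ w| / (α + |w|), vigilance match M = |I ∧ w| / |I| ≥ ρ,
learning w ← β(I ∧ w) + (1 − β)w).  Defaults: ρ = 0.73, α = 0.001
(conservative-limit choice behavior), β = 1 (fast learning), max 50
epochs.  Presentation order is the given (chronological) row order,
constant across epochs — determinism beats shuffling for
reproducibility.  Ties on the choice value resolve to the lowest
category index.  An epoch with no assignment and no weight change ends
training; with β = 1 weight updates are exact componentwise minima, so
exact equality is a safe convergence test.  Prediction never updates
weights; the default `nearest` mode assigns every row to its
highest-choice category (reporting the match value), `strict` returns
an uncommitted sentinel when vigilance fails.

Invariants maintained and tested: |I| = d after complement coding;
weights componentwise non-increasing over learning events; with β = 1
each weight equals the componentwise min of every input that ever
resonated with the category; a converged model is a fixed point.

## Association screen

Under the null, cluster membership is phase-blind, so the ES count in a
cluster of n is Binomial(n, p0) with p0 the schedule's ES time fraction
(0.5 for 30 s/30 s).  The two-tailed p-value is the minimum-likelihood
construction (sum of probabilities of all outcomes no more likely than
the observed one), which at p0 = 0.5 coincides with doubling the tail,
capped at 1.  The default screen thresholds raw p-values at 0.05;
Benjamini–Hochberg is available because many clusters are tested.
Clusters with n < 5 are flagged low-power.  The grid search reruns the
entire chain per (segment length, cumulative variance, vigilance) cell
and records the strongest ES-leaning association per cell
(`best_neg_log10_p`), plus the direction-agnostic maximum as a
separate column.

## Transfer evaluation

The 80/20 split is uniform, seeded, and stratified by phase by default
so p0 stays 0.5 in both sets (the randomized, stratified choice is
ours; chronological and unstratified splits are available).  A leakage
guard refuses any feature state whose fitted row count differs from
the model's training size.  Cluster profiles (mean of the six
kinematic parameters over members) from train and test are z-scored
per parameter across all profiles — the parameters' units are
incommensurate — and compared by average-linkage hierarchical
clustering with deterministic leaf order.  Group comparisons use
Welch's two-tailed t-test by default: the groups being compared are
data-driven clusters with uncontrolled variances; the pooled-variance
variant is available by flag.

## The synthetic session generator

The generator stands in for the recording rig and real fish.  What it
emulates: two orthogonal views of one fish per session in a
20×20×20 cm tank at 60 fps; an alternating 30 s QT / 30 s ES schedule;
a configurable inter-camera frame offset with an LED-on event in both
intensity traces (baseline 10 ± 1, step to 200 — arbitrary units, only
detectability matters); i.i.d. per-frame per-view dropout emitted as
explicit missing values; and a phase-dependent motion contrast.

Motion is a correlated random walk.  Per step the horizontal speed is
gamma-distributed (phase mean, default QT 3 cm/s / ES 9 cm/s, shape 2)
and the heading receives a wrapped-normal perturbation with
sd = 1/√κ (QT κ = 8, ES κ = 2: the stimulus evokes faster swimming and
broader turning — the direction of the contrast is the modeled claim,
not its magnitude).  Vertically the fish keeps depth: vertical velocity
is a persistent AR(1) process (≈0.5 s glides) whose stationary
amplitude is 0.35 × the phase's mean speed — an agitated fish moves
faster in all three dimensions — and depth mean-reverts (0.5 /s)
toward a shared mid-water preferred depth, so depth excursions stay
bounded for arbitrarily long sessions.  Walls reflect specularly and
mirror the heading, avoiding wall-sticking artifacts that would
confound turning statistics.

Two generator choices matter downstream and were made deliberately.
First, depth variance is bounded and its covariance across a segment
decays smoothly, so the depth block of the encoding contributes a few
strong, interpretable PCA modes rather than either swamping the 72%
target on its own or vanishing; with the defaults the retained space is
low-dimensional (k ≈ 2) and every retained mode's score spread scales
with the phase's activity, which is what makes the ES motif
recoverable at vigilance 0.73 without category proliferation.  Second,
all fish share the mid-water preferred depth: per-fish depth offsets
would let the clusterer partition segments by fish identity, and since
each fish's schedule is exactly phase-balanced, such clusters are
uninformative for the screen and artificially depress its calibration.

What the generator does **not** emulate: novel-tank top/bottom
exploration and diving responses (depth is phase-neutral in mean),
burst-and-glide gait microstructure, tail-beat kinematics or body
posture (the fish is a point), wall-following (thigmotaxis), the
500 ms on/off duty cycle inside ES phases, and inter-fish variability
in motion parameters.  Passing tests therefore show the pipeline
recovers a speed/turning/vertical-agitation motif under controlled
conditions — not that it captures every structure of real recordings.

## Calibration of the screen under the null

With the motif disabled (identical motion in both phases) the fraction
of clusters flagged significant at α = 0.05 measures the screen's
false-positive behavior.  Two structural effects make the measured rate
sit below the nominal 5% (≈1–3% at realistic cluster sizes): the exact
binomial test is conservative at moderate n (attained size 0.02–0.049
for n = 10–40), and the schedule fixes the session's overall ES
fraction at exactly 50%, so cluster compositions are jointly
hypergeometric and negatively dependent.  The calibration test
therefore bounds inflation with cluster-level binomial error
(rate ≤ 5% + 3σ) and compares the rate to 5% with replicate-level
binomial error (m = 200 replicates), the replicate being the
independent sampling unit.  Practically: the screen is conservative,
never anti-conservative, under the balanced design.

## Numerical choices and degenerate inputs

- LED detection uses strict `>` against the threshold; an all-constant
  trace is an error, not frame 0.
- Turn angles ignore horizontal steps shorter than 1e-6 cm (a
  stationary fish has zero turn angle, not NaN).
- Kinematic rates divide by the time actually spanned by a segment's
  steps ((n − 1)/fps), so a constant-speed path reports its speed
  exactly.
- PCA uses the full (deterministic) SVD; the component count uses a
  1e-12 tolerance on the cumulative-variance comparison so a target of
  1.0 selects the full rank.
- Min-max ranges below 1e-12 are treated as constant columns (map to
  0.5).
- FuzzyART tie-breaks (equal choice values) go to the lowest category
  index via a stable sort; model serialization round-trips through
  JSON deterministically.
- The grid search and the experiment runner are deterministic given
  the seed: identical configs reproduce byte-identical CSV/JSON.

## Problem sizes used in the shipped checks

Study-condition runs use 10 fish × 10 min (1200 five-second segments);
the oracle-equivalence suite uses 200 input sets of ≤ 8 rows; the
binomial oracle covers all n ≤ 25 exhaustively; the null calibration
uses 200 replicates of 3 fish × 10 min.  These sizes were chosen so the
full suite completes in a few minutes on one CPU while keeping every
check statistically meaningful.

## Known limitations

- The segment encoding (displacement + depth profile) is one of many
  reasonable choices; real-data performance will depend on it, and the
  encoder is deliberately swappable.
- Cluster identifiers are presentation-order artifacts: reordering
  segments renumbers clusters, so analyses should reference cluster
  *content* (profiles, phase composition), never raw ids across runs.
- Calibration assumes config-supplied pixel bounds; no lens-distortion
  or epipolar correction is attempted.
- The binomial screen treats segments as exchangeable; strong temporal
  autocorrelation in real behavior can violate this, and the balanced
  schedule makes the screen conservative (see calibration section).
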