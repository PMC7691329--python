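# Methods

This note documents the models, statistics, and numerical choices behind
`orientrack`, and what the synthetic generators do and do not emulate.

## The task and its outcome logic

The package models a head-fixed two-choice visuomotor task: a mouse reports
the side of a lateral visual cue by rotating a trackball whose cumulative
rotation is coupled to the cue position in closed loop. A trial is decided
by the **first** time the cumulative ball angle reaches +15° or −15° within
the 1 s response window; excursions short of threshold must be offset by
opposite rotation, exactly as the closed-loop stimulus coupling implies, so
classification reduces to a first-crossing rule on the cumulative-angle
trace. Under the *inward* contingency a right cue makes the positive
rotation correct; the *outward* contingency mirrors the mapping. Traces
that never reach threshold are timeouts; timeouts are excluded from
incorrect-rate denominators (which count completed trials only) but define
their own rate over all trials of a cue.

One sign convention is declared once
(`task.POSITIVE_IS_CONTRA_FOR_LEFT_HEMISPHERE`): positive cumulative angle
is the rotation that brings a right-side cue to center in the inward task,
which is the contraversive action for a left-hemisphere analysis. Every
contra/ipsi label downstream derives from this constant plus the session's
hemisphere field, so relabeling the hemisphere swaps contra and ipsi
groupings without touching outcomes — a property the test battery checks
exhaustively.

Trial scheduling mirrors the training apparatus: an optional anti-bias rule
repeats the cue after any non-correct trial and randomizes after correct
ones; hold-to-start (1 s) and the inter-trial interval (2.5 s) are dead
time that only advances the session clock. Laser trials cover a fixed
fraction of the session and may never occur on two consecutive trials. The
scheduler draws the laser-trial positions uniformly over all k-subsets of
non-adjacent indices using the standard bijection onto plain k-subsets of
n−k+1; this is exact, satisfies the hard adjacency constraint by
construction, and realizes the target fraction to within rounding (naive
whole-sequence rejection sampling has vanishing acceptance probability at
realistic session lengths).

For spontaneous (no-cue) sessions, back-to-back 2 s "trials" each designate
one rewarded direction at a ±5° threshold, with two concurrent anti-bias
rules: the designation repeats after an unrewarded trial and switches after
a rewarded one. When the two rules could conflict (the trial after a reward
earned under repetition), switching takes precedence — the package applies
"switch after reward, repeat otherwise" uniformly.

## Behavioral metrics and the permutation test

Performance is summarized per cue × laser cell: timeout rate (denominator:
all trials of the cue), incorrect rate (denominator: completed trials),
and response time (mean over complete correct responses). From these the
package computes:

- **side preference** (contra − ipsi)/(contra + ipsi) on correctly selected
  proportions,
- **laser bias indices** of the form
  ((x_corr,l + y_incorr,l) − (x_corr,nl + y_incorr,nl)) / (x_corr,nl + y_incorr,nl),
  instantiated for the contraversive action (x = contra-instructing cue,
  y = ipsi-instructing cue) and for the right stimulus (x = right cue,
  y = left cue); both constituent rates are probabilities of selecting the
  same response, so the index reads as a fractional laser-induced change in
  that response's selection. The cue-to-action mapping resolves per
  contingency, making the same formula valid for inward and outward data.
- **spontaneous deltas** (x_l − x_nl)/x_nl per movement direction, counting
  only attempted movements (≥5° crossings),
- **movement velocity**: mean per-tick |Δangle|/Δt from movement start
  (first sample beyond 0.5°) to the first threshold crossing. Magnitudes
  are used (direction-agnostic), a deliberate choice since only speed, not
  signed velocity, enters the analyses.

Cohort-level inference uses a within-animal label permutation test:
sessions are combined per mouse, each permutation round reshuffles the
laser labels independently within each animal (preserving its laser-trial
count), all trials are then pooled and the laser-induced change recomputed.
The observed statistic is that same pooled quantity, so observed and null
values are exchangeable under the null; equal-weight per-animal means are
reported alongside as a diagnostic. The two-sided p is the fraction of
null draws at least as extreme as the observed value relative to zero,
with no +1 smoothing — p can be 0 at resolution 1/R, and the resolution is
reported with every result. (An alternative convention centers extremes on
the null median rather than zero; with label permutations the null is
centered very near zero and the choice is immaterial in practice.)
Significance for the right/left cue pair uses the Bonferroni-adjusted
per-comparison alpha 0.05/2 = 0.025. Per-animal trial tables are put in a
canonical sort order before permuting so results are exactly invariant to
the order sessions or mice are supplied in.

## Statistical primitives

- **Fisher exact test (two-sided)**: point-probability definition — the
  sum of probabilities of all tables with the observed margins whose
  hypergeometric probability does not exceed the observed one, accumulated
  in log space (`logsumexp` over `hypergeom.logpmf`) so p-values far below
  the double underflow threshold remain representable. A relative log-space
  tolerance of 1e-7 guards floating ties, matching common implementations.
  The test suite checks exact agreement with full enumeration.
- **Binomial confidence intervals**: exact tail inversion
  (Clopper–Pearson), delegated to statsmodels.
- **AUROC**: the rank-statistic definition (fraction of positive/negative
  pairs won, ties half), computed from midranks; the preference score is
  2(AUROC − 0.5) with the contraversive/contralateral condition as the
  positive class, so +1 means complete contra preference.
- **Shuffle significance**: pooled values are re-partitioned into groups of
  the original sizes; the observed score is significant outside the
  empirical central 95% of the shuffled scores.
- **Rank tests**: signed-rank (zeros dropped, the classical convention —
  the source analyses do not specify) and rank-sum. P-values are exact for
  small tie-free samples and asymptotic otherwise; the reported z is the
  tie-corrected normal approximation and flips sign under argument swap.
- All stochastic operations take an explicit seed; generators are built on
  the counter-based Philox bit generator so streams are identical across
  platforms.

## Fluorescence pipeline

For somatic ROIs the corrected trace is F = F_soma − 0.7 · F_neuropil;
axonal boutons skip the subtraction (their ROIs have no matched neuropil
annulus). F0 is the fluorescence value of highest density over the
session: a Gaussian KDE mode, implemented as a 512-bin histogram spanning
the 1st–99th percentile smoothed with Silverman's bandwidth — numerically
equivalent to a direct KDE at a fraction of the cost. ΔF/F =
(F − F0)/F0 × 100; ROIs with F0 ≤ 0 are flagged invalid and excluded
downstream. Baseline drift is removed by subtracting
max-filter(min-filter(Gaussian-smooth(ΔF/F))): the Gaussian width is
interpreted as σ = 1 s (not FWHM; configurable), and both minimum and
maximum filters use centered windows of 60 s (301 frames at 5 Hz) with
edge values held constant. Detrending precedes per-ROI z-scoring.

Trial tensors align z-scored traces to stimulus onset or response time on
the 5 Hz frame grid using half-up rounding of the anchor time onto frame
indices (consistent under time shifts, unlike nearest-sample ties).
Completed trials carry one of four cue × action conditions; sessions with
fewer than five trials in any condition are marked excluded. Task
statistics are 1 s post-stimulus window means: per-condition means per
neuron, cue/action marginals (each marginal is the average of its two
constituent condition means), population contrasts by paired signed-rank
across neurons, per-neuron action differences by across-trial rank-sum at
alpha 0.05 (the per-neuron test and shuffle count are package defaults;
the source analyses name neither), and an optional velocity median split
computed per session with a shared split point. Bouton responsiveness
compares 1 s pre-stimulus means against 0.6–1.2 s post-stimulus means
(signed-rank, p < 0.01); the same post window feeds the AUROC preference
score, whose significance comes from 1000 trial-label shuffles (central
95%).

## Decoding

Features are per-trial ROI means over −0.2 to +0.4 s around the response.
The classifier is a soft-margin linear SVM (hinge loss, L2 penalty) with
C = 1e-4 and no feature standardization. Each iteration subsamples five
trials from each cue × action condition — read as the four cue × action
combinations, the same "condition" the five-trial session-inclusion rule
uses; this makes each action class exactly cue-balanced (10 trials per
class) and supports stratified 10-fold cross-validation (two pseudotrials
per fold, one per class). Cross-session pseudotrials concatenate
same-condition trials from different sessions, re-pairing randomly every
iteration. Chance is estimated by repeating the procedure with shuffled
test labels; the decoder is significant when its mean accuracy falls
outside the central 95% of the shuffled iteration means. Within-session
comparisons subsample unlabeled ROIs down to the projection-labeled count
each iteration and run both populations through the identical CV on the
same trial subsample.

## Spike trains and pose

Firing rates are counted per block with half-open [start, end) intervals;
condition rates are total spikes over total duration. The laser modulation
index (FR_laser − FR_nonlaser)/(FR_laser + FR_nonlaser) is bounded in
[−1, 1] and undefined (NaN, not modulated) when both rates are zero.
"Modulated" is a two-sided rank-sum over block-wise rates at alpha 0.05 —
a documented package default. Analysis uses the 6 s block intervals (the
7 s laser pulse brackets them); the epoch is a parameter.

Pose clips are rotated frame-by-frame into a body frame: anchor (tail base
or headplate) at the origin and the nose bearing rotated to +y. The
transform is rigid, distance-preserving to machine precision, and
equivariant to global rigid motions; frames missing the anchor or nose are
skipped and counted. The clip summary is the mean x of both paws over
valid frames (positive = animal's right).

## Synthetic generators

Each generator is deterministic under a fixed seed and returns a
machine-readable ground-truth record.

**Behavior.** Stochastic agents draw a timeout (probability 0.12), then an
action from per-cue correct probabilities (default 0.8, within the
reported expert range), with response times log-normal (median 0.4 s,
σ = 0.35, truncated to the window). A laser trial shifts the probability
of the contraversive action additively by `laser_delta_contra` (clipped to
[0, 1], clips counted). The closed-form expectation of the contra-action
index follows directly from these probabilities and anchors the recovery
tests. The traced mode synthesizes piecewise-linear ramps consistent with
each sampled outcome and response time (approach speed 40 deg/s) and runs
them through the full closed-loop engine; a traceless mode draws outcomes
directly from the same distributions (i.i.d. cues) for large calibration
sweeps, with the traced path cross-checked against it. Default cohort
size: 6 mice × 3 sessions × 300 trials.

**Calcium.** Underlying activity is a trial impulse train weighted by
selective tuning — each neuron has a preferred cue side and action
direction (gamma-distributed amplitudes, mean 0.3 and 0.5 fractional ΔF/F;
non-preferred conditions evoke 0.1× the response) and responds on 70% of
trials, giving traces with quiescent periods as real GCaMP6s recordings
have — convolved with a rise/decay kernel (0.2 s / 1.5 s) at 5 Hz.
Measured soma fluorescence is baseline × (1 + signal) × (1 + drift) +
0.7 × neuropil + noise: the contamination coefficient equals the one the
correction assumes (a mismatch knob exists for sensitivity studies), and
drift is a slow sinusoid (period ≥ 100 s so the 60 s min/max filter can
track it) plus a small random walk. A `labeled_action_gain` multiplier and
an `ipsi_bias` on the preferred-action probability create the
projection-labeled and population-preference structures the imaging and
decoding analyses look for. The generator does not model indicator
nonlinearity, spike-to-calcium saturation, or motion artifacts — passing
tests show the pipeline's arithmetic and filtering are correct under the
stated noise model, not that real-data artifacts are handled.

**Boutons.** Passive-viewing trials (1 s lateralized stimuli, 5 s spacing)
drive each bouton at amplitude 0.5 for its preferred side and 0.5 − effect
for the other, with trial-to-trial gain noise; effect 0 is the calibration
null (responsive but side-indifferent).

**Spikes.** Homogeneous Poisson within 6 s blocks (1 s gaps, half laser);
laser rates solve the modulation-index formula, r_l = r_nl(1 + m)/(1 − m),
so target indices are exact by construction. Index +1 with a finite
baseline is rejected (infinite rate), as is −1 with zero baseline
(undefined).

**Pose.** A turning body (1 deg/frame at 30 fps) with nose on the body
axis and paws laterally offset by the ground-truth amount, plus landmark
noise.

## Problem sizes and analysis regimes

The calibration suite runs 500 null cohorts (6 mice × 300 trials) with 200
permutations each; recovery uses 20-mouse cohorts; the imaging round-trip
uses 200 neurons over a ~20 min session at 5 Hz; decoders run 100
iterations (50 for the within-session comparison across 8 sessions). These
sizes give stable Monte-Carlo estimates while keeping the full suite quick
to re-run. For the labeled-vs-unlabeled comparison the generator uses weak
tuning (action amplitude 0.12, noise 4) so both populations decode below
ceiling — at ceiling the comparison is uninformative — matching the
sub-ceiling single-session accuracies such recordings actually produce.

## Known limitations

- The task engine models only the final training stage; shaping curricula,
  reward-volume control, and display calibration are out of scope.
- The permutation test's pooled observed statistic weights animals by
  trial count; the equal-weight per-animal mean is reported but not used
  as the test statistic.
- Bouton analyses assume a common stimulus schedule across boutons of a
  session; across-bouton correlations (shared neuropil, vascular
  artifacts) are not modeled, so the 5% null flag rate is an independence
  result.
- The decoder treats ROI responses as exchangeable across sessions when
  building pseudotrials; real session-to-session gain differences would
  add variance the generator does not emulate.
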