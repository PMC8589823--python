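# Methods

`surgact` implements an unsupervised surgical-activity-recognition pipeline
for trajectories recorded on a virtual-reality hysteroscopy simulator: a
video sequence X = {x_t} and a time-aligned categorical sensor stream
Z = {z_t}, to be labeled per frame with one of six activities of a
hysteroscopic myomectomy — *diagnosis*, *position hysteroscope*, *cutting*,
*coagulation*, *clear view*, *handle chips*. Because activity annotations
are expensive, only one fully annotated sequence is assumed; everything
else is learned self-supervised or initialized from domain knowledge.

## Self-supervised progress regression (RSP)

The pretext task regresses, from video alone, the remaining surgery
progress

    y_t = 1 − t/τ,   t = 1…τ,

so y_τ = 0 exactly. Labels are free (they follow from the sequence
length), yet a model that predicts them well must implicitly recognize
milestone events such as the end of the diagnostic phase.

The architecture is an encoder–decoder: a per-frame CNN encoder, a
recurrent decoder (GRU by default; LSTM available), and a three-layer MLP
head with PReLU after the first two layers and a sigmoid output so
ŷ ∈ (0, 1). Training minimizes the mean absolute error over whole
sequences with Adam (RMSProp available). At the package's desk scale the
encoder is a three-convolution CNN on 16×16 grayscale frames and the
default learning rate is 1e-3; at full video scale (256×256, pretrained
backbone hooks `alexnet_like` / `resnet18_like`) the reference setting is
1e-5. Splits are always by trajectory, never by frame.

Because no tensor framework is part of the supported stack, the layers
(`surgact.nn`) are compact numpy implementations with explicit
backpropagation (im2col convolutions, full BPTT through GRU/LSTM).
Gradients are verified against central finite differences in the test
suite; training ~20 toy sequences for 60 epochs takes well under a minute
on one CPU.

## Representation analysis

For each trajectory, internal activations — layer outputs and the
recurrent gate activations, addressed as e.g. `decoder.l1.update` — form a
multivariate trace r_t. The analysis proceeds:

1. **Change-point detection.** PELT with a kernelized mean-change cost
   (`cost(I) = Σ k(x_t,x_t) − (1/|I|) ΣΣ k(x_t,x_u)`); the linear kernel
   reduces to within-segment variance, RBF with median-heuristic bandwidth
   is optional. Channels are standardized per trajectory. The penalty is
   calibrated by bisection (the detected count is non-increasing in the
   penalty) so that on average ten robust change points are reported per
   trajectory, keeping any manual review bounded. Minimum segment length
   defaults to 2 frames (one second at 2 fps).

   *Exactness caveat fixed here:* textbook PELT pruning is not exact under
   a minimum-segment constraint — a dominated candidate may still be
   needed before the dominating split becomes admissible. Pruning is
   therefore delayed by `min_segment` frames, restoring equality with
   unpruned optimal partitioning (property-tested on random series).

2. **Component association.** Where a fully manual workflow would have an
   expert review the video at each detected change point, the package
   scores units automatically against known (planted or annotated) event
   times: standardized mean shift
   |mean(after) − mean(before)| / pooled std in a window around the event,
   averaged over trajectories; units are ranked by this effect size. The
   pipeline additionally validates the top eight candidates by how well
   their discretized onsets match the training events and keeps the best
   (`select_indicator_unit`).

3. **Event indicator.** The chosen unit's trace is discretized into a
   latched binary "diagnosis has ended" observable. Two onset rules are
   provided because gate traces come in two shapes: a baseline-threshold
   rule (first sustained exceedance of baseline mean + k·std; defaults
   k=3, m=3, b=10) for flat traces with a level shift, and a derivative
   rule (first one-step increment above k times the robust scale of past
   increments, with an absolute floor; defaults k=5, baseline=4,
   floor=0.01) for traces that also drift with surgery progress — which is
   what trained gates look like here, since every unit tracks progress to
   some degree and the event appears as a sharp jump riding on that trend.
   The pipeline uses the derivative rule at toy scale.

The "end of first cut" event is tracked by the same machinery under the
event name `first_cut_end` but is not wired into the default recognition
model.

## Explicit-duration HSMM

States are the six activities. Dwell time in state s is 1 + NB(r_s, p_s)
(an activity occupies at least one frame; the negative binomial
accommodates large between-trial duration variance), truncated at d_max
and renormalized. d_max defaults to the smallest bound covering 99.9% of
every state's mass, capped at the sequence length; an explicit d_max is
used as given. Transitions are categorical with a zero diagonal (leaving
a state is decided solely by the duration model); all-zero rows mark
terminal states. Emissions are per-state products of per-channel
categorical distributions.

Inference is exact and in log space. The explicit-duration Viterbi
recursion maximizes over the last segment's duration and predecessor
state; the forward recursion replaces max with log-sum-exp. The final
segment is scored with its full (renormalized) duration pmf — the same
convention as the sampler and the forward pass, so the brute-force oracle
tests close; a survival-function alternative is switchable
(`final_censoring="survival"`). Ties break toward the lower state index,
then the shorter duration. Symbols with zero probability under every
state abort decoding with the frame and channel named; an optional
epsilon-smoothing flag redistributes 1e-8 mass for robustness runs.

Only the emission tables are estimated from data: Dirichlet-MAP from the
single annotated sequence,

    B[s,c,v] = (n_scv + α_v − 1) / (N_sc + Σα − K),

with α ≥ 1 required (α = 2 by default; α = 1 reduces to empirical
frequencies and demands every state be observed). Initial distribution,
transition matrix and duration parameters are supplied as expert
initialization — in the synthetic study they equal the generator's own
task graph (uniform over allowed edges) and duration parameters, with an
initial distribution of 0.5/0.5 on diagnosis and position hysteroscope to
model the expert's uncertainty about what a recording starts with.

**SensorHSMM vs UpdateGateHSMM.** The two compared models differ only in
their observables: the SensorHSMM sees the categorical sensor channels;
the UpdateGateHSMM additionally sees the diagnosis-ended indicator. The
indicator channel's emission row is set by construction rather than
estimated: P(1|diagnosis) = 0.05, P(1|position hysteroscope) = 0.8, and
P(1|any later activity) = 0.95. The reduced value for position
hysteroscope models detection latency — a latched onset that fires a few
frames late places those frames, which read 0, inside the activity
immediately following the diagnosis. Count-based MAP estimation of this
engineered feature was tried and rejected: with a single annotated
sequence, the prior mass produces spurious per-state differences whose
sign is random across runs.

## Synthetic cohort (what it emulates, and what it does not)

The real simulator dataset is private, so the generator produces
structurally matched stand-ins:

- **Task graph.** diagnosis → position hysteroscope → cutting, then an
  operative loop over {position hysteroscope, cutting, coagulation, clear
  view} with uniform transitions, absorbing into handle chips. Every
  trajectory starts with diagnosis and ends with handle chips
  (configurable off).
- **Durations** (frames at 2 fps; mean = 1 + r(1−p)/p): diagnosis
  NB(22, 2/3) (mean 12; overdispersed relative to a geometric but with a
  light left tail, so near-instant diagnoses are rare), position
  hysteroscope NB(3, .5) (mean 4), cutting NB(5, .5) (6), coagulation and
  clear view NB(3, .5) (4), handle chips NB(6, .5) (7). Expected
  trajectory length ≈ 48 frames (≈ 24 s of procedure at 2 fps),
  computable in closed form from the absorbing chain
  (`GeneratorConfig.expected_length`).
- **Sensors.** Four categorical channels (3, 2, 4, 3 symbols) standing in
  for pedal/valve/position-derived observables; each activity prefers one
  symbol per channel with probability 0.7. Deliberate ambiguity:
  diagnosis, position hysteroscope and handle chips share identical
  emission tables (`ambiguity_pairs`), encoding that tool usage looks the
  same from the sensors during inspection, repositioning and chip
  handling — exactly the confusions the sensor-only model should exhibit.
- **Video.** 16×16 grayscale; global intensity drifts linearly with t/τ
  (so progress is decodable) under a per-trajectory gain (±25%) and
  offset (±0.08) jitter emulating lighting/contrast variation — which
  makes the drift alone an unreliable progress cue and rewards the use of
  content landmarks; a bright square "tool" blob (amplitude 0.6, side
  video_size//3) appears at the planted diagnosis-end frame and stays
  (the hysteroscope entering the camera picture); Gaussian pixel noise
  (σ = 0.02); clipped to [0, 1].
- **Reproducibility.** One random stream per trajectory, spawned from the
  master seed by a counter; datasets regenerate bit-identically from
  their manifest.

What passing tests on this cohort do **not** show: photorealistic
hysteroscopy, event-driven sensor timing (streams are emitted
frame-aligned; the real recording logs on change), continuous kinematics,
or the magnitudes of any real-data scores. The synthetic benchmark is
designed to exhibit the *direction* of the model comparison — an
indicator derived from learned representations pins the diagnosis
boundary that the sensors cannot see, which both fixes the diagnosis IoU
directly and removes parses in which the sensor-only model lets the
diagnosis or its ambiguous neighbors swallow later segments.

## Evaluation

Per-activity IoU is computed on frame sets (hence invariant to interval
splitting): |pred ∩ truth| / |pred ∪ truth|, defined as 1.0 when the
activity occurs in neither (a flag excludes such trajectories instead).
Mean IoU aggregates across trajectories with the sample (n−1) standard
deviation. Timeline bar plots render per-trajectory segmentations for
side-by-side comparison, plus a prediction-vs-annotation overlay.

## Numerical and design choices

- All HSMM and change-point arithmetic in float64 log space; log(0) is
  clamped to −1e8 so impossible options never poison the DP with NaNs.
- Viterbi/forward cost O(τ · S · d_max) per sequence via per-state
  cumulative emission log-probabilities.
- Segment costs in PELT come from prefix sums (linear kernel) or 2-D Gram
  prefix sums (RBF), O(1) per query.
- The annotated sequence defaults to the first trajectory containing all
  six activities: MAP emissions for a state absent from the annotation
  would be pure prior.
- The toy training cohort is 20 training + 20 held-out trajectories; the
  model-comparison cohort is 19 (one annotated + 18 evaluated),
  mirroring a study design in which 18 trials carry expert annotations
  for two key activities. These sizes keep the full test suite around
  half a minute.

## Known limitations

- Event-encoding strength varies across training runs: with some seeds no
  gate unit yields an onset hit rate above ~0.6, even though the progress
  regression itself converges. The onset-validated unit selection
  mitigates but does not remove this.
- No EM/Baum–Welch re-estimation: emissions come from MAP initialization
  only, transitions/durations from expert initialization.
- Continuous (e.g. Gaussian) emission channels are out of scope; the
  recognition models are restricted to categorical observables.
- The pretrained-backbone encoder options are configuration hooks that
  require externally supplied weights; no weights are bundled.
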