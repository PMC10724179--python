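# Methods

This package reproduces, as a tested pipeline, an in-silico research
program: recurrent actor-critic agents are trained by reinforcement on
simulated interval-timing and working-memory tasks, their hidden-unit
activity is recorded with weights frozen, and the recordings are passed
through the analysis battery used in the time-cell / ramping-cell
literature.  Everything below is the package's own account of what is
computed and which choices were open.

## Tasks

All environments are discrete-time and episodic, with the standard
`reset()` / `step(action)` protocol.

**DDC (delayed duration comparison).**  Two stimuli with durations T1 ≠ T2
drawn uniformly from a fixed set are shown sequentially, separated by a
fixed delay; a single decision step follows, rewarded +1 for naming the
longer stimulus and −1 otherwise.  Observations are one-hot over four
channels {stim1, delay, stim2, go}.  At full scale the durations are
{10, 15, …, 40} steps with a 20-step delay.

**DNMS (delayed non-match-to-stimulus).**  An initiation cue, then a
left/right sample that stays on until the agent touches the matching side
(capped at 20 steps, after which the phase advances anyway), a stimulus-
free delay (40 steps at full scale), and a single choice step.  The
mnemonic variant rewards the non-matching side (+1); the non-mnemonic
variant always rewards "left", removing the memory demand while keeping
the episode structure.  An incorrect choice earns 0 (only the DDC
punishment is part of the original design; the DNMS penalty is exposed in
the config).  Observations are one-hot over five channels {init,
sample-left, sample-right, delay, choice}.

**Spatial DNMS.**  The same trial logic embedded in a 4×7 walled grid
whose walkable cells form an inverted triangle (a wide top row of five
cells and a single bottom apex).  Signals light up at grid cells
(initiation red at the apex, samples green at the top corners); the agent
(blue) must navigate and *interact* at the lit cell to advance.  Six
actions (up/down/left/right/interact/stay); every action costs −5 except
an appropriate interaction; the correct final interaction pays +100.  The
observation is the rendered RGB image of the whole arena (an egocentric
4×7 window is available as a config switch).  A wrong final interaction is
treated as an ordinary penalized action that ends the episode; the choice
phase times out as incorrect at the phase cap, so every episode is
bounded for any action sequence.

## Agent

The agents are rate-coded recurrent networks, written directly in numpy
(forward pass and backpropagation through time alike — no autodiff
framework is used):

* **Shared trunk** (default): input → LSTM (gate order i, f, g, o) →
  linear "memory" layer → separate linear policy and value heads.  The
  policy is a softmax over actions; actions are sampled at temperature 1
  (1.5 during transfer learning, to encourage exploration).  Full scale
  uses 128 LSTM + 128 linear units.
* **Separate pathways**: two disjoint LSTM+linear trunks compute the
  policy and the value with no shared representation; gradient isolation
  between the two parameter sets is asserted by test.
* **Spatial variant**: two convolutional blocks (16 and 32 feature maps,
  2×2 kernels, each followed by 2×2 max pooling at stride 1) encode the
  image; convolutions use same padding (valid pooling alone would
  collapse a 4-row image), and a single learned linear map projects the
  flattened feature maps into the LSTM input (256 units at full scale).

Weights use uniform fan-in initialization, seeded; hidden and cell states
start at zero and are reset to zero at every trial boundary by default.
The no-reset control copies the end-of-trial state into the next trial,
detached from the gradient (backpropagation is truncated at episode
boundaries in any case).  The "activity" recorded for analysis is the
hidden-state vector h, not the cell state.

## Training

Single-worker advantage actor-critic, one gradient update per episode
(batch size 1), minimizing

    L = L_π + L_V,
    L_π = Σ_t −log π(a_t|S_t) · (R_t − V̂(S_t)),
    L_V = Σ_t smoothL1(V̂(S_t), R_t),

with the advantage treated as a constant (no gradient through it), the
smooth-L1 threshold at 1, and natural logarithms.  R_t is the
**future-discounted** return computed by the backward recursion
R_t = r_t + γ R_{t+1} with γ = 0.99.  (A past-discounted reading of the
return — summing rewards from the start of the episode up to t — makes
the advantage identically zero before the terminal step in these
terminal-reward tasks and is not learnable; the future-discounted
convention is the one consistent with the tasks being learnable and is
what is implemented.)  Optimization uses Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8).  Two stabilizers are package choices rather than part of the
original recipe: global gradient-norm clipping at 40, and an optional
entropy bonus whose default coefficient is 0 (the printed loss has no
entropy term, and none is needed at the scales used here).  The BPTT
gradients are verified against central finite differences for all three
architectures in the test suite.

### Scales and presets

Full-scale presets reproduce the original settings: 150k episodes for
DDC, 200k for non-spatial DNMS, 80k for spatial tasks; learning rates
1e−5 (DDC), 1e−4 (mnemonic DNMS), 5e−5 (non-mnemonic), 5e−6 (spatial);
5000 recorded episodes; results aggregated by running the pipeline once
per seed.

The REDUCED presets are the package's desk-scale conditions: 64 recurrent
units, DNMS delay 10, DDC durations {3,…,9} with delay 6, at most
30k/40k training episodes, 1000 recorded episodes, and a single matched
learning rate of 1e−3 for all non-spatial tasks (matched so that
learning-speed comparisons between task variants are like-for-like; the
value was chosen by a small grid at this scale).  Training stops early
once the rolling accuracy over the last 1000 episodes reaches 0.96; a
shorter window proved noisy (a lucky streak can end training before the
policy is stable).  Under these presets one DNMS agent trains in well
under a minute on one CPU and one DDC agent in two to three minutes.

Two analyses keep the original 40-step delay even at reduced scale,
because the phenomenon they probe lives on that timescale and no training
bottleneck forces a reduction:

* the **untrained-network control** (no training at all): over a 10-step
  window the untrained LSTM's smooth exponential relaxation is almost
  linear, and about a quarter of units spuriously pass the |r| ≥ 0.9
  ramping criterion — an artifact of the short window, not a property of
  the network.  At 40 steps the control reproduces the expected result
  (essentially all units time cells, none ramping).
* the **mnemonic-demand decoding comparison**: the non-mnemonic agent's
  passive stimulus trace outlives a 10-step delay, so its decay to chance
  is only observable when the delay (40 steps) outlasts the network's
  intrinsic memory.  Both DNMS variants still train in a few thousand
  episodes at the reduced learning rate and unit count.

## Recording and tuning curves

After training, activity is recorded over an analysis window (the
stimulus periods and/or the delay) for N episodes with weights frozen and
actions still sampled from the policy.  Each unit is min-max normalized
by its extrema over all recorded steps (constant units map to 0 — they
carry no temporal signal and the rule keeps the [0, 1] bound;
normalization is idempotent).  Tuning curves λ(t) are trial averages per
time bin (one bin per environment step); occupancy p(t) is the empirical
probability of a recorded step falling in bin t — uniform for fixed
windows, decreasing in t for the ragged DDC stimulus windows, where late
bins are occupied only by long-duration trials.  Incorrect trials are
recorded and kept by default, with correctness stored per trial so either
inclusion mode is available.

## Cell classification

For each unit (always on normalized activity):

* **Temporal information** I = Σ_t λ(t) log₂(λ(t)/λ̄) p(t), with λ̄ the
  p-weighted mean (equal to the plain mean under uniform occupancy).
  Zero-activity bins contribute 0; a zero-mean curve has I = 0.
* **Ramping candidate**: linear regression of λ(t) on t with p ≤ 0.05 and
  |r| ≥ 0.9 — both signs, since ramps go up or down.  Zero-variance
  curves fail (r undefined).
* **Time-cell candidate**: I exceeds the strict 99th percentile of 100
  surrogate curves, each built by circularly rotating every trial's
  activity by an independent uniform offset and re-averaging.  For
  ramping candidates the statistic is computed on the residual after
  subtracting the fitted line — and each surrogate curve is detrended by
  *its own* fit, so the null is subjected to the same transformation.
  The detrended residual is shifted to be nonnegative before the
  information is taken (the formula assumes nonnegative rates); a pure
  line then carries I = 0 and is not double-counted as a time cell.
* **Trial reliability gate**: the Pearson correlation between even-trial
  and odd-trial average curves must exceed the strict 99th percentile of
  the same statistic on the circularly shuffled surrogates.  Both
  candidate kinds require it.

Ragged DDC windows are classified on the maximal-length trials (a common
time axis for the rotation-based shuffles); pooled occupancy-weighted
curves remain available for tuning-curve summaries.  Ties at the
percentile use strict inequality.  On pure-noise populations these
criteria yield ≤ 2% time-cell and ≤ 1% ramping false positives (asserted
by test); on planted populations (σ = 0.1, 500 trials) category counts
are recovered within ±2.

## Joint mutual information

Records are (trial, time-step) pairs — one activity value per recorded
step with the step's stimulus, time, and (spatial tasks) location bin,
one bin per walkable grid cell.  The information formula extends to the
joint grid: I = Σ λ(s,t[,l]) log₂(λ/λ̄) p(s,t[,l]) with empirical λ and
p.  Dimension randomization replaces one variable in every record with an
independent draw from its empirical marginal and rebuilds the map; the
reported randomized score is the mean over 100 draws (a single draw is
noisy).  Significance of the non-randomized score: I must exceed the mean
plus two standard deviations of 100 activity permutations across records.
Population comparisons between raw and randomized scores use
Kruskal–Wallis tests, Bonferroni-corrected across the comparisons made.

## Decoding

**Stimulus.**  At each time step independently, a linear support vector
machine (C = 1, the smallest-assumption reading of "support vector
machine") on the population vector, under stratified 5-fold
cross-validation.  The chance baseline shuffles cell identities *across
episodes* — each unit's activity at a time point is reassigned to a
random episode — and decodes identically.  A per-vector permutation of
unit order (the other possible reading of a cell shuffle) is **not**
chance whenever population-level statistics such as mean activity differ
between conditions, because a linear readout can still use
permutation-invariant features; the across-episode surrogate destroys the
alignment between vectors and labels and is therefore chance by
construction, which is the property the baseline is for.

**Time.**  Ordinary least squares from the population vector to the step
index, trained on a random 60% of pooled vectors and tested on the rest
(minimum-norm solution if the design is singular, logged).  Trial filters
allow training on correct trials only and testing on incorrect trials;
the correct/incorrect comparison uses a two-sided rank-sum test on
absolute errors (the original comparison is graphical; a rank test makes
it checkable).

**Spatial rate maps.**  Occupancy-normalized trial-averaged activity per
walkable cell, with unvisited cells undefined (NaN).

## Lesion and silencing

Targets are selected incrementally: batches of 5 drawn uniformly from the
requested pool (time cells, ramping cells, or any unit), nested across
sizes within a repeat; when the pool runs out, further draws come from
the remaining units.  *Lesioning* forces the targeted units' hidden and
cell states to zero inside the recurrent update, so the perturbation
propagates through the dynamics.  *Silencing* leaves the recurrent update
untouched and zeroes the targets only in the copy of the hidden vector
passed to the downstream linear layers, isolating the direct readout
contribution; with actions held fixed, non-targeted trajectories are
bit-identical to an unperturbed run (asserted by test).  Evaluation
trials are balanced across stimulus conditions, with fresh environment
randomness per trial; a forced-action replay mode exists solely to verify
the perturbation semantics.

## Synthetic planted populations

The generator emulates the statistical motifs the analyses are sensitive
to: single-peaked Gaussian temporal fields at evenly tiled latencies with
width w(latency) = 1.5 + 0.05·latency (fields widen with latency, as in
the recorded populations), linear ramps of random sign, ramp+bump units
(bump amplitude 0.25 so the summed curve still passes the linearity
criterion while the residual carries temporal information), oscillatory
units, i.i.d. noise units, and stimulus-/location-only units for the
information analyses.  Per-trial additive Gaussian noise (default
σ = 0.1) is applied everywhere; activity is clipped at 0 and min-max
normalized.  Condition coding is either identical across conditions,
orthogonal (independent latencies per condition), or decaying (the
condition-specific component shrinks linearly to zero across the window).

What the generator does *not* emulate: recurrent correlations between
units, activity that depends on the agent's actions, non-Gaussian or
temporally correlated noise, and any coupling between coding and reward.
Passing the recovery tests therefore shows that the analysis code
implements its criteria correctly — not that those criteria are robust to
every statistical structure a trained network can produce.

## Known limitations

* A3C's asynchrony is replaced by a single synchronous worker (same
  objective, deterministic given a seed); no multi-process execution.
* The information estimators are plug-in (no bias correction), matching
  the analyses they reproduce.
* Reduced-scale results are qualitative matches, not quantitative
  reproductions of the full-scale aggregates (which pool 50 seeds).
* The spatial task trains much more slowly than the non-spatial ones and
  is exercised end-to-end only through the experiment runner, not the
  routine test suite.
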