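# tempocells

**Time cells and ramping cells in recurrent actor-critic agents.**

Neuroscientists observe *time cells* — neurons that fire at a preferred
moment within an interval — and *ramping cells*, whose rate climbs or
falls steadily across it, and often read them as the brain's clock.  This
package implements an in-silico test of that reading: recurrent
actor-critic networks are trained by reinforcement on simulated
interval-timing (delayed duration comparison, DDC) and working-memory
(delayed non-match-to-stimulus, DNMS, plus a spatial grid-world version)
tasks, their hidden activity is recorded with weights frozen, and the
recordings are analyzed exactly as electrophysiologists analyze neural
data — cell classification, information theory, population decoding, and
targeted in-silico lesion/silencing experiments.  It is intended for
computational-neuroscience researchers who want a reproducible,
desk-scale version of this experimental program.

## The model and the statistics

Agents are LSTM networks (input → LSTM → linear layer → policy π(a|S)
and value V̂(S) heads; a convolutional encoder precedes the LSTM for the
spatial task), trained with single-worker advantage actor-critic on

    L = L_π + L_V,   L_π = Σ_t −log π(a_t|S_t)·(R_t − V̂(S_t)),
    L_V = Σ_t smoothL1(V̂(S_t), R_t),

where R_t is the future-discounted return with γ = 0.99 and the
advantage carries no gradient.  The network and backpropagation through
time are written directly in numpy and verified against finite
differences.

Recorded units are classified with the standard criteria: a unit is a
**time cell** when the temporal information of its tuning curve,

    I = Σ_t λ(t) · log₂(λ(t)/λ̄) · p(t),

exceeds the 99th percentile of 100 circular-shuffle surrogates, and a
**ramping cell** when a linear fit of λ(t) on t has p ≤ 0.05 and
|r| ≥ 0.9 — in both cases gated on significant even/odd trial
reliability.  The same information statistic extends to joint
stimulus × time (× location) grids with dimension-randomization
controls; stimulus decoding uses per-timestep linear SVMs, time decoding
a linear regression; lesioning zeroes units inside the recurrent update
while silencing zeroes them only in the copy sent to the readout.  See
`docs/methods.md` for every formula, convention, and default.

## Worked example

Train a reduced-scale mnemonic DNMS agent (64 LSTM units, 10-step delay)
and evaluate it frozen:

```
$ tempocells train --task dnms --seed 0 --out runs/demo
trained dnms for 3839 episodes; eval accuracy over 500 episodes: 1.000
```

Training stopped once the rolling accuracy over 1000 episodes reached
0.96 (after 3839 episodes here); the frozen policy then chose the
non-matching stimulus on every one of 500 held-out trials.  The same can
be done from Python, continuing into the analysis battery:

```python
from tempocells import run_experiment
man = run_experiment("untrained_control", "REDUCED", seed=0, out_dir="runs")
print(man["summary"]["counts"])
```

which prints

```
{'time_only': 64, 'ramp_only': 0, 'both': 0, 'neither': 0}
```

— the classic control result: in an *untrained* network every recurrent
unit already qualifies as a time cell (reliable, information-bearing
temporal tuning arises from the recurrent dynamics alone) while none
qualifies as a ramping cell.  Other `run_experiment` names cover the
figure-level experiments: `fig2_cells`, `fig3_pathways`, `fig4_mi`,
`fig5_perturb`, `fig6_dissociation`, `fig7_mnemonic`, `fig8_spatial`,
`noreset_control`, `transfer_control`; each writes its tables and a JSON
manifest under the output directory.

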