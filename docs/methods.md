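# Methods

## The model

`tristage` simulates systems memory consolidation as a chain of three
Bayesian Confidence Propagation Neural Networks (BCPNNs): a small, fast
prefrontal working-memory stage (PFC, 50 units in 5 hypercolumns), an
intermediate hippocampal stage (HIP, 250 units, non-modular), and a large,
slow neocortical long-term store (CTX, 500 units in 50 hypercolumns).  Each
rate unit abstracts a cortical minicolumn; a hypercolumn is a group of units
under normalizing lateral inhibition (soft winner-take-all), so activity sums
to one within each hypercolumn.  The hippocampal stage has no columnar
structure and is normalized by a k-winner-take-all rule (k = 13, 5% of 250).

### Support, activity, learning

The support of post-synaptic unit *j* under a projection with gain *g* is

    h_j = g * [ beta_j + sum_k log( sum_{i in H(k)} w_ij * pi_i ) ]

with one log term per pre-synaptic hypercolumn H(k).  For a non-modular pre
population every unit is treated as a singleton hypercolumn, which for
binary kWTA activity reduces the drive to `sum_{i active} log w_ij`.  This
keeps the ratio of weight evidence (H log terms) to the bias (one term) the
same in modular and non-modular stages; with a single log-sum over all 250
HIP units instead, the recency spread of the bias `beta_j = log Lambda_j`
dominates the cued-recall competition and hippocampal memory collapses after
one day.  A structurally silent pre population (e.g. a fully lesioned stage)
contributes no evidence: its drive is flat, not its bias.

Supports relax toward their target with the membrane time constant
tau_C = 1 ms; with 10 ms steps this is effectively instantaneous.  Modular
activities are the per-hypercolumn softmax of the supports; kWTA activities
set the k highest-support units to 1 (ties to the lowest index, for
determinism).

Weights and biases are pure functions of exponentially smoothed activation
estimates: unit rates Lambda_i, co-activation rates Lambda_ij, with

    beta_j = log Lambda_j
    w_ij   = ((1 - l0^2) Lambda_ij + l0^2)
             / (((1 - l0) Lambda_i + l0) ((1 - l0) Lambda_j + l0))

where the background rate l0 = 0.025 bounds the weights from both sides
(maximum anticorrelation weight l0^2).  Adaptation (after-hyperpolarization
and synaptic depression) is a second projection of exactly the same form
with a fast time constant tau_A and a negative gain; it destabilizes
attractors and produces the autonomous replay that drives consolidation.

### Integration

Rate estimates follow `tau dLambda/dt = pi - Lambda` and are integrated with
the exact exponential step `Lambda += (1 - exp(-dt/tau)) (pi - Lambda)`.
Forward Euler is unusable here: the PFC learning constants (5-8 ms) are
shorter than the 10 ms step, and clamping the Euler fraction at one would
collapse prefrontal working memory to a single item, contradicting its
intended 5-7 item span.  `tau = inf` is the frozen sentinel and skips the
update entirely.  Trace updates are algebraically deferred: a phase worth of
steps is folded into the estimates with one matrix product (the smoothing is
a linear recursion), and weights are computed lazily from the traces only
when a projection actually drives something.  This is exact, not an
approximation.

### Trace floors

Associative unit rates are floored at l0 times the stage's uniform prior
(1/M per unit for modular stages, the sparsity A for kWTA), pair rates at
the product of the two unit floors (flooring pairs at the unit floor itself
would give fully-forgotten pairs weights above one).  Adaptation traces
model a biophysical fatigue variable: they relax toward ongoing activity in
*every* phase (only their gain is phase-gated) and are floored at the
stage's resting activity - 1/M for the soft-WTA stages, whose units rest at
the uniform softmax state, and l0 for the kWTA stage, whose losing units are
silent.  Deeper adaptation floors give long-silent units a large "novelty"
bias that fragments replay into single-step flickers.

## Stimuli

Each stimulus has three coordinated binary encodings.  CTX: one active unit
per ten-unit hypercolumn, drawn uniformly (10% activity).  PFC: the CTX
pattern restricted to five designated hypercolumns through a fixed 1-to-1
subset map (hypercolumns 0, 10, 20, 30, 40; any fixed choice is
statistically equivalent).  HIP: the 13 units receiving the largest summed
drive from the active CTX units through a fixed random Uniform(0,1)
connection matrix - a sparsification and pattern-separation transform
emulating the dentate gyrus.  One changed CTX hypercolumn (a 2% pattern
change) changes about 17% of the HIP code; the exact figure depends mildly
on the separator weight distribution, which is a documented sensitivity
knob.

Training runs 39 simulated days of 9 patterns each (three percepts of three
patterns), ids 1-351, plus one unstudied day (ids 352-360) used to validate
the recall thresholds against false positives.

## The simulation cycle

One day is 330 steps of 10 ms - three perception (3 steps) + reflection
(52 steps) blocks and one sleep phase (165 steps) - compressing 24 h by a
factor of ~26,000.  This scales plasticity only, not the neural dynamics.

* **Perception**: all three stages are clamped to the pattern's encodings
  (the idealized limit of feed-forward drive), one pattern per step.  All
  plastic projections learn, including the inter-stage PFC->HIP and
  HIP->CTX associations (tau_L = 20 ms), which learn *only* here, while
  both ends are clamped, and are frozen while driving.
* **Reflection**: PFC free-runs under its (frozen) auto-association against
  adaptation and rehearses the day's percepts; its replay drives HIP
  through the forward projection (kWTA) and CTX through the fixed subset
  map (softmax).  HIP and CTX associative traces learn from the reinstated
  activity; learning continues through convergence and depression, with no
  wait-for-convergence gating.
* **Sleep**: PFC is silenced and forgets overnight (tau_L = 5 ms onto
  uniform activity); HIP free-runs under auto-association and adaptation,
  replaying stored patterns, and drives CTX through the learned
  back-projection; CTX slowly accumulates the reinstated patterns
  (tau_L = 18,500 ms, six scaled days).

Per-phase gains and time constants follow the reference gating table; the
PFC perception learning constant is 5 ms (the per-phase table takes
precedence over the stage-level 8 ms where they conflict, and both are
exposed in the configuration).

## Recall

Recall is tested with plasticity fully frozen.  The CTX cue is the
pattern's encoding; PFC and HIP cues are its images under the fixed forward
maps (for an intact system, exactly the stored encodings).  Each stage then
relaxes independently under its auto-association (adaptation off) until the
per-step activity change falls below 1e-6 (max 50 steps; non-convergence is
flagged and the distance still computed).  The distance between cue a and
converged state b is half of one minus their cosine; a pattern counts as
recalled when d < Theta with stage thresholds 0.093 / 0.252 / 0.383
(PFC / HIP / CTX).  `optimize_threshold` regenerates boundaries per run by
minimizing the summed type I and type II error *rates* (rates, not counts:
the 351-vs-9 class imbalance makes the count criterion degenerate).
Combined (behavioral) recall is the disjunction over stages; because PFC
forgets during sleep, its contribution to combined curves uses the
pre-sleep evaluation of the final day.  Where a memory lives makes no
behavioral difference.

An untrained modular BCPNN has exactly uniform weights, so a cue relaxes to
the uniform state at d = (1 - 1/sqrt(10))/2 ~ 0.342 - above the PFC and HIP
thresholds but slightly inside the CTX boundary, which was calibrated on
trained networks where failed cues fall into other attractors (d ~ 0.45).

## Experiments

* **Lesions**: a random fraction of HIP units is permanently silenced;
  every connection through a dead unit is nullified and k shrinks to 5% of
  the survivors (round half up).  `timing='after'` probes retrograde
  amnesia on the trained system, `'before'` anterograde amnesia.
* **Plasticity modulation**: a multiplier m on the HIP associative rate
  1/tau_L.  A constant boost (factor 2, "halving tau_L") applies while the
  target percept is being learned - its perception steps and the following
  reflection, since that is where the hippocampal trace is actually built.
  A decaying suppression (factor 0.1) follows
  `m(t) = 1 - (1 - f) 2^(-(t - t_onset)/T_half)` from the target percept's
  onset, with the 2 h pharmacological half-life scaling to ~275 model ms.
* **Sleep deprivation**: every sleep phase shortened by a fraction
  (50% -> 82 steps, floor).

## Reproducibility and problem sizes

All randomness (patterns, separator, lesion selection) derives from one
seed; runs are bit-identical given seed and configuration.  Batch drivers
spawn per-run seeds from a master seed so experiment and control batches
share patterns and differ only in the manipulated factor.  The test suite
and the acceptance script use batches of 20 full 39-day runs (a few seconds
each) for the stochastic statistics, 6-run batches for the lesion
gradients, and 1000 pattern pairs for the separation statistic.

## Known limitations

* **Compressed consolidation window.**  HIP traces are plastic for 165
  steps/day at tau_L = 400 ms, i.e. they decay by e^-4.1 per day, while the
  usable weight signal range above the l0^2 regularization is ~7.4 e-folds.
  Hippocampal memory lifetime is therefore bounded at about two days
  regardless of trace strength, and the consolidation window is compressed
  accordingly (neocortical recall peaks at roughly 4-10 days only because
  CTX itself retains what the first two nights transfer).
* **Few, long sleep reinstatements.**  With tau_A = 400 ms the
  competitor-cooling clock allows only one or two hippocampal attractor
  transitions per 1.65 s sleep phase, so CTX reinstatement events are long
  and few rather than many and short.  Event statistics in the ~6 Hz /
  ~100 ms regime would require the driven-stage overlap to hover near the
  90% detection threshold, which the saturating softmax does not produce.
* **Scale-free competition.**  kWTA ranking and attractor competition are
  invariant to the overall magnitude of a trace, so moderate (factor 2-10)
  plasticity modulations change encoding strength without reliably changing
  which pattern wins recall or sleep replay.  The modulation experiments
  therefore show the expected sign at the trace level but weak behavioral
  effects.
* The stimulus generator produces statistically exchangeable random
  patterns with independent hypercolumns; real sensory codes are
  correlated, so capacity and interference figures here are optimistic
  relative to natural stimuli.  Passing tests demonstrate the mechanism,
  not performance on realistic input statistics.
* Spiking dynamics, oscillatory (theta/gamma) structure, REM sleep and
  hippocampal reconsolidation during replay are out of scope.
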