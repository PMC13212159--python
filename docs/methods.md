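# Methods

This note documents the models, the synthetic-data generator, the
numerical machinery and the design choices behind `banditlab`.

## Task model

The task is a restless four-armed bandit.  Arm `i`'s latent mean reward
follows a mean-reverting Gaussian random walk,

    mu[0, i] ~ Uniform(1, 100)
    mu[t, i] ~ Normal(lam * mu[t-1, i] + (1 - lam) * 50, sigma_d)

with defaults `lam = 0.9836`, `sigma_d = 2.8` (points).  The reward shown
on a trial is `r ~ Normal(mu, sigma_o)` with `sigma_o = 4`, rounded to an
integer and clipped to [1, 100].  The latent means are deliberately left
unclipped: clipping only the displayed reward keeps the walk's stationary
distribution exact (mean 50, s.d. `sigma_d / sqrt(1 - lam^2)` per arm)
while matching what a participant could actually observe.  Blocks are 150
trials; every participant-block gets a fresh schedule.

Rewards enter every model on the points/100 scale (0.01–1).  This keeps
absolute prediction errors below 1, which in turn keeps the Pearce–Hall
variable learning rate inside [0, 1] without extra constraints.

## The model ladder

All models expose one step interface: a state (values `Q`, choice kernel
`c`, hidden states where applicable), an update that consumes the previous
trial's action and reward, and pre-softmax logits for the next choice.
The first trial is included in the likelihood; its inputs are a zero
action encoding and the mid-scale reward 0.5 (the models have no previous
trial to condition on, and a fixed neutral placeholder keeps the
likelihood well-defined there).  A missed trial contributes nothing to the
loss and its latent update is skipped entirely — state is carried forward
unchanged — because nothing is known about how a missed trial is consumed.

### Tabular Q-learning variants

The mechanisms are: biased delta-rule update
`Q(a) += alpha*(r - Q(a)) + b`; perseveration `c(prev action) = kappa`
(zero elsewhere); exponential forgetting `Q <- (1-f)*Q + f*Q_init`; and
the Pearce–Hall variable learning rate
`alpha' = w*|delta| + (1-w)*alpha`.  Policy: `softmax(beta * (Q + c))`.

Per-trial order of operations: decay first, then the delta-rule update of
the chosen arm from its post-decay value, then the perseveration
overwrite, then the policy for the next choice.  The default decay scope
is the unchosen arms only; an all-arms option exists because both
readings of the decay rule are defensible, and the variant grid treats
the scope as an explicit model dimension:
4 binary mechanism flags (bias, perseveration, free `Q_init`, variable
learning rate) x 3 forgetting scopes (off / unchosen / all) = 48
variants.  `simple_rl` (alpha, beta) and `best_rl` (alpha, beta, f,
kappa, b, Q_init; unchosen-scope decay) are the named anchors.  Variants
without a free `Q_init` initialize values at 0.5 (mid-scale).

Parameter transforms: sigmoid for rates in (0,1), tanh for signed
strengths in (-1,1), softplus for `beta` in (0, inf) — softplus rather
than a relu-style hinge so the gradient stays informative near zero —
and `Q_init` unrestricted.  All transforms round-trip exactly with their
inverses.

### Hybrid neural architectures

`RLANN` keeps Best RL's architecture but replaces both update rules with
two-layer tanh MLPs (reward module: `[Q(a), r] -> Q'(a)`; action module:
scalar-coded action -> 4-vector `c`).  `ContextANN` adds the full `Q`
vector (reward side) and `c` vector (action side) as inputs.  `MemoryANN`
makes both modules recurrent — the hidden activations from the previous
trial replace the choice-variable inputs, and the `Q(a)` input is dropped
— separating memory variables from choice variables; unchosen values
still decay exponentially toward a trainable reference with a trainable
rate.  `VanillaRNN` is a single fully connected recurrent network over
`[one-hot action, reward, state]` with a linear readout to four logits.

ANN logits are `Q + c` with no inverse temperature (scale lives in the
readout weights).  Hidden states start at zero, `Q` at a trainable
`q_init`, `c` at zero.  The previous action enters size-1 action modules
as the scalar `(a+1)/4`, with 0 reserved for "no previous action"; a
scalar code (rather than one-hot) preserves the published one-unit input
layer while still letting steep tanh units decode arm identity.

## Fitting

Training is behavioural cloning: minimize the negative log-likelihood of
observed choices, by Adam over batches of blocks sampled with
replacement from the training split, with decoupled L2 weight decay on
network weight matrices (not on cognitive parameters or biases).
Tabular parameters are optimized by the same machinery through their
transforms.  Splits are at the participant level (80/10/10 by default),
so held-out evaluation is over unseen participants with unseen
schedules.  Checkpoints are selected by validation NLL.  Per-block
held-out performance is reported as the trial-wise prediction accuracy
`100 * exp(-L_block / n_valid_trials)` — the geometric-mean probability
assigned to the observed choices; chance on four arms is exactly 25%.

Gradients come from a small tape-based reverse-mode autodiff engine on
numpy arrays (`banditlab.autodiff`), sized to this model family: a closed
set of primitives, unrolled over the 150-trial recurrences, gradient-
checked against central finite differences in the test suite.  Desk-scale
defaults (step size 1e-2, batch 32 blocks, 2,000 steps, hidden size 32)
keep a full fit in the minutes range on one CPU; `FULL_SCALE_CONFIG` preserves
the published protocol's hyperparameter scale (1e6 steps, sweeps over
step size, decay, width and batch size) for larger runs.

## Synthetic cohorts

`build_dataset` generates N participants x B blocks x 150 trials with a
fresh schedule per participant-block and participant-level splits; the
desk-scale default is 200 x 2.  Heterogeneity comes from per-participant
parameter priors; the documented default Best-RL population uses
`alpha ~ Beta(mean 0.35, concentration 20)`, `beta ~ LogNormal(log 6, 0.3)`,
`f ~ Beta(mean 0.15, concentration 30)`, `kappa = 0.1`, `b = 0`,
`q_init ~ Normal(0.5, 0.05)` — moderate learning rates, soft-greedy
choice, mild forgetting and perseveration, the ranges typically reported
for this task family.  These priors are an artifact decision: the
reference analysis fits one population-level model and never
parameterizes individual differences.

### The rich-memory teacher

For exercising the model-comparison ordering, a Memory-ANN teacher is
hand-constructed (see `rich_memory_teacher`'s docstring for the exact
weights).  Its reward module tracks the reward history at three
timescales — a fast trace kept in the tanh linear regime (so the
teacher's projection onto the RL-ANN class stays close to a linear delta
rule), a ~10-trial global trace whose timescale matches the value decay
(recoverable from the value vector, i.e. by context-conditioned models),
and a ~100-trial trace that also modulates reward sensitivity through a
saturating gain unit (recoverable only from the hidden state).  The
action module is a plain perseveration bump built from steep-threshold
units.  This stratification is what makes the ladder's rungs
behaviourally distinguishable at desk scale: each architecture can
capture exactly the components its inputs expose.

What the generator does not emulate: response times, per-participant
heterogeneity of the teacher network, education/demographic covariates,
block-order or fatigue effects.  Passing tests therefore show that the
pipeline recovers structure that is present by construction — not that
human data contain that structure.

## Behavioural statistics

Missed trials are dropped from sequences before any metric.  Stay
probabilities are binned by reward change in 10-point bins.  Repeat
streaks are maximal runs, including length-1 runs (chance for iid
uniform four-arm choice is then exactly 4/3).  Cyclic responses are
counted in overlapping windows of four trials containing all four arms
(chance expectation `(n-3) * 4!/4^4`).  LZW compressibility uses the
emitted-code count as the length unit, an initial dictionary of the four
single symbols, and a baseline of 100 matched iid-uniform sequences; the
score is baseline count / observed count.  The lagged logistic
regression uses 20 "bandit-reward" and 20 "other-reward" regressors per
bandit (zero-padded before the block start), a small ridge penalty
(1e-3) against separation, and averages the four per-bandit fits.

## Interpretability

Closed-loop (teacher-forced) runs record `Q`, `c`, `s^(r)`, `s^(a)` per
trial.  PCA is mean-centred over pooled states; each component is
oriented so its score correlates non-negatively with the previous
trial's reward, giving "PC1 = reward sensitivity" a reproducible sign.
Components with explained variance below 1% are ignored by the default
pipeline.  Probes sample rewards across the full scale and states up to
±1.5 s.d. along a chosen PC (21 x 11 grid by default); for feedforward
reward modules the state axis is replaced by previous-value samples
between the 10% and 90% quantiles observed closed-loop.  History
decoding regresses the reward at lag i on the current PC score,
univariately per (PC, lag).  Priming and PC-activity injection iterate
the reward module alone from a fresh zero state.

## Known limitations

* Python-loop unrolling over trials makes training ~100 ms/step on one
  CPU at batch 64; the package targets desk-scale studies, not the
  million-step sweeps of the full protocol.
* The acceptance-scale ordering study uses one seed per model fit; a
  k-replicate sweep (`sweep(..., n_replicates=k)`) is the supported way
  to average out initialization variance.
* Teacher-forced latents after a missed trial carry the pre-miss state
  forward; alternative conventions (e.g. decaying through the miss) are
  not implemented.
* The lagged regression operates in valid-trial time: lags count valid
  trials, not calendar trials, once missed trials are dropped.
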