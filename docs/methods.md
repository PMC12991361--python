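# Methods

`gazerl` implements a family of combined reinforcement-learning and
sequential-sampling models (RL-SSMs) for decisions from experience, in which
eye-gaze data constrains the decision stage. This note documents the model,
the numerical choices, and what the synthetic-data machinery does and does
not emulate.

## Model

### Learning stage

Each option *i* carries a value estimate `Q_i`, initialized at 0.5 and
updated after feedback with a delta rule,

    Q_i <- Q_i + alpha * (R(x_i) - Q_i),

where `alpha` in [0, 1] is the learning rate and `R(x_i)` the subjective
encoding of the displayed outcome `x_i` (points). Feedback is complete in
both built-in tasks — every displayed option's outcome is shown — so all
shown options are updated each trial and the value trajectory is
independent of the agent's own choices.

Outcomes are encoded by a weighted mix of two range normalizations,

    R(x) = (1 - w_rel) * (x - gmin) / (gmax - gmin)
         +      w_rel  * (x - lmin) / (lmax - lmin),

where `gmin`/`gmax` are extremes over all outcomes observed in the session
and `lmin`/`lmax` are the extremes among the outcomes displayed on the
current trial. `w_rel` in [0, 1] interpolates between absolute,
context-independent valuation (0) and fully relative, rank-like valuation
within the trial's context (1). R is always in [0, 1], so Q stays in [0, 1].

Two choices here were genuinely open:

* **Causal (running) global extremes.** The global extremes are running
  minima/maxima over everything observed *up to and including* the current
  trial, updated before that trial's outcomes are encoded. The running form
  is the default because one-step-ahead prediction requires that the state
  at trial *t* depend only on data before *t*; a retrospective whole-session
  normalization is available via `global_mode="fixed"`.
* **Degenerate ranges.** When a range is empty (first trial, or identical
  outcomes within a trial) the corresponding normalized term is defined as
  0.5 — the midpoint keeps the encoding unbiased and continuous as the range
  shrinks to zero.

### Decision stage

Choices and response times come from a linear ballistic accumulator (LBA)
race over the available options. Accumulator *i* starts at
`z_i ~ Uniform(0, A)`, rises linearly at rate `d_i ~ Normal(v_i, s)`, and
the first to reach the threshold `b` wins; RT is the winner's passage time
plus the nondecision time `t0`. The drift SD is fixed at `s = 0.1` (the
model's scaling convention), and the threshold is parameterized as
`b = A + b_sep` with `b_sep >= 0` so the start point can never exceed the
threshold. All times are milliseconds; with thresholds ~10^3 and drifts
~10^-1 this yields second-scale RTs.

The mean drift rates are produced by a **linking function** of the current
Q-values and the trial's proportional gaze. Eight variants are implemented,
crossing linear versus softmax integration of Q with no / additive /
multiplicative gaze (see the table in `gazerl.linking`). The softmax is
taken over the two available options with max-subtraction; it makes drifts
depend only on Q *differences* and keeps them positive. The exact forms of
the multiplicative variants (models 2, 5, 6) follow the `(1 + beta_gaze *
gaze_i)` amplification convention; each `ModelSpec` carries its linking
callable, so alternative forms can be registered without touching the
fitting machinery. In the softmax(Q + gaze) variant the effective gaze
sensitivity is the product `theta * beta_gaze`, which is why that model
behaves multiplicatively despite its additive appearance.

### Likelihood

The joint (choice, RT) likelihood is the standard defective LBA density:
the winner's first-passage density times the survivor functions of the
losers, evaluated at `t = rt - t0`. The drift distribution in the
*likelihood* is the untruncated normal (the standard analytic form); the
*simulator* resets negative drift draws to zero, as is conventional when
generating data. For the softmax-based models drifts are strictly positive
and the discrepancy is negligible; a drift-truncated likelihood variant is
out of scope. The `A -> 0` limit is evaluated analytically
(`P(T <= t) = Phi((t v - b)/(t s))`) below `A = 1e-6` to avoid cancellation.

Numerical guards: per-trial log densities are floored at `ln(1e-29)`
(observations impossible under a candidate vector, e.g. `rt <= t0`, stay
finite for the optimizer); trials with RT < 250 ms or > 10 s are excluded
from the likelihood but still advance the learner, since their feedback was
observed. The simulator resamples trials until the RT lands in that window
and raises after 10,000 attempts per trial so that pathological parameter
vectors surface as errors rather than hangs.

## Estimation

Fits are maximum a posteriori: summed log-likelihood plus independent
priors

| parameter | prior (shape-scale) | support used | role |
|---|---|---|---|
| alpha | Beta(1.3, 3.7) | [0, 1] | learning rate |
| w_rel | Beta(1.1, 1.1) | [0, 1] | relative encoding |
| beta_q, beta_gaze | Gamma(2, 0.5) | [0, 10] | drift scaling |
| theta | Gamma(2, 20) | [0, 100] | softmax inverse temperature |
| A, b_sep | Gamma(6, 100) | [0, 3000] | start bound, threshold separation |
| t0 | Gamma(6, 30) | [0, 1500] ms | nondecision time |

The search runs differential evolution on the natural (bounded) scale with
an explicit population of NP = 100 members (half prior draws, half uniform
box coverage), up to 1000 generations, stopping early after 250 stagnant
generations, followed by a bounded L-BFGS-B polish whose gradients are
batched central differences. The objective is vectorized across the whole
candidate population and all trials simultaneously — the value trajectory
depends on the parameters only through `alpha` and `w_rel`, and the
range-normalized outcome encodings depend only on the data, so they are
precomputed once per sequence. A full 232-trial fit takes on the order of a
second on one CPU, which is what makes the prequential model comparison
below practical. Population convergence tolerance is 1e-4 (relative spread
of population energies), tight enough that the stagnation rule and
generation cap are the effective stopping criteria. Fits of different
participants are independent and reproducible given per-fit seeds.

When a design cannot identify `w_rel` (no transfer test and weak local/
global contrast), it can be clamped with `fixed={"wrel": 0.0}`.

## Model comparison

Models are compared with the accumulative one-step-ahead prediction error
(APE): for each usable observation index i from `n_min = 5` to N - 1, the
model is refit to the first i usable observations and charged
`-ln p(y_{i+1} | y_1..y_i)`; the terms are summed. The comparison never
uses future data to predict the past and penalizes complexity through
realized generalization. Skipped-RT trials neither train nor get predicted,
but their feedback still advances the learner. Per-step optimizer seeds
derive deterministically from (seed, step); warm-starting each step's
population with the previous optimum is on by default (the objective gains
one trial per step). Across participants, models are compared by mean APE,
with one-sample t-tests on per-participant APE differences against the
winning model.

## Synthetic data

The built-in designs mirror the two target experiments: `exp1` (two
4-option contexts; 12 within-context pairs x 5 repetitions = 60 learning
trials; all four context members displayed, two available, full feedback)
and `exp2` (four 2-option contexts; 120 learning trials; transfer test of
all 28 unordered pairs x 4 = 112 feedback-free trials). Outcomes are
`round(Normal(EV, 2))`. Only a few EVs are pinned by the task descriptions
(the duplicated EV-30 option in exp1; the 18-versus-21 incongruent transfer
pair in exp2); the remaining defaults — exp1 contexts {10, 26, 28, 30} and
{10, 12, 14, 30} with identical ranges and opposite skew, exp2 pairs
(15, 18), (21, 24), (27, 30), (33, 36) with a constant 3-point gap — honor
the stated structure and are configurable.

Because the models consume only *proportional* gaze, the generator does not
synthesize fixation sequences. Instead the higher-valued option's gaze
share is drawn from `Beta(m * kappa, (1 - m) * kappa)` with

    m = logistic(gamma0 + gamma1 * (Q_hi - Q_lo) + gamma2 * progress),

defaults `gamma0 = 0.1, gamma1 = 2.0, gamma2 = 0.5, kappa = 5`, and a 2%
chance of a no-fixation trial (both shares exactly 0). These defaults yield
a small positive gaze advantage for the correct option that grows over
learning and with value separation, matching the qualitative pattern in
real gaze data. What the generator does **not** emulate: fixation order and
count, last-fixation biases, spatial/salience biases, and any independent
trial-to-trial gaze variance beyond the Beta noise. Consequently, passing
recovery and comparison tests on synthetic cohorts shows the estimation
machinery is sound under these conditions, not that real gaze data are this
well behaved; in particular, synthetic gaze is more collinear with value
differences than real gaze, which makes `beta_gaze` *harder* to identify
here than with empirical fixations.

## Recovery protocol and problem sizes

The recovery study draws generating vectors from the priors
(rejection-truncated to the optimizer's box, since a generating value
outside the box could never be recovered), simulates each agent on the full
232-trial `exp2` task, refits with the full optimizer budget, and
correlates generating with recovered values. The drift-scaling parameters
and `w_rel` recover well (r typically 0.86-0.97 across cohorts); `theta`,
`A`, and `t0` recover more weakly, as expected for LBA nuisance parameters
and for the `theta * beta_gaze` trade-off in the softmax(Q + gaze) model.
Agents whose prior draw cannot produce RTs inside the admissible window are
replaced by fresh draws.

The packaged acceptance study uses 40-agent cohorts; the APE
self-consistency study uses 30 agents with 30-trial learning prefixes and a
reduced optimizer budget (NP = 20, 60 generations, 20-generation patience,
warm-started). These sizes are the package's own trade-off between
statistical resolution and a test suite that runs in minutes; the same
functions scale to the full 100-agent / full-sequence protocols unchanged.

## Known limitations

* MAP point estimates only; no hierarchical pooling or posterior sampling.
* Static decision threshold; RT speed-up over learning is captured only
  through drift growth, which understates steep empirical RT decreases.
* The likelihood/simulator drift-truncation mismatch noted above.
* Gaze is exogenous: the generator's value-driven gaze is a stand-in for
  measured fixations, not a model of attention.
* Two-accumulator races throughout (both tasks are binary choice); the LBA
  algebra generalizes to K > 2, and the likelihood code already handles it,
  but the gaze generator and task designs are two-option.
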