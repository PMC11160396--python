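# Methods

This note documents the models the package implements, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
option existed.

## The two-stage analysis

The package targets a common question in skill-acquisition research: does
instructing a stimulus-response (SR) mapping change only the early phase of
learning, or does it alter performance after extensive practice?  The
analysis proceeds in two stages, both fitted per participant.

### Stage 1 — exponential law of practice

Response time after `R` prior presentations of a stimulus is modelled as

    RT(R) = RT0 + B * exp(-alpha * R)

* `RT0` (s) — the asymptote, performance in the automatic-execution phase;
* `B` (s) — the difference between initial and asymptotic performance (the
  "head start" that instructions can provide);
* `alpha` (per repetition) — the learning rate.

`R` is 0-based, so performance on the first presentation is exactly
`RT0 + B`.  Parameters are estimated by minimising the summed squared error
(SSE) over trials with particle swarm optimisation (PSO).  Each of the
three parameters may be tied across the two instruction conditions
(feedback-only F vs instructed I+F) or free to differ; the `2^3 = 8`
resulting models form the constraint hierarchy.  Least-squares fits are
compared with

    BIC = k ln(n) + n ln(SSE / n)

where `n` counts fitted observations and `k` the free parameters
(3 + number of freed parameters).

### Stage 2 — diffusion decision model of asymptotic trials

Because an RT-only analysis ignores speed-accuracy trade-offs, the final
repetitions of each stimulus (where behaviour is approximately stationary)
are refitted with the full diffusion decision model: evidence accumulates
with drift `v` (evidence/s, diffusion coefficient fixed at `s = 1`) between
absorbing boundaries a distance `a` apart, starting unbiased at `a/2`;
observed RT adds a non-decision time `t0`.  Between-trial variability uses
the standard full-DDM components: drift ~ Normal(v, sv), start point ~
Uniform over a range `sz` centred on `a/2`, non-decision time ~ Uniform over
a range `st0` centred on `t0` (`t0` is reported as the window midpoint).

Responses are accuracy-coded (correct -> upper boundary), because the
analysis collapses over response sides and stimuli.  Each trial is scored
under a two-component mixture: with probability `1 - p` the DDM density,
with probability `p` (default 0.05) a contaminant that is uniform over the
observed RT range of that participant and condition and makes either
response with probability 1/2 (a maximum-entropy choice, since only the
contaminant RT distribution is specified by the approach this follows).
Maximum-likelihood fits are compared with

    BIC = k ln(n) - 2 SLL.

The constraint hierarchy mirrors stage 1, with the rule that freeing a mean
parameter frees its variability counterpart (`v` with `sv`, `a` with `sz`,
`t0` with `st0`), so `k = 6 + 2 * |free|` for two-condition fits.

### Model comparison

BIC weights follow `w_i ∝ exp(-(BIC_i - min BIC)/2)`, normalised, read as
posterior model probabilities.  Parameter estimates are model-averaged:
`sum_i w_i * theta_i`, with tied fits contributing their shared value.  The
group-level Bayes factor of model A over model B is defined as the ratio of
the mean per-participant weights, `mean(w_A) / mean(w_B)`; a
product-of-ratios reading exists but yields extreme magnitudes, and the
choice is isolated in `group_bayes_factor`.

### Diagnostics

* `llr_slope` — one-sided log likelihood ratio for a negative OLS slope of
  RT on repetition in the final window (evidence of residual learning);
  positive when the fitted slope is negative.
* `llr_ddm` — `log((1 - w_none) / w_none)`: evidence that any DDM
  parameter differs between conditions.
* `rt_quantiles` / `qq_table` — empirical 0.1/0.3/0.5/0.7/0.9 RT quantiles
  per response class against quantiles obtained by numerically inverting
  the fitted model's conditional CDF.
* `condition_param_diff` — per participant, `(theta_F - theta_I+F)`
  divided by the standard deviation of that parameter over all
  (participant, condition) values within the participant's mapping group.
  The normalisation scale is a design choice; z-scaling by the
  across-participant spread keeps parameters on comparable scales.

## Synthetic data

The generator reproduces the structure the analyses assume, so every stage
can be validated by parameter recovery without any behavioural data:

* **Designs.**  Experiment 1: 32 objects, 16 per instruction condition, 40
  repetitions each, 1280 trials; F and I+F blocks alternate (configurable
  starting block) and the mapping ratio 1:1/2:1/4:1/8:1 sets 8/4/2/1 blocks
  per condition with 2/4/8/16 stimuli per block.  Experiment 2: 16 SR
  mappings, 60 repetitions, one instruction condition per participant.
  Within-block stimulus order is a seeded permutation.
* **Learning curves.**  `rt = RT0 + B exp(-alpha R) + eps`,
  `eps ~ N(0, sd)`, truncated below at 0.15 s and above at the 5 s response
  deadline.  Default truth: `RT0 = 0.55 s`, `B = 0.45 s`, `alpha = 0.12`,
  `sd = 0.15 s`.  Accuracy, where needed, follows an exponential rise from
  0.65 to 0.95 — plumbing only, never used for inference.
* **Asymptotic trials.**  Full-DDM samples with default truth
  `v = 5.0`, `a = 1.2`, `t0 = 0.33 s`, `sv = 1.5`, `sz = 0.3`, `st0 = 0.1`,
  plus 5% uniform contaminants.  Drift and non-decision time sit at the
  group means reported for this paradigm; the boundary separation is chosen
  to give asymptotic mean RT near 0.5 s at ~96% accuracy.
* **Full sessions** combine both: curve RTs everywhere except the final
  `ddm_last_k` repetitions (default 10), which are drawn from the DDM per
  condition — exactly the window the stage-2 fits consume.

What the generator does **not** emulate: sequential dependencies (post-error
slowing, block fatigue), stimulus-specific difficulty, learning *within*
the asymptotic window, lapses other than the uniform contaminant, and any
relation between curve noise and diffusion noise.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data misspecification.

## Numerics

* **Wiener first-passage density.**  Evaluated by the classic pair of
  series (small-time image expansion, large-time eigenfunction expansion),
  selecting per evaluation the representation that needs fewer terms for a
  truncation error of 1e-7.  A compiled (numba) elementwise kernel is used
  when available; a pure-numpy implementation of the same series is the
  fallback and reference.
* **Variability integrals.**  Gauss-Hermite over drift, Gauss-Legendre over
  start point and non-decision time; defaults (11, 7, 11) nodes.  The t0
  integral is clipped per trial at the observed RT: the Wiener density
  vanishes for non-decision times at or above the RT, and integrating across
  that kink is what makes naive fixed-node quadrature converge slowly.
  With the clip, doubling all node counts moves the SLL of a few-hundred
  trial data set by well under 0.01.  Hierarchy sweeps use a lighter
  (7, 3, 5) grid: quadrature bias is shared across the specs being compared
  and cancels from BIC differences, and recovery accuracy is verified
  empirically in the acceptance tests.
* **Path simulation.**  Euler-Maruyama with dt = 1e-4 s by default, with a
  Brownian-bridge crossing test inside each step
  (`P(cross) = exp(-2 d0 d1 / dt)`), which removes the O(sqrt(dt)) bias of
  discretely monitored paths; the million-trial distribution then agrees
  with the analytic density to KS ~ 0.002.  Paths still open at the 5 s
  deadline are censored there.
* **Optimisation.**  Global-best PSO (constriction coefficients 0.7298 /
  1.49618), box bounds, seeded restarts, optional Nelder-Mead polish of the
  swarm optimum, optional early stop when the optimum stalls.  Curve
  bounds: RT0 in [0.15, 3] s, B in [0, 5] s, alpha in [0, 3].  DDM bounds:
  v in [-2, 12], a in [0.3, 4], t0 in [0.05, 1] s, sv in [0, 4]; sz is
  searched as a fraction of `a` (<= 0.9) and st0 as a fraction of
  min(0.4, 1.9 t0), which keeps `sz < a` and `t0 > st0/2` throughout.
* **Quadrature refinement of fits.**  The full DDM likelihood has a
  well-known soft ridge along jointly increasing drift, boundary separation
  and drift variability, and a light quadrature is least accurate exactly
  in that extreme-variability corner — accumulated over thousands of
  trials, its error can manufacture a spurious optimum there.
  `DiffusionModel.fit(refine_quad=...)` therefore re-scores every restart's
  optimum under a finer grid (11, 5, 9 in the recovery studies) and
  polishes the winner there; impostor optima lose their quadrature-error
  advantage on re-scoring.  Hierarchy sweeps skip the refinement: all specs
  share the same data and quadrature, so the bias largely cancels from BIC
  differences.  Seeding one swarm particle with closed-form EZ-diffusion
  moment estimates (`ez_diffusion_start`) speeds convergence to the
  plausible region.
* **Hierarchy fitting order.**  The none model is fitted first and its
  optimum is injected into the starting swarm of every larger spec.  A
  nested optimum is feasible for every nesting model, so larger models can
  never end with a worse objective — the dominance property that makes BIC
  comparisons meaningful — while the rest of the swarm still searches the
  full box for genuine condition differences.
* **Degenerate inputs.**  SSE = 0 (noiseless data) is rejected rather than
  mapped to -inf BIC; an all-identical RT set has no contaminant range and
  is rejected; single-condition data reject condition-freeing specs.

## Problem sizes used in validation

Recovery and model-selection checks run at the study's own cell sizes: 16
stimuli x 40 repetitions for curve recovery (50 replicates), 160 trials per
condition for the DDM hierarchy (10 replicates), 2000 trials for the
dedicated DDM recovery check, and one million paths for the
density-vs-simulator agreement.  Optimiser effort for these sweeps (swarm
12-20, 50-80 iterations, single restart with polish) was chosen as the
smallest configuration that reproduces the dominance and recovery
properties; `OptimizerConfig` exposes larger budgets for final analyses.

## Known limitations

* Per-participant fitting only; no hierarchical pooling across
  participants.
* The start point is fixed at `a/2` (plus variability): response bias is
  not estimable under accuracy coding.
* The learning curve assumes homoscedastic Gaussian residuals; RT
  distributions are in reality right-skewed, which least squares ignores.
* The DDM stage assumes stationarity within the asymptotic window;
  `llr_slope` quantifies, but does not correct for, residual learning.
* Group Bayes factors depend on the mean-weight definition documented
  above and are not marginal-likelihood Bayes factors.
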