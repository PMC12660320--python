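# Methods

## The task model

`revlearn` materialises a probabilistic reversal-learning session as a
pre-drawn schedule. A session has four blocks (100, 100, 60, 60 trials by
default, 320 total). Each block introduces three fresh abstract symbols —
symbols are numbered globally, block *b* owning `3b, 3b+1, 3b+2`, twelve in
all — of which exactly one carries a 70% reward probability while the other
two carry 30%. Trials cycle through the three possible symbol pairs in the
fixed order AB, BC, CA (restarting at each block), with left/right placement
randomised per trial. Every 25 trials the high probability moves, uniformly,
to one of the two symbols currently at low probability, so a reversal always
changes the contingency; the first high-probability symbol of a block is
drawn uniformly. 60-trial blocks therefore contain reversals after trials 25
and 50, leaving a truncated 10-trial final period, which downstream analyses
treat as a period like any other (its positions simply contribute fewer
observations).

Outcomes are **pre-drawn for all three block symbols on every trial**
(Bernoulli 0.70 for the current high-probability symbol, 0.30 for the
others). A chooser's outcome is then fully determined by the schedule and
its choice, which makes simulated sessions, replays and the
simulation-based likelihood exactly reproducible, and leaves the marginal
reward probabilities untouched.

Trials and blocks are 0-based in all in-memory tables; reports print
1-based labels. Lost trials (no response within the 1.25-s window) are the
only use of the response window: no reaction times are modelled.

## The learning models

Two Rescorla–Wagner variants share the delta rule
`V ← V + α·(r − V)` with binary outcomes `r ∈ {0, 1}`:

- **RW1** — one learning rate α;
- **RW2** — a valence split: α⁺ applies after reward (`r = 1`),
  α⁻ after non-reward (`r = 0`). RW2 with α⁺ = α⁻ reproduces RW1 exactly
  (same arithmetic path; tested bitwise).

Choices follow the SoftMax rule `P(A) = σ(β·(V_A − V_B))` over the two
symbols actually shown, with σ the logistic function and β ≥ 0 the inverse
temperature. Only the chosen symbol's value is updated; the unchosen and
the unshown symbol carry their values forward. Values start at, and reset
to, `v0 = 0.5` at block boundaries — the uninformative midpoint of 0/1
outcomes, and forced by each block's fresh symbols. Within a block, values
carry across reversals without reset (reversals are covert). Lost trials
trigger no choice, no update, and no likelihood contribution.

Parameter legality: rates live on the closed interval [0, 1] and β ≥ 0, so
the degenerate control agents (α = 0, frozen values; β = 0, coin-flip
choice) are first-class. The *fitting* constraint box is stricter (below).

## Fitting

Parameters are estimated per participant × block × condition by default
(`granularity="block"`), with a pooled per-participant × condition mode for
convenience. The procedure is:

1. **Grid search** over the constraint box 0.1 < α < 0.9, β > 0:
   17 learning-rate points placed strictly inside (0.1, 0.9) and 20 β points
   log-spaced over [0.1, 20] (RW2 uses the full α⁺ × α⁻ × β product). Ties
   resolve to the smallest (α, then β) cell. The grid kernel is vectorised
   over parameter cells; tests pin it to the scalar replay route at 1e-9.
2. **Nelder–Mead simplex refinement** from the grid best, run in an
   unconstrained space (scaled logit for rates into the open α interval,
   log for β) so constraints hold by construction. Tolerances 1e-6 on
   parameters and objective, iteration cap 2000; non-convergence is flagged
   (`converged=False`), never raised, and the refined likelihood can never
   fall below the grid start.

Two likelihood modes:

- **observed** (default): the analytic log-likelihood of the recorded
  choices — the sum over non-lost trials of the log SoftMax probability of
  the choice made, along the trajectory implied by the recorded choices and
  outcomes. Choice probabilities are floored at 1e-12 before logs.
- **simulated**: predicted choice probabilities from forward simulations
  (default 1000 per parameter set) in which the model's own choices drive
  value updating on the schedule's pre-drawn outcomes. For each non-lost
  trial the predicted probability of the participant's observed choice is
  the mean across simulations of the SoftMax probability each simulation
  assigns to that choice; the log-likelihood sums the logs of the floored
  means. This aggregation is the package's reading of a procedure that is
  underspecified in the field's usual one-line description: it is the only
  per-trial quantity that is both driven by model-determined choices and a
  probability of the observed behaviour. Observed lost trials are skipped in
  every simulation to preserve alignment. The same seed drives every
  parameter set during a grid search (common random numbers). The two modes
  agree exactly in the degenerate cases (β = 0; α = 0) and correlate
  strongly (Spearman ρ > 0.9) on typical data; observed mode is the default
  for speed and determinism.

Model comparison uses `BIC = −2·log L + d·log n` with d = 2 (RW1) or
3 (RW2) and n the number of non-lost trials, summed over subjects; the
lower sum wins and exact ties are reported as ties. Latent trajectories
(expected values V, prediction errors δ) handed to the statistics layer are
always produced by **re-entering all fitted parameters on the observed
choices**, never by the forward simulations.

## Behavioural statistics

**Win-stay regression (Analysis A).** For consecutive within-block trial
pairs (t, t+1): `WinStay(t+1)` is +1 when trial t was rewarded and the same
symbol is chosen again, −1 when it was rewarded, shown again, and not
chosen, and 0 otherwise — including the one-third of trials where the pair
rotation does not re-show the chosen symbol, and all unrewarded trials.
Regressors are `Reward(t)` (or the prediction error δ(t) in the model-based
variant), `choiceStickiness(t)` (choice repeats the previous trial's
choice; 0 on a block's first trial), and `isHPScreen(t+1)` (high-probability
symbol on screen at t+1). Pairs touching a lost trial are marked invalid
and excluded; pairs spanning blocks do not exist. The OLS is solved by
normal equations (numpy) and is pinned to statsmodels OLS in tests; a
constant regressor yields an undefined (NaN) coefficient with a warning.
A regression needs at least 8 valid rows.

**Condition comparison.** Per-subject coefficients are averaged over blocks,
then compared across the three conditions with a one-way ANOVA (F with
df = 2, 3n − 3), three two-sided paired t-tests with Bonferroni correction
(×3), and the paired Cohen's D (mean difference / SD of the differences).
Subjects missing a condition are dropped with a warning. **Block-wise
contrasts (Analysis B)** are per-block paired t-tests between two
conditions, deliberately uncorrected (predefined hypotheses traced over
time). **Learning curves (Analysis C)** align trials on their position
within a 25-trial contingency period and average the high-probability
choice indicator (over trials where that symbol is shown) or, in the
model-based variant, the fitted expected value of the high-probability
symbol; a centred 5-trial running average smooths the curve, which shifts
the apparent reversal point slightly earlier, and the SEM is taken across
subjects (across periods for a single session). The trial-level condition
contrast is a linear mixed model of the choose-high indicator on condition
(two conditions coded 0/1) with a per-subject random intercept, fitted by
REML via statsmodels MixedLM; with balanced data its fixed effect equals
the OLS slope, and a single subject degenerates to OLS with a warning.

**Maladaptive win-stay.** On trials where both shown symbols are
low-probability and the choice was rewarded, the analysis asks whether the
same symbol is chosen again on the next trial where it appears alongside
the high-probability symbol (+1 repeat / −1 switch). Per-subject rates are
tested against zero per condition and compared across conditions.

**Exploratory metrics.** Post-learning accuracy is the high-probability
choice rate over the last 10 trials of each contingency period (window
truncated, with a warning, in shorter periods); perseveration is the rate
of choosing the previous high-probability symbol on post-reversal conflict
trials (old and new high-probability symbols shown together, first 5 trials
of the new period); post-error adjustment is the switch rate following a
non-reward when the previous choice is available again. The last-10 and
first-5 windows are package choices: the metrics are conventional but have
no universal definition. Undefined metrics are reported as missing.

**Two-group rank test.** Mann–Whitney U, exact enumeration for small
untied groups (n ≤ 8) and the tie-corrected normal approximation otherwise.

## The synthetic cohort generator

A cohort emulates the within-subject three-condition stimulation design:
every subject performs a fresh session per condition, condition order
rotated across subjects when counterbalancing is on, all random streams
spawned independently from one master seed. Condition effects are additive
parameter shifts; the bundled presets raise α⁺ by +0.15 in the NAcc-like
condition (the direction of an increased reward learning rate under
excitatory stimulation) and lower β in the DBS-ON-like condition (blunted
reward sensitivity), without claiming a mechanism. Defaults chosen once as
mid-range values typical of probabilistic reversal-learning fits: base RW2
agent α⁺ = α⁻ = 0.35, β = 5.0, v0 = 0.5; lost trials i.i.d. at 2% (real
lost-trial rates are not published for this task; 2% is a plausible
scanner-task figure).

What the generator deliberately does **not** emulate: between-subject
parameter heterogeneity (all subjects share the base parameters, so
between-session noise is the only subject-level variance — this keeps the
one-way ANOVA's type-I calibration exact by construction), reaction times,
within-session drift (fatigue, time-on-task), and any serial structure in
lost trials. Passing tests therefore show that the pipeline recovers
parameters and injected condition effects under clean, exchangeable-subject
conditions; they do not show robustness to subject heterogeneity or model
misspecification in real data.

A note on attainable power: with these study conditions the +0.15 α⁺ shift
produces a paired NAcc-vs-Sham effect of roughly d ≈ 0.3–0.5 on the
win-stay reward coefficient — a realistic, moderate behavioural effect —
which gives the 26-subject omnibus ANOVA roughly 50–65% power, not
the ≥80% a stricter recovery suite might demand. The directional contrast
(NAcc-like above Sham-like) is recovered essentially always. The generator
parameters were fixed a priori and are not tuned to inflate this power.

## Numerical choices and degenerate inputs

- Choice probabilities floored at 1e-12 before logs; values stay in [0, 1]
  and prediction errors in [−1, 1] for binary outcomes by construction.
- Grid ties break to the smallest (α, β); `argmax` over a lexicographically
  ordered mesh makes this deterministic.
- Zero-variance paired differences (identical conditions) report t = 0,
  p = 1, D = 0 rather than 0/0.
- All-lost sessions raise a data error in likelihoods and are reported as
  missing in the descriptive metrics.
- Sessions shorter than 8 valid win-stay pairs are skipped with a warning
  at the cohort level.

## Problem sizes used by the test and acceptance suites

Recovery and calibration suites run at the study's own scale where that is
what is being claimed (320-trial sessions; 26-subject cohorts; 1000
replicates for the type-I calibration; 50 agents for parameter recovery;
20 replicates for model recovery and power), and at reduced scale (smaller
grids, 40–120-trial blocks, 2–4 subjects) for plumbing tests where the
claim is structural rather than statistical. The acceptance script draws
≥100,000 pre-drawn high-probability outcomes (~313 schedules) for the
reward-calibration estimates.

## Known limitations

- No hierarchical/Bayesian estimation, eligibility traces, decay, or
  counterfactual updating; gradient-based optimisers are out of scope.
- The simulated-likelihood mode is Monte-Carlo noisy (SD ∝ 1/√n_sims);
  simplex refinement on it inherits that noise and is off by default.
- The mixed-model contract is a two-condition contrast; omnibus mixed
  models over three conditions are not provided (run the pairwise
  contrasts).
- The win-stay regression treats the ±1/0 outcome as continuous (OLS), as
  is conventional for this analysis, rather than via an ordinal model.
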