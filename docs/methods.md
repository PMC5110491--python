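# Methods

This note documents the models implemented in `efficacysim`, their
assumptions, the parameter defaults and why they were chosen, what the
synthetic-study generator emulates, and the numerical choices that matter
for reproducing its behavior.

## Measurement model

Dichotomous adherence (success/failure of person i on exercise j) is
modeled with the Rasch / one-parameter IRT model,
`Pr(X_ij = 1) = logistic(θ_i − δ_j)`. Estimation follows standard GLMM
practice: exercise difficulties enter as fixed effects, person abilities
as zero-mean random intercepts, and no global intercept is fit, so the
difficulties absorb the location and the equation holds as printed.
Abilities are reported as predicted random effects (posterior means).

Two backends satisfy the same contract. The default is the
variational-Bayes binomial mixed GLM from statsmodels (`fit_vb`, with
weakly informative priors: fixed-effect sd 5, log-sd prior scale 2). The
fallback is a ridge-penalized IRLS fit in which the random-effect
variance is updated by a moment (EM-like) step; both recover the
generating difficulty ordering with rank correlation ≥ 0.9 in the suite's
simulations. Because the person sample locates the scale, absolute δ
values are identified only up to the random-effect mean constraint;
comparisons against external estimates should use ordering or shared
shifts. Complete separation (an exercise always passed or always failed)
carries no finite MLE; such difficulties are set to a configurable clamp
(±6 logits by default) with a warning, a deliberate choice because
month-long logs routinely contain always-passed warm-up exercises.

## Declarative memory

Memory chunks carry one behavioral episode with slots for behavior label,
difficulty, ability, effort (all logits), and outcome, plus a list of
presentation times in days. The subsymbolic quantities follow the
standard ACT-R forms: base-level learning
`B_i = ln(Σ_j t_j^−d) + β_i`, noisy activation `A_i = B_i + ε_i` with
zero-mean logistic ε of scale `s`, softmax retrieval probability at
temperature `s`, and blending as minimization of
`Σ_i P_i (1 − Sim(V, V_i))²`.

Choices the equations leave open:

- **Similarity.** `Sim(V, V_i) = 1 − |V − V_i|/range`, clipped to [0, 1],
  with `range` = 4 logits by default. Linear similarity makes the
  blending objective convex with the probability-weighted mean as the
  exact minimizer whenever the value spread fits inside `range`; beyond
  that the clipped objective is minimized numerically (coarse grid plus
  bounded scalar refinement), and the unit tests check agreement with a
  brute-force grid search to 1e−3.
- **Time base and lag floor.** Time is measured in days; lags are floored
  at 0.5 day so that the power law never sees a zero lag (three same-day
  goals receive distinct fractional timestamps 0.1 day apart).
- **Defaults `d = 0.5`, `s = 0.25`.** The community-standard base-level
  decay and noise values; both are configuration fields, since the
  original simulation's exact settings are not published in the article
  text.
- **Noise realization.** ε is drawn once per chunk per retrieval request;
  no permanent per-chunk noise.
- **Retrieval threshold.** None by default: every chunk matching the hard
  constraints (outcome, optionally behavior label) participates in
  blending. Numeric slots are never hard constraints; they act through
  similarity penalties.

## Agent

The agent's processing of one goal (difficulty δ, day t):

1. **Self-efficacy θ**: blended retrieval of the *difficulty* slot over
   chunks with outcome = success. Self-efficacy is what the agent
   remembers having overcome. If no success is retrievable, θ falls back
   to a configured floor (−1 by default) with a warning.
2. **Intended effort Ψ**: blended retrieval of the *effort* slot over
   success chunks whose activation is additionally penalized by
   `(|ability_i − θ| + |difficulty_i − δ|)/range` — recall of efforts that
   earned success in comparable situations. Floored at 0.
3. **Prediction**: `s = logistic(θ + Ψ − δ)`; with Ψ = 0 this is exactly
   the measurement model.
4. **Attempt**: strict comparison `s > threshold`, threshold 0.25 by
   default (a config knob; the default leaves the easy arm's goals
   almost always attempted).
5. **Storage**: the episode is stored as a new chunk. A success at a goal
   harder than the current self-efficacy is stored with effort
   `max(Ψ, δ − θ)`: achievement beyond one's perceived capability is
   attributed to effort, so later effort recall is higher for experiences
   in which the difficulties overcome were well beyond the self-efficacy
   of the time. This attribution is what lets single large mastered
   increments produce durable gains in subsequent performance — the
   mechanism the closed-form impulse model abstracts as γΔ.

**Background experiences.** Pre-program memory is a grid of 2,100 chunks
(21 abilities −1..+1 × 5 difficulties −1.5..+0.5 × 2 efforts {0, 0.25} ×
10 replicates) whose outcomes are Bernoulli with probability
`logistic(ability + effort − difficulty)`, spread uniformly over the 30
days before day 1. A `center` offset shifts both grids to represent a
person whose pre-program mastery history matches a given ability level.

**Model tracing** iterates a participant's recorded goals in day/slot
order, producing (θ, Ψ, s, attempt) per goal and then storing the
*observed* outcome unconditionally — the trace conditions on what the
person actually reported. **Forward simulation** instead samples
outcomes: by default from the agent's own predicted probability, or, when
a true ability is supplied, from the world model
`Bernoulli(logistic(ability + Ψ − δ + u_day))`, the same law that
generates the background experiences. The separation matters: perception
(which drives attempt and effort) and capability (which drives the
outcome) can disagree, and only then do persistent individual differences
in adherence exist in simulated data.

## Impulse model

The closed-form approximation represents self-efficacy gain as decaying
impulses. Only days with at least one achieved goal emit an impulse
`β₁ + γΔ_k` (achievements, not attempts, build efficacy); the stress
`Δ_k = δ̄_k − δ̄_m` compares day k's mean assigned difficulty with the mean
difficulty of the most recent prior successful day, and is 0 before the
first success. The gain sum runs over completed days k = 1..t−1; the
printed upper limit k = t would contribute a zero-lag term `0^−d`, so the
same-day term is excluded. The pre-program intention term α·t^−d shares
the decay d with the gain sum (a config switch allows separating them).

Fitting minimizes squared residuals between observed and predicted
success rates pooled by condition and day — the scale on which fit
quality (RMSE) is reported — using `scipy.optimize.least_squares` (TRF)
with bounds γ ≥ 0, 0 < d ≤ 1, α ≥ 0 and a 5-point seeded multi-start. A
per-trial Bernoulli likelihood objective is available but not the
default. Confidence intervals are normal approximations from the
Jacobian at the optimum, truncated at the bounds; with boundary estimates
(γ = 0) the interval is one-sided by construction. Parameter recovery at
the suite's reference scale (200 pooled replicate studies of 60
participants) returns γ and d within ±50% of the generating values with
a γ interval excluding zero, and covers zero under a γ = 0 truth; at
single-study scale (60 participants) the pooled objective often cannot
distinguish γ > 0 from a compensating (β₁, d), and estimates legitimately
hit the γ = 0 boundary.

## Synthetic studies

`synthesize_study` emulates a three-arm 28-day program: exercise days
Monday/Wednesday/Friday with exactly three goals, meditation days
Tuesday/Thursday/Saturday and Sunday rest generated as calendar entries
but carrying no modeled outcomes. The 46-exercise pool is drawn from a
left-skewed skew-normal (shape −4) rescaled to sd 0.6 and median −0.21
logits, then binned into 14 contiguous levels; abilities are N(0, 0.5²).
The sd choices anchor on the background-experience grid spans, which were
designed to approximate the corresponding empirical distributions.

**Coaching rule.** Advance one level after an all-success day, regress
one level after a zero-success day, hold otherwise, clipped to the level
range. The all-or-nothing variant (regress on *any* failure) was
implemented first and rejected: its stationary point requires per-goal
success ≈ 0.79 (0.5^⅓), which drives every simulated adaptive schedule to
the easiest level — incompatible with adaptive difficulty tracking the
person. The hold state gives a balance point at per-goal success 0.5, so
assigned difficulty tracks θ + Ψ.

**Ramps.** The fixed arms' level-per-day tables are surrogates (the
original programs' tables are not public): easy 1→3 and difficult 4→9
linearly over the 12 exercise days, adaptive starting at level 3. They
are placed in the pool's mid-range, where goals sit at or above baseline
self-efficacy: pilot runs showed that floor-hugging ramps put assignments
below remembered background difficulty, where blended self-efficacy can
only drift down and mastery dynamics never engage. The slopes were chosen
so the fixed ramps straddle the adaptive arm's mean trajectory.

**Engagement disturbance.** In-study outcomes under the agent truth
include a day-level disturbance u_day shared by the day's three goals,
N(0, 1.5²) on the logit scale with AR(1) persistence 0.7 across exercise
days. This emulates two well-documented features of real daily adherence
that independent per-goal coin flips lack: strong within-day correlation
(one does the day or skips it) and multi-day engagement streaks. These
two parameters were calibrated in pilot runs so that the generator
reproduces the qualitative memory signatures observed in real adherence
data — success rising with past success frequency, falling with lag since
last success, rising with the stress increment last overcome — which is
the generator's stated emulation target; without day-grained dependence
the past-success-day count degenerates into elapsed time and carries no
person signal.

**Ground truths.** `rasch-static` draws every trial independently from
the measurement model with exercises assigned uniformly at random across
the whole pool (a linking design: level-ramped assignment leaves some
exercises unattempted and confounds difficulty with person, capping
recovery); `agent` runs the memory agent forward under its arm's
schedule with person-centered backgrounds and the world model above;
`impulse` runs the closed-form process sequentially. All true parameters
are returned in a sidecar for recovery testing.

**What passing tests do not show.** The generator has no dropout, no
missing reports, no meditation-day effects, no within-person learning of
the exercises themselves, and its engagement process is a stationary
AR(1) rather than the structured weekly and life-event variation of real
data. Recovery and signature results on these data demonstrate internal
consistency of the estimators and mechanisms, not performance on the
original trial's records, which are not publicly deposited.

## Signature analyses

For each trial, the frequency covariate is the count of the participant's
earlier days with ≥ 1 success (a flag switches to counting individual
successes); the lag covariate is days since the last such day (trials
before any success are excluded and counted); the stress covariate is the
stress increment Δ of the last successful day before the trial — the rise
in difficulty that participant last achieved — binned at 0.25 logits.
Day indexing is calendar-based (day 1 = Monday) so lags include weekend
gaps. Observed-vs-predicted evaluation pools success rates by condition
and exercise day (successes over goals assigned) and reports RMSE over
the pooled points. Signature direction tests compute rank correlations
over bins holding at least 30 trials, since near-empty tail bins are
dominated by binomial noise; the tests state the simulation sizes they
use (300 participants for the signature directions, 100 adaptive
participants for the schedule-ordering property).

## Known limitations

- Absolute difficulty locations from different estimation conventions
  differ by a constant; only logit differences are meaningful across
  fits.
- The blending similarity, noise settings, and attempt threshold are
  community defaults, not values recovered from the original simulation.
- Whether intended effort enters the success logit as the raw blended
  slot value (implemented) or as a function of the θ–δ gap is left open
  by the source account; the gap enters here only through storage
  attribution.
- The impulse model's γ is weakly identified from pooled means at
  single-study scale; trust interval statements, not point estimates,
  below a few tens of pooled replicates.
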