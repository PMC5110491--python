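# efficacysim

Memory-based modeling of self-efficacy and daily adherence in adaptive
mHealth exercise programs.

Mobile-health coaching apps assign daily behavioral goals (e.g., three
exercises every Monday/Wednesday/Friday over a 28-day program) and can
adapt goal difficulty to each user's performance. Whether a person
attempts and achieves tomorrow's goal depends on their *self-efficacy* —
the belief that they are capable of it — which social cognitive theory
says is built primarily through enactive mastery: succeeding at
progressively harder goals. `efficacysim` implements a computational
account in which self-efficacy is a declarative-memory read-out:
remembered past successes are blended, weighted by recency and frequency,
into an assessment that drives effort, attempt decisions, and predicted
adherence. The package is aimed at computational behavioral scientists
and mHealth methodologists who want to simulate, fit, and probe these
dynamics at the level of individual (participant, day, exercise) trials.

## The models

**Measurement (Rasch / 1-PL IRT).** Person ability θ_i and exercise
difficulty δ_j live on one logit scale, and

    Pr(X_ij = 1) = exp(θ_i − δ_j) / (1 + exp(θ_i − δ_j)).

`fit_rasch` estimates difficulties as fixed effects and abilities as
zero-mean random intercepts of a logistic mixed model (variational-Bayes
backend from statsmodels, with a penalized-likelihood fallback); the
intercept is absorbed into the difficulties so the equation holds as
printed.

**Declarative memory.** Experience chunks (behavior, difficulty, ability,
effort, outcome) gain base-level activation `B_i = ln Σ_j t_j^−d + β_i`
from their presentation history, receive logistic noise, are retrieved
with softmax probability `P_i = e^{A_i/s} / Σ e^{A_j/s}`, and are *blended*:
the value V minimizing `Σ_i P_i (1 − Sim(V, V_i))²`, which under the
linear similarity used here is the retrieval-probability-weighted mean.

**Agent.** For each goal of difficulty δ the agent blends the difficulty
slot of remembered successes into self-efficacy θ, blends the effort slot
of successes at similar (θ, δ) into intended effort Ψ, predicts success
via `logit(s) = θ + Ψ − δ`, attempts when s clears a threshold, and stores
the outcome — which reshapes every later assessment. Model tracing runs
the agent in lock-step with a recorded log; forward simulation lets it
generate its own study.

**Impulse model (closed form).** Each day with at least one achieved goal
emits a self-efficacy impulse `β₁ + γΔ_k`, where the stress
`Δ_k = δ̄_k − δ̄_m` is that day's rise in mean difficulty over the last
previously-achieved day. Impulses decay as a power of lag and sum into
`ς(t) = Σ_{k<t} (t−k)^−d (β₁ + γΔ_k)`, and

    Pr(X_ij = 1) = logistic(β₀ + θ_i − δ_j + α t^−d + ς(t)).

`fit_impulse` recovers (β₀, β₁, γ, d, α) by bounded nonlinear least
squares on success rates pooled by condition and day.

**Study generator.** `synthesize_study` emulates a three-arm, 28-day
trial (adaptive, easy-fixed, difficult-fixed goal progressions; 46
exercises with a left-skewed difficulty pool, median ≈ −0.21 logits;
abilities ≈ N(0, 0.5²)) from a chosen ground truth — static Rasch, the
memory agent, or the impulse process — and returns the full trial-level
log plus a sidecar of every generating parameter.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from efficacysim import synthesize_study, fit_rasch, fit_impulse

records, truth = synthesize_study(n_per_condition=20,
                                  ground_truth="rasch-static", seed=7)
fit = fit_rasch(records)
keys = sorted(truth["difficulties"])
rho = spearmanr([truth["difficulties"][k] for k in keys],
                [fit.difficulties[k] for k in keys])[0]
print(len(records), round(records.success.mean(), 3))   # 2160 0.515
print(round(rho, 3))                                    # 0.884
print(round(fit.ability_variance, 3))                   # 0.206
```

The 60 synthetic participants yield 2,160 trials (60 × 12 exercise days ×
3 goals) with a 51.5% overall success rate; the mixed-model fit recovers
the generating difficulty ordering with Spearman 0.884 at this
single-study size, and the estimated ability variance (0.206) is of the
order of the generating 0.25. At the scale used by the recovery tests
(200 pooled replicate studies, `tests/test_acceptance.py`), fitting the
impulse model to data generated with (β₀, β₁, γ, d) = (0.12, −0.18, 0.23,
0.94) returns estimates (0.111, −0.143, 0.290, 0.793) with pooled RMSE
0.003 and a γ confidence interval [0.185, 0.395] that excludes zero,
while a γ = 0 ground truth yields an estimate of 0 with CI [0, 0.317].

A command-line front end covers the same pipeline:

```bash
efficacysim --seed 7 synthesize --truth agent --n 20 --out study.csv
efficacysim fit-rasch --input study.csv --output fit.json
efficacysim fit-impulse --log study.csv --rasch fit.json --out params.json
efficacysim signatures --log study.csv --out-prefix sig
```

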