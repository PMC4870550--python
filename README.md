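# bayeshaz

Bayesian and classical two-sample tests for equivalence of hazard
functions in right-censored survival data, with a matching Monte-Carlo
power-study toolkit.

## The problem

Given two groups of right-censored survival times
`(X_i, δ_i, z_i)` — observed time, event indicator, group label — the
classical question is whether the two hazard functions coincide.  The
log rank test is close to optimal when the hazards are proportional,
but it loses essentially all power when the hazard ratio *crosses* 1
over follow-up (e.g. a risky therapy that pays off later): early and
late differences cancel in its linear statistic.  Weighted log rank
tests recover some power but require choosing the weight in advance.

## The test

`bayeshaz` implements a Bayesian test that needs no weight choice.  The
data enter through the Cox model with a *time-varying* coefficient,

    λ(t | z) = exp(z·β(t)) λ₀(t),

and the hypotheses are M₀: β ≡ 0 (equivalent hazards) versus
M₁: β ≠ 0.  The log hazard ratio is expanded in a B-spline basis,

    β(t) = η · Σₗ γₗ B_{d,aₙ,l}(t),      η ∈ {0, 1},

with priors η|q ~ Bernoulli(q), q ~ Uniform(0,1), and
γₗ ~ N(0, σ²) truncated to |γₗ| < L, i.i.d.  Inference uses only the
Cox partial likelihood, so the baseline hazard λ₀ never has to be
modelled.  A Metropolis-within-Gibbs sampler draws (γ, η, q) from their
exact full conditionals, and the test reports the posterior inclusion
probability P(η = 1 | data) — equivalence is rejected when it exceeds
0.5.  The spline knots are placed on the data-driven interval between
the larger of the group-wise first event times and the smaller of the
group-wise last event times, where the two-sample comparison actually
carries information.

The package also provides the comparators (log rank,
Fleming–Harrington weighted log rank with pooled-KM weights `S(t-)` and
`1-S(t-)`, and Renyi supremum tests), a simulator for five canonical
hazard-ratio shapes (equivalent, proportional, step, crossing,
diverging) with censoring calibrated to a target rate, and a replicated
power-study driver.

## Worked example

Simulate crossing-hazards data (hazard ratio 0.1 + 0.5t on [0, 6],
baseline rate 0.25, 30% censoring) and test it:

```bash
bayeshaz simulate --model M3 --n 100 --censor-rate 0.3 --seed 7 --out m3.csv
bayeshaz test --input m3.csv --seed 11
```

which prints (abridged):

```json
{
  "post_eta": 0.7923177492057433,
  "reject_equivalence": true,
  "threshold": 0.5,
  "diagnostics": { "acceptance_rate": 0.309, "raw_eta_mean": 0.79 }
}
```

`post_eta` is the estimated posterior probability that the time-varying
coefficient is active, i.e. that the hazards differ; 0.79 > 0.5, so
equivalence is rejected.  On the same dataset the classical tests give

```
log rank   p = 0.655     # blind to the crossing
FH early   p = 0.423
FH late    p = 0.032     # only the correctly-guessed weight works
Renyi late p = 0.052
```

the textbook crossing-hazards picture: the log rank test sees nothing,
the weighted tests work only with the right weight, and the Bayesian
test detects the difference without any weight choice.

Python API equivalent:

```python
from bayeshaz import HazardScenario, sample_dataset, run_test, log_rank
from bayeshaz.bayes_test import McmcConfig

ds = sample_dataset(HazardScenario("M3", censor_rate_target=0.3), 100, 7)
res = run_test(ds, mcmc=McmcConfig(seed=11))
print(res.post_eta, res.reject_null, log_rank(ds).p_value)
```

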