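# Methods

## Model and hypotheses

Data are two-group right-censored survival records
`(X_i, δ_i, z_i)`, `X_i = min(T_i, C_i)`, `δ_i = I(T_i ≤ C_i)`,
`z_i ∈ {0,1}`, observed on a study horizon `[0, τ]` (all observed times
are bounded by τ; the censoring distribution places its remaining mass
at τ, i.e. administrative end of study).  Failure times follow a Cox
model with time-varying coefficient, `λ(t|z) = exp(z β(t)) λ₀(t)`, and
the test is

    M₀: β ≡ 0   versus   M₁: β ≢ 0.

β is assumed smooth (bounded derivatives up to order p on [0, τ]) and
is represented by a degree-d B-spline expansion with `a_n` basis
functions and equally spaced interior knots,
`β(t) = η Σₗ γₗ B_l(t)`, `η ∈ {0,1}`.

## Likelihood

Only the Cox partial likelihood is used; the baseline hazard is never
modelled.  Writing `R(t) = {k : X_k ≥ t}`,

* null kernel: `P₀ = Π_events 1/|R(X_i)|`,
* alternative kernel:
  `P₁(γ) = Π_events exp(z_i β(X_i)) / Σ_{j∈R(X_i)} exp(z_j β(X_i))`.

Because the covariate is binary each risk-set sum collapses to
`n₀(t) + n₁(t) exp(β(t))` with `n_g(t)` the group-g at-risk count, so a
likelihood evaluation is O(E·a_n) after one sort.  Everything is
computed in log space with log-sum-exp, so the kernels stay finite up
to the prior truncation bound |γₗ| = L.  Tied event times (possible in
imported data only; simulated times are continuous) use the Breslow
convention, which reduces to the no-ties formula when ties are absent.

## Priors and sampler

    η | q ~ Bernoulli(q),  q ~ Uniform(0, 1),
    γₗ ~ N(0, σ²) truncated to (−L, L), i.i.d.

Defaults σ² = 1, L = 10, τ = 6.  The truncation constant c_L cancels
in every posterior ratio and is computed only for reporting.

A Metropolis-within-Gibbs sampler cycles through the exact full
conditionals:

1. `γ | η=1, D`: one component-wise Gaussian random-walk Metropolis
   sweep on `P₁(γ) × prior`; proposals outside (−L, L) are rejected.
   `γ | η=0` is an exact i.i.d. redraw from the truncated prior (the
   null kernel does not involve γ), which keeps the chain irreducible
   across η without pseudo-priors.
2. `η | γ, q`: Bernoulli with success probability
   `q P₁ / (q P₁ + (1−q) P₀)`, evaluated as
   `expit(logit(q) + log P₁ − log P₀)`.
3. `q | η`: Beta(1+η, 2−η).

Chains run 1000 burn-in sweeps and keep 200 states thinned by 25.  The
proposal scale starts at `0.4/√a_n` and adapts during burn-in toward a
20–40% acceptance rate (frozen afterwards, so the kept chain is valid
MCMC).  The reported `post_eta` is the Rao-Blackwellized average of the
conditional inclusion probabilities over kept states; the raw mean of
the η draws is kept in the diagnostics (both estimate P(η=1|D); the
conditional average has lower variance).  Equivalence is rejected when
`post_eta > 0.5` (threshold exposed as a parameter).  Identical data,
configuration and seed give bit-identical chains.

The sampler was validated two independent ways: against 1-D quadrature
of the marginal likelihood for a single constant basis function, and
against prior-importance-sampling estimates of the Bayes factor for the
full 5-dimensional basis; agreement is within Monte-Carlo error (~0.01
on the probability scale) in both cases.

## Spline configuration

* Degree 2 with `a_n = 5` basis functions by default.  The
  rate-driven rule `a_n = ⌊(n/log n)^{1/(2p+1)}⌋` is exposed
  (`default_n_basis`) for users who want the sample-size-adaptive
  choice; at the study's sample sizes it gives 1–2 functions, too few
  to represent a crossing, which is why the fixed 5 is the default.
* Knot support `[l_n+ε, u_n−ε]` where `l_n` is the larger group-wise
  minimum event time and `u_n` the smaller group-wise maximum;
  `ε = 1e−6 (u_n − l_n)`.  Outside the support the spline is continued
  as a constant (evaluation clamps to the boundary): risk-set sums must
  be defined at every event time, and clamping preserves nonnegativity
  and the partition of unity.  The alternative convention (basis ≡ 0
  outside the support, making events outside the interval cancel
  between the two kernels) was measured and gives a slightly more
  liberal null — fewer informative events weaken the effective Ockham
  penalty — so clamping is kept.
* Each group must contribute at least one event, otherwise the support
  is undefined and the test raises (an explicit interval can be passed
  for degenerate inputs; a dataset with no events at all falls back to
  [0, τ] with a warning, where the posterior of η correctly returns to
  its Bernoulli(½) prior).

## Simulator

Five named scenarios on `[0, τ=6]`, group-1 hazard ratio `exp(β(t))`:

| name | exp(β(t))                  | λ₀   | character      |
|------|----------------------------|------|----------------|
| M0   | 1                          | 0.25 | equivalent     |
| M1   | 2                          | 0.25 | proportional   |
| M2   | 1 (t<0.7), e^{−1.2} (t≥0.7)| 0.5  | step           |
| M3   | 0.1 + 0.5 t                | 0.25 | crossing       |
| M4   | 3.0 + 1.5 t                | 0.25 | diverging      |

Failure times are drawn by closed-form inversion of the cumulative
hazard (linear, piecewise-linear or quadratic; custom hazard ratios use
adaptive quadrature and bracketed root-finding with 1e−10 tolerances).
Censoring is `C = min(Exp(θ), τ)`: a truncated exponential on [0, τ)
with the remaining mass at τ, so G(τ)=1 and every observed time is
bounded by τ.  θ is calibrated by quadrature plus root bisection
(tolerance 1e−6) so that the expected censored fraction `P(T > C)`,
with T mixed equally over the two groups, hits the requested target; a
target of 0 disables the exponential component (administrative
censoring only).  The achievable range is `[P(T > τ), 1)`; targets
below the administrative floor raise with the attainable range.  Groups
are balanced (odd n puts the extra subject in group 0).

λ₀ is 0.25 except for M2.  At λ₀ = 0.25 the administrative floor for
M2 is 0.393, so the study's 30% censoring target would be unattainable;
M2 therefore uses λ₀ = 0.5, close to the smallest rate that keeps the
target feasible.  This choice also reproduces the published operating
characteristics of all five classical tests under M2 to within
Monte-Carlo error.

What the simulator does *not* emulate about real data: covariates
beyond the binary group, non-exponential or covariate-dependent
censoring, tied recording of event times, left truncation, and
unbalanced arms.  Passing tests therefore demonstrate correctness of
the method under its own model, not robustness to those features.

## Classical comparators

At each distinct event time the standard 2×2 table yields the
increment `d₁ − d·Y₁/Y` with hypergeometric variance
`d (Y₁/Y)(1−Y₁/Y)(Y−d)/(Y−1)`.  The weighted log rank statistic is
`(Σ w (O−E))² / Σ w² V ~ χ²₁` with weights 1 (log rank), `Ŝ(t−)`
(early) or `1−Ŝ(t−)` (late), where Ŝ is the pooled Kaplan–Meier
estimate evaluated at the left limit (the standard convention; using
Ŝ(t) instead changes results at O(1/n)).  The Renyi tests take the
supremum of the running partial sums of the same weighted increments,
standardized by the total variance, with p-values from the law of
`sup |B(u)|` on [0,1] for Brownian motion B: the reflection series
`4 Σ (−1)^k Φ̄((2k+1)q)` for q ≥ 1 and the dual theta series for
q < 1, each truncated at 1e−12 (the law was verified against direct
simulation of Brownian paths).  Comparators reject at p ≤ 0.05.

## Power study

`run_grid` simulates R = 100 replicated datasets per
(scenario, n, censoring) cell and tabulates rejection fractions with
binomial standard errors.  Replicate r of a cell is seeded by
`SeedSequence([master_seed, crc32(cell), r])`, so cells are
reproducible in isolation and independent of execution order.
Replicate-level failures (e.g. an undefined knot support in a sparse
high-censoring replicate — at n = 50 with 70% censoring each group has
about seven events and the group-wise event ranges occasionally fail
to overlap) are excluded and counted; a cell errors if more than 5% of
replicates fail (the acceptance script relaxes this to 20% so that a
sparse cell still reports a fraction, always computed over completed
replicates only).

## Design choices on genuinely open points

* The estimate of P(η=1|D) could be the raw η-mean or the
  Rao-Blackwellized conditional mean; both are computed, the latter is
  reported (same estimand, lower variance).
* The proposal distribution and scale for the Metropolis step are not
  canonical; per-coordinate Gaussian random walk with burn-in
  adaptation is used.
* Spline degree 2 rather than 1 (both are plausible); the choice has a
  negligible measured effect on operating characteristics.
* The Renyi weights are taken equal to the Fleming–Harrington pair;
  supremum tests need a weight and these are the natural companions.

## Known limitations

* With five spline coefficients and ~70 events, the exact posterior is
  mildly liberal: the measured null rejection rate at the 0.5 posterior
  threshold is about 0.09–0.13 rather than the nominal-feeling 0.05.
  This is a property of the prior/model combination (the Ockham penalty
  of a 5-dimensional N(0,1) prior at this information level), not of
  the sampler — the rate is confirmed by exact importance-sampling
  computation of the Bayes factors.  It shrinks as n grows, consistent
  with the test's asymptotic consistency.
* Power collapses under heavy censoring (~70%), where few events fall
  inside the knot support; knot selection is the binding constraint
  there.
* Only two groups and no additional covariates are supported; β(t)
  itself is not estimated or reported beyond the posterior draws (the
  test is a model-choice procedure, not an estimation procedure).
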