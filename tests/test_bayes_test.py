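import numpy as np
import pytest

from bayeshaz import (
    HazardScenario,
    McmcConfig,
    PriorSpec,
    build_basis,
    calibrate_censoring,
    run_test,
    sample_dataset,
)
from bayeshaz.bayes_test import (
    BasisConfig,
    ParameterState,
    _draw_truncated_prior,
    inclusion_probability,
    sample_eta,
    sample_gamma,
    sample_q,
)

from conftest import make_ds
from oracles import constant_beta_posterior_by_quadrature

FAST = McmcConfig(burn_in=200, thin=5, n_keep=200, seed=0)


class TestConditionals:
    def test_q_conditional_is_beta(self):
        rng = np.random.default_rng(0)
        draws1 = np.array([sample_q(1, rng) for _ in range(100_000)])
        draws0 = np.array([sample_q(0, rng) for _ in range(100_000)])
        assert draws1.mean() == pytest.approx(2 / 3, abs=0.005)
        assert draws0.mean() == pytest.approx(1 / 3, abs=0.005)
        assert ((draws1 > 0) & (draws1 < 1)).all()

    def test_inclusion_probability_balanced(self):
        assert inclusion_probability(-3.0, -3.0, 0.5) == pytest.approx(0.5)

    def test_inclusion_probability_odds_nine(self):
        assert inclusion_probability(0.0, np.log(9), 0.5) == pytest.approx(0.9)

    def test_inclusion_probability_q_limit(self):
        # as q -> 1 the prior overwhelms any fixed likelihood deficit
        assert inclusion_probability(0.0, -5.0, 1 - 1e-12) > 0.999

    def test_sample_eta_with_zero_gamma_is_fair_coin(self, toy3):
        basis = build_basis((1.0, 2.0), degree=0, n_basis=1)
        rng = np.random.default_rng(1)
        draws = [sample_eta(toy3, np.zeros(1), basis, 0.5, rng) for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.03)

    def test_prior_c_L(self):
        assert PriorSpec().c_L == pytest.approx(1.0, abs=1e-12)
        assert PriorSpec(sigma2=100.0, L=10.0).c_L == pytest.approx(0.6827, abs=1e-3)


class TestGammaConditional:
    def test_truncated_prior_moments(self):
        prior = PriorSpec()
        draws = _draw_truncated_prior(prior, 50_000, np.random.default_rng(2))
        assert np.abs(draws).max() < prior.L
        assert draws.mean() == pytest.approx(0.0, abs=3 * 1 / np.sqrt(50_000))
        assert draws.var() == pytest.approx(1.0, rel=0.05)

    def test_eta0_update_is_prior_draw(self, toy3):
        basis = build_basis((1.0, 2.0), degree=2, n_basis=5)
        rng = np.random.default_rng(3)
        state = ParameterState(np.zeros(5), eta=0, q=0.5)
        draws = np.array(
            [
                sample_gamma(toy3, state, basis, PriorSpec(), FAST, rng)
                for _ in range(2000)
            ]
        )
        assert draws.mean() == pytest.approx(0.0, abs=3 / np.sqrt(draws.size))
        assert draws.var() == pytest.approx(1.0, rel=0.05)

    def test_eta1_single_group_data_targets_prior(self):
        # with every subject in group 0 the alternative kernel is constant
        # in gamma, so the Metropolis chain samples the prior
        ds = make_ds([1, 2, 3, 4, 5], [1, 1, 1, 1, 0], [0, 0, 0, 0, 0])
        basis = build_basis((1.0, 4.0), degree=2, n_basis=5)
        rng = np.random.default_rng(4)
        state = ParameterState(np.zeros(5), eta=1, q=0.5)
        chain = []
        for _ in range(6000):
            state = ParameterState(
                sample_gamma(ds, state, basis, PriorSpec(), FAST, rng), 1, 0.5
            )
            chain.append(state.gamma)
        chain = np.asarray(chain)[1000:]
        assert chain.mean() == pytest.approx(0.0, abs=0.08)
        assert chain.var() == pytest.approx(1.0, rel=0.15)


class TestRunTest:
    def test_matches_quadrature_oracle_constant_basis(self):
        # one constant basis function: the exact posterior inclusion
        # probability is a 1-D integral; MCMC must agree within MC error
        scn = HazardScenario("M1", censor_rate_target=0.0)
        ds = sample_dataset(scn, 10, 42, theta=0.0)
        oracle = constant_beta_posterior_by_quadrature(ds)
        posts = [
            run_test(
                ds,
                basis=BasisConfig(degree=0, n_basis=1),
                mcmc=McmcConfig(seed=s),
            ).post_eta
            for s in range(6)
        ]
        se = np.std(posts, ddof=1) / np.sqrt(len(posts))
        assert np.mean(posts) == pytest.approx(oracle, abs=max(3 * se, 0.02))

    def test_zero_event_dataset_recovers_prior(self):
        ds = make_ds([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        with pytest.warns(UserWarning, match="no events"):
            res = run_test(ds, mcmc=McmcConfig(seed=0))
        assert res.post_eta == pytest.approx(0.5, abs=0.05)

    def test_single_group_flat_likelihood_recovers_prior(self):
        ds = make_ds([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 0], [0] * 6)
        res = run_test(ds, interval=(0.5, 5.5), mcmc=McmcConfig(seed=1))
        assert res.post_eta == pytest.approx(0.5, abs=0.05)

    def test_seed_determinism_bit_exact(self):
        scn = HazardScenario("M1", censor_rate_target=0.3)
        ds = sample_dataset(scn, 60, 8, theta=0.12)
        a = run_test(ds, mcmc=McmcConfig(seed=99))
        b = run_test(ds, mcmc=McmcConfig(seed=99))
        assert a.post_eta == b.post_eta
        for sa, sb in zip(a.kept_states, b.kept_states):
            assert (sa.gamma == sb.gamma).all()
            assert (sa.eta, sa.q) == (sb.eta, sb.q)

    def test_cumulative_mean_trace_stabilizes(self):
        scn = HazardScenario("M1", censor_rate_target=0.3)
        ds = sample_dataset(scn, 200, 3, theta=0.12)
        res = run_test(ds, mcmc=McmcConfig(seed=5))
        cm = res.diagnostics["cumulative_mean"]
        half = cm[len(cm) // 2:]
        assert np.max(np.abs(half - cm[-1])) < 0.05

    def test_decision_matches_threshold(self):
        scn = HazardScenario("M1", censor_rate_target=0.3)
        ds = sample_dataset(scn, 80, 2, theta=0.12)
        res = run_test(ds, mcmc=McmcConfig(seed=2))
        assert res.reject_null == (res.post_eta > 0.5)

    def test_acceptance_rate_in_healthy_band(self):
        scn = HazardScenario("M3", censor_rate_target=0.3)
        ds = sample_dataset(scn, 100, 4, theta=0.1)
        res = run_test(ds, mcmc=McmcConfig(seed=3))
        assert 0.1 < res.diagnostics["acceptance_rate"] < 0.6

    def test_posterior_trend_with_sample_size(self):
        # evidence for the alternative grows with n under crossing
        # hazards and shrinks (or stays low) under equivalence
        reps = 12
        means = {}
        for model in ("M3", "M0"):
            scn = HazardScenario(model, censor_rate_target=0.3)
            th = calibrate_censoring(scn)
            means[model] = []
            for n in (50, 100, 200):
                vals = [
                    run_test(
                        sample_dataset(scn, n, 1000 + 17 * r, theta=th),
                        mcmc=McmcConfig(seed=2000 + r),
                    ).post_eta
                    for r in range(reps)
                ]
                means[model].append(np.mean(vals))
        m3, m0 = means["M3"], means["M0"]
        assert m3[0] <= m3[1] + 0.05 and m3[1] <= m3[2] + 0.05
        assert m0[2] <= m0[0] + 0.10
        assert m3[2] > 0.7
        assert m0[2] < 0.5
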