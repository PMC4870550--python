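import numpy as np
import pytest
from lifelines.statistics import logrank_test

from bayeshaz import (
    HazardScenario,
    calibrate_censoring,
    log_rank,
    renyi_test,
    sample_dataset,
    weighted_log_rank,
)
from bayeshaz.classical_tests import _sup_brownian_pvalue

from conftest import make_ds, random_dataset
from oracles import hypergeometric_log_rank


@pytest.fixture
def identical_groups():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 1, 0, 1]
    return make_ds(t + t, e + e, [0] * 4 + [1] * 4)


class TestLogRank:
    def test_identical_groups_no_signal(self, identical_groups):
        res = log_rank(identical_groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_against_table_enumeration(self):
        ds = make_ds([1, 3, 2, 4], [1, 1, 1, 1], [0, 0, 1, 1])
        u, v = hypergeometric_log_rank(ds.time, ds.event, ds.group)
        res = log_rank(ds)
        assert res.statistic == pytest.approx(u**2 / v, abs=1e-10)

    def test_agrees_with_lifelines(self):
        for seed in range(20):
            ds = random_dataset(np.random.default_rng(seed), n=40)
            if ds.n_events == 0 or not ds.has_both_groups():
                continue
            ours = log_rank(ds)
            ref = logrank_test(
                ds.time[ds.group == 0], ds.time[ds.group == 1],
                ds.event[ds.group == 0], ds.event[ds.group == 1],
            )
            assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_strong_proportional_effect_detected(self):
        scn = HazardScenario("M1", censor_rate_target=0.3)
        th = calibrate_censoring(scn)
        hits = sum(
            log_rank(sample_dataset(scn, 1000, s, theta=th)).p_value < 1e-3
            for s in range(20)
        )
        assert hits >= 19

    def test_no_events_errors(self):
        ds = make_ds([1, 2], [0, 0], [0, 1])
        with pytest.raises(ValueError, match="no events"):
            log_rank(ds)


class TestWeightedLogRank:
    def test_unit_weight_equals_log_rank(self):
        ds = random_dataset(np.random.default_rng(11), n=30)
        a = weighted_log_rank(ds, "unit")
        b = log_rank(ds)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-14)

    @pytest.mark.parametrize("weight", ["km", "one-minus-km"])
    def test_identical_groups_null(self, identical_groups, weight):
        assert weighted_log_rank(identical_groups, weight).statistic == pytest.approx(
            0.0, abs=1e-12
        )

    @pytest.mark.parametrize("weight", ["km", "one-minus-km"])
    def test_six_subject_brute_force(self, weight):
        ds = make_ds([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1], [0, 1, 0, 1, 0, 1])
        time, event, group = ds.time, ds.event, ds.group
        # direct summation with pooled left-limit KM weights
        s = 1.0
        U = V = 0.0
        for t in np.unique(time[event == 1]):
            at = time >= t
            y, y1 = at.sum(), (at & (group == 1)).sum()
            d = ((time == t) & (event == 1)).sum()
            d1 = ((time == t) & (event == 1) & (group == 1)).sum()
            w = s if weight == "km" else 1 - s
            U += w * (d1 - d * y1 / y)
            if y > 1:
                V += w**2 * d * (y1 / y) * (1 - y1 / y) * (y - d) / (y - 1)
            s *= 1 - d / y
        res = weighted_log_rank(ds, weight)
        assert res.statistic == pytest.approx(U**2 / V, abs=1e-10)


class TestRenyi:
    def test_identical_groups_null(self, identical_groups):
        res = renyi_test(identical_groups, "early")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("weight,wlr", [("early", "km"), ("late", "one-minus-km")])
    def test_supremum_dominates_endpoint_statistic(self, weight, wlr):
        # the final partial sum is the weighted log-rank numerator, so the
        # supremum statistic is at least the endpoint standardized statistic
        scn = HazardScenario("M3", censor_rate_target=0.3)
        th = calibrate_censoring(scn)
        for seed in range(30):
            ds = sample_dataset(scn, 60, seed, theta=th)
            sup = renyi_test(ds, weight).statistic
            endpoint = np.sqrt(weighted_log_rank(ds, wlr).statistic)
            assert sup >= endpoint - 1e-12

    def test_pvalue_law_against_brownian_simulation(self):
        rng = np.random.default_rng(4)
        paths = np.cumsum(rng.normal(0, 1, (40000, 800)) / np.sqrt(800), axis=1)
        sup = np.abs(paths).max(axis=1)
        for q in (1.0, 1.96, 2.5):
            mc = np.mean(sup >= q)
            # discrete paths slightly undershoot the continuous supremum
            assert _sup_brownian_pvalue(q) == pytest.approx(mc, abs=0.02)

    def test_detects_late_difference(self):
        scn = HazardScenario("M2", censor_rate_target=0.3)
        th = calibrate_censoring(scn)
        ds = sample_dataset(scn, 400, 0, theta=th)
        assert renyi_test(ds, "late").p_value < 0.01


class TestInvariances:
    def test_group_label_swap(self):
        ds = random_dataset(np.random.default_rng(2), n=50)
        swapped = make_ds(ds.time, ds.event, 1 - ds.group, tau=ds.tau)
        for fn in (
            log_rank,
            lambda d: weighted_log_rank(d, "km"),
            lambda d: renyi_test(d, "late"),
        ):
            a, b = fn(ds), fn(swapped)
            assert a.statistic == pytest.approx(b.statistic, abs=1e-10)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-10)

    def test_null_levels_close_to_nominal(self):
        # all five tests on equivalent-hazards data, alpha=0.05
        scn = HazardScenario("M0", censor_rate_target=0.3)
        th = calibrate_censoring(scn)
        R = 500
        hits = dict.fromkeys(["lr", "fe", "fl", "re", "rl"], 0)
        for s in range(R):
            ds = sample_dataset(scn, 100, s, theta=th)
            hits["lr"] += log_rank(ds).p_value <= 0.05
            hits["fe"] += weighted_log_rank(ds, "km").p_value <= 0.05
            hits["fl"] += weighted_log_rank(ds, "one-minus-km").p_value <= 0.05
            hits["re"] += renyi_test(ds, "early").p_value <= 0.05
            hits["rl"] += renyi_test(ds, "late").p_value <= 0.05
        for k, h in hits.items():
            assert 0.01 <= h / R <= 0.10, (k, h / R)
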