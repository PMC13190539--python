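import numpy as np
import pytest

from pyrotier import (default_config, km_estimate, logrank_test,
                      simulate_cohort, survival_rates,
                      three_tier_survival_report)
from pyrotier.errors import DegenerateTestError, NoEventsError
from pyrotier.threshold import ThreeTierRule


def oracle_logrank_chi2(ta, ea, tb, eb):
    """Hand O/E/V table over all distinct event times — independent oracle."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, int)
    tb, eb = np.asarray(tb, float), np.asarray(eb, int)
    times = sorted(set(ta[ea == 1]) | set(tb[eb == 1]))
    O = E = V = 0.0
    for tj in times:
        n1 = (ta >= tj).sum()
        n2 = (tb >= tj).sum()
        d1 = ((ta == tj) & (ea == 1)).sum()
        d2 = ((tb == tj) & (eb == 1)).sum()
        n, d = n1 + n2, d1 + d2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestKM:
    def test_uncensored_steps_and_median(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.survival_prob == pytest.approx([0.75, 0.5, 0.25, 0.0])
        assert curve.median == 2.0

    def test_censored_hand_example(self):
        # times (1, 2+, 3, 4): S(1)=0.75, S(3)=0.75*(1-1/2)=0.375
        curve = km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        assert curve.event_times == pytest.approx([1.0, 3.0, 4.0])
        assert curve.survival_prob == pytest.approx([0.75, 0.375, 0.0])
        assert curve.median == 3.0

    def test_all_censored_flat_at_one(self):
        curve = km_estimate([2, 5, 9], [0, 0, 0])
        assert curve.survival_at(100.0) == 1.0
        assert curve.median is None

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(1)
        t = rng.integers(1, 20, size=100).astype(float)
        curve = km_estimate(t, np.ones(100, dtype=int))
        for tk, s in zip(curve.event_times, curve.survival_prob):
            assert s == pytest.approx((t > tk).mean(), abs=1e-12)

    def test_risk_table_consistent(self):
        curve = km_estimate([1, 2, 2, 3], [1, 1, 1, 0])
        assert curve.n_at_risk.tolist() == [4, 3]
        assert curve.n_events.tolist() == [1, 2]


class TestRates:
    def test_horizon_zero_is_one(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert survival_rates(curve, [0.0])[0]["survival"] == 1.0

    def test_step_function_readout(self):
        curve = km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        rate = survival_rates(curve, [2.5])[0]
        assert rate["survival"] == pytest.approx(0.75)
        assert not rate["extrapolated"]

    def test_extrapolation_flagged(self):
        curve = km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        rate = survival_rates(curve, [10.0])[0]
        assert rate["extrapolated"]
        assert rate["survival"] == pytest.approx(0.0)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = [1.0, 3.0, 5.0, 8.0]
        e = [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_match_hand_table(self):
        ta, ea = [1.0, 2.0, 3.0], [1, 1, 1]
        tb, eb = [4.0, 5.0, 6.0], [1, 1, 1]
        res = logrank_test(ta, ea, tb, eb)
        assert res.chi_square == pytest.approx(
            oracle_logrank_chi2(ta, ea, tb, eb), abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        ta = rng.uniform(1, 20, size=30)
        ea = rng.integers(0, 2, size=30)
        tb = rng.uniform(1, 25, size=25)
        eb = rng.integers(0, 2, size=25)
        ea[0] = eb[0] = 1
        a = logrank_test(ta, ea, tb, eb)
        b = logrank_test(tb, eb, ta, ea)
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_observed_and_expected_totals_match(self):
        rng = np.random.default_rng(3)
        ta = rng.integers(1, 10, size=40).astype(float)
        ea = rng.integers(0, 2, size=40)
        tb = rng.integers(1, 10, size=40).astype(float)
        eb = rng.integers(0, 2, size=40)
        ea[0] = eb[0] = 1
        res = logrank_test(ta, ea, tb, eb)
        assert sum(res.observed) == pytest.approx(sum(res.expected))

    def test_no_events_raises(self):
        with pytest.raises(NoEventsError):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_zero_variance_degenerate(self):
        # group B leaves the risk set before the only event: V = 0
        with pytest.raises(DegenerateTestError):
            logrank_test([5.0], [1], [1.0], [0])

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(4)
        ta = rng.integers(1, 15, size=50).astype(float)
        ea = rng.integers(0, 2, size=50)
        tb = rng.integers(1, 15, size=50).astype(float)
        eb = rng.integers(0, 2, size=50)
        ea[0] = eb[0] = 1
        res = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert res.chi_square == pytest.approx(ref.test_statistic,
                                               rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)


class TestThreeTierReport:
    def test_single_tier_cohort_no_tests(self, default_cohort):
        cohort, _ = default_cohort
        rule = ThreeTierRule(lower=100.0, upper=101.0)
        rep = three_tier_survival_report(cohort, rule)
        assert rep.tiers["unmethylated"].n == len(cohort)
        assert rep.pairwise == {}
        assert any("fewer than two" in w for w in rep.warnings)

    def test_all_tiers_present_gives_three_tests(self):
        cfg = default_config(n=1500, seed=61)
        cohort, _ = simulate_cohort(cfg)
        rule = ThreeTierRule(lower=6.0, upper=14.0)
        rep = three_tier_survival_report(cohort, rule)
        assert len(rep.pairwise) == 3

    def test_median_ordering_matches_generating_effect(self, default_cohort):
        cohort, _ = default_cohort
        rule = ThreeTierRule(lower=8.0, upper=11.0)
        rep = three_tier_survival_report(cohort, rule)
        assert (rep.tiers["unmethylated"].median_os
                < rep.tiers["methylated"].median_os)

    def test_bonferroni_option_scales_p(self):
        cfg = default_config(n=1500, seed=63)
        cohort, _ = simulate_cohort(cfg)
        rule = ThreeTierRule(lower=6.0, upper=14.0)
        plain = three_tier_survival_report(cohort, rule)
        adj = three_tier_survival_report(cohort, rule, bonferroni=True)
        for pair in plain.pairwise:
            assert adj.pairwise[pair].p_value == pytest.approx(
                min(1.0, 3 * plain.pairwise[pair].p_value))
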