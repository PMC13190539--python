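import numpy as np
import pandas as pd
import pytest

from pyrotier import (LogLogisticAFT, build_design, concordance_index,
                      default_config, loglogistic_loglik, simulate_cohort)
from pyrotier.errors import DesignError, NoEventsError, NoPairsError


def intercept_frame(n):
    return pd.DataFrame({"intercept": np.ones(n)})


def simulate_loglogistic(rng, n, eta, sigma):
    return np.exp(eta + sigma * rng.logistic(size=n))


class TestLogLik:
    def test_single_censored_at_eta_equals_log_half(self):
        # z = 0 => log S = -log 2
        ll = loglogistic_loglik([np.log(5.0)], 1.0, [5.0], [0],
                                intercept_frame(1))
        assert ll == pytest.approx(-np.log(2.0), rel=1e-12)

    def test_three_observation_toy_matches_direct_evaluation(self):
        t = np.array([2.0, 5.0, 7.0])
        e = np.array([1, 1, 0])
        eta, sigma = np.log(4.0), 1.0
        expected = 0.0
        for ti, ei in zip(t, e):
            z = (np.log(ti) - eta) / sigma
            if ei:
                expected += z - 2 * np.log1p(np.exp(z)) - np.log(sigma * ti)
            else:
                expected += -np.log1p(np.exp(z))
        ll = loglogistic_loglik([eta], sigma, t, e, intercept_frame(3))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(1, 40, size=30)
        e = rng.integers(0, 2, size=30)
        perm = rng.permutation(30)
        a = loglogistic_loglik([2.5], 0.6, t, e, intercept_frame(30))
        b = loglogistic_loglik([2.5], 0.6, t[perm], e[perm],
                               intercept_frame(30))
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            loglogistic_loglik([0.0], 1.0, [0.0], [1], intercept_frame(1))


class TestFit:
    def test_intercept_only_recovery_uncensored(self):
        rng = np.random.default_rng(1)
        n = 5000
        t = simulate_loglogistic(rng, n, 3.0, 0.4)
        res = LogLogisticAFT(t, np.ones(n, dtype=int),
                             intercept_frame(n)).fit()
        assert res.params["intercept"] == pytest.approx(3.0, rel=0.02)
        assert res.scale == pytest.approx(0.4, rel=0.02)

    def test_methylation_effect_recovered_on_simulated_cohort(self):
        cfg = default_config(n=2000, seed=31)
        cfg.survival_dichotomy_pct = 10.0
        cohort, _ = simulate_cohort(cfg)
        res = LogLogisticAFT.from_cohort(cohort, cutoff=10.0).fit()
        assert res.params["methylated"] == pytest.approx(cfg.b_meth,
                                                         abs=0.1)
        assert res.scale == pytest.approx(cfg.sigma_aft, abs=0.05)
        assert res.converged

    def test_time_scaling_shifts_intercept_by_log_c(self):
        rng = np.random.default_rng(2)
        n = 800
        x = rng.integers(0, 2, size=n).astype(float)
        t = simulate_loglogistic(rng, n, 2.5 + 0.6 * x, 0.5)
        X = pd.DataFrame({"intercept": np.ones(n), "x": x})
        e = np.ones(n, dtype=int)
        a = LogLogisticAFT(t, e, X).fit()
        b = LogLogisticAFT(2.0 * t, e, X).fit()
        assert b.params["intercept"] - a.params["intercept"] == \
            pytest.approx(np.log(2.0), abs=1e-5)
        assert b.params["x"] == pytest.approx(a.params["x"], abs=1e-5)
        assert b.scale == pytest.approx(a.scale, rel=1e-4)

    def test_no_events_raises(self):
        with pytest.raises(NoEventsError):
            LogLogisticAFT([1.0, 2.0], [0, 0], intercept_frame(2)).fit()

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(5), "dup": np.ones(5)})
        with pytest.raises(DesignError):
            LogLogisticAFT(np.arange(1.0, 6.0), np.ones(5, dtype=int), X)

    def test_agrees_with_lifelines_loglogistic_aft(self):
        from lifelines import LogLogisticAFTFitter

        cfg = default_config(n=1200, seed=33)
        cohort, _ = simulate_cohort(cfg)
        res = LogLogisticAFT.from_cohort(cohort, cutoff=9.0).fit()
        X = build_design(cohort.df, cutoff=9.0).drop(columns=["intercept"])
        frame = X.assign(os_months=cohort.df["os_months"],
                         event=cohort.df["event"])
        ll = LogLogisticAFTFitter().fit(frame, "os_months", "event")
        for term in X.columns:
            assert res.params[term] == pytest.approx(
                ll.params_.loc[("alpha_", term)], abs=1e-3)
        # lifelines' shape beta_ is the reciprocal of the AFT scale sigma
        assert res.scale == pytest.approx(
            1.0 / np.exp(ll.params_.loc[("beta_", "Intercept")]), rel=1e-3)


class TestPredict:
    def test_all_zero_row_gives_intercept(self, default_cohort):
        cohort, _ = default_cohort
        res = LogLogisticAFT.from_cohort(cohort, cutoff=8.0).fit()
        row = pd.DataFrame(
            {name: [1.0 if name == "intercept" else 0.0]
             for name in res.model.term_names})
        assert res.predict(row)[0] == pytest.approx(
            res.params["intercept"])

    def test_methylation_flip_changes_eta_by_beta(self, default_cohort):
        cohort, _ = default_cohort
        res = LogLogisticAFT.from_cohort(cohort, cutoff=8.0).fit()
        base = {name: [1.0 if name == "intercept" else 0.0]
                for name in res.model.term_names}
        flipped = dict(base, methylated=[1.0])
        delta = (res.predict(pd.DataFrame(flipped))[0]
                 - res.predict(pd.DataFrame(base))[0])
        assert delta == pytest.approx(res.params["methylated"])

    def test_term_mismatch_rejected(self, default_cohort):
        cohort, _ = default_cohort
        res = LogLogisticAFT.from_cohort(cohort, cutoff=8.0).fit()
        with pytest.raises(DesignError):
            res.predict(pd.DataFrame({"wrong": [1.0]}))


def oracle_concordance(times, events, preds):
    """Exhaustive double loop over ordered pairs — independent oracle."""
    n_pairs = n_conc = n_tied = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if times[i] < times[j] and events[i] == 1:
                comparable = True
            elif (times[i] == times[j] and events[i] == 1
                  and events[j] == 0):
                comparable = True
            else:
                comparable = False
            if not comparable:
                continue
            n_pairs += 1
            if preds[j] > preds[i]:
                n_conc += 1
            elif preds[j] == preds[i]:
                n_tied += 1
    return n_pairs, n_conc, n_tied


class TestConcordance:
    def test_perfect_ranking(self):
        res = concordance_index([1, 2, 3, 4], [1, 1, 1, 1],
                                [0.1, 0.2, 0.3, 0.4])
        assert res.c_index == 1.0

    def test_reversed_ranking(self):
        res = concordance_index([1, 2, 3, 4], [1, 1, 1, 1],
                                [0.4, 0.3, 0.2, 0.1])
        assert res.c_index == 0.0

    def test_tied_toy_example(self):
        # 5 comparable pairs: 3 concordant, 1 tied, 1 discordant
        res = concordance_index([2, 4, 4, 6], [1, 1, 0, 1],
                                [1.0, 2.0, 2.0, 1.5])
        assert res.n_comparable_pairs == 5
        assert res.n_concordant == 3
        assert res.n_tied == 1
        assert res.c_index == pytest.approx(0.7)

    def test_all_censored_raises(self):
        with pytest.raises(NoPairsError):
            concordance_index([1, 2], [0, 0], [0.5, 0.6])

    def test_matches_exhaustive_oracle_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(5, 60)
            t = rng.integers(1, 8, size=n).astype(float)
            e = rng.integers(0, 2, size=n)
            p = rng.integers(0, 4, size=n).astype(float)
            n_pairs, n_conc, n_tied = oracle_concordance(t, e, p)
            if n_pairs == 0:
                continue
            res = concordance_index(t, e, p)
            assert (res.n_comparable_pairs, res.n_concordant,
                    res.n_tied) == (n_pairs, n_conc, n_tied)

    def test_identity_decomposition(self):
        rng = np.random.default_rng(3)
        t = rng.integers(1, 10, size=60).astype(float)
        e = rng.integers(0, 2, size=60)
        e[0] = 1
        p = rng.integers(0, 5, size=60).astype(float)
        res = concordance_index(t, e, p)
        assert res.c_index == pytest.approx(
            (res.n_concordant + 0.5 * res.n_tied) / res.n_comparable_pairs)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(1, 30, size=80)
        e = rng.integers(0, 2, size=80)
        e[:5] = 1
        p = rng.normal(size=80)
        a = concordance_index(t, e, p)
        b = concordance_index(t, e, np.exp(3.0 * p) + 7.0)
        assert a.c_index == b.c_index
        assert a.n_comparable_pairs == b.n_comparable_pairs
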