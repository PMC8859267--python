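import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy.stats import kstest

from m6apattern.survival import (
    _cox_llgh,
    _logrank_chi2,
    cox_fit,
    kaplan_meier,
    logrank_test,
    maxstat_cutpoint,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        fit = kaplan_meier([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(fit.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        fit = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert fit.times.size == 0  # no drops: S identically 1

    def test_no_censoring_empirical_identity(self, rng):
        t = rng.exponential(5, 40)
        fit = kaplan_meier(t, np.ones(40, int))
        for ti, si in zip(fit.times, fit.survival):
            assert si == pytest.approx((t > ti).mean())

    def test_matches_lifelines_with_censoring(self, rng):
        t = np.ceil(rng.exponential(10, 80))
        e = rng.binomial(1, 0.6, 80)
        e[0] = 1
        fit = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(fit.times).to_numpy()
        np.testing.assert_allclose(fit.survival, ref, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0] * 4 + [1] * 4
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_permutation_p_within_mc_ci_of_enumeration(self):
        # n=8: module's 5000-draw MC permutation p vs exact enumeration over
        # all C(8,4) label assignments
        t = np.array([3.0, 5, 7, 2, 9, 11, 4, 6])
        e = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        obs = _logrank_chi2(t, e, g == 0)
        hits = total = 0
        for combo in itertools.combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(combo)] = True
            total += 1
            if _logrank_chi2(t, e, mask) >= obs - 1e-12:
                hits += 1
        p_exact = hits / total
        res = logrank_test(t, e, g, n_permutations=5000, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / 5000)
        assert abs(res.p_value - p_exact) < 4 * se + 2 / 5000

    def test_label_swap_symmetry(self, rng):
        t = rng.exponential(5, 30)
        e = rng.binomial(1, 0.7, 30)
        e[0] = 1
        g = rng.binomial(1, 0.5, 30)
        g[:2] = [0, 1]
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.statistic == pytest.approx(b.statistic)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [0, 0], [0, 1])


class TestCoxFit:
    def test_planted_hazard_ratio_recovery(self):
        rng = np.random.default_rng(100)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2.0) * x)))
        fit = cox_fit(t, np.ones(n, int), x)
        assert fit.converged and not fit.flagged
        assert 1.8 <= np.exp(fit.beta[0]) <= 2.2

    def test_matches_lifelines_efron(self, rng):
        n = 120
        t = np.ceil(rng.exponential(8, n))  # heavy ties
        e = rng.binomial(1, 0.7, n)
        X = pd.DataFrame({"x1": rng.normal(0, 1, n), "x2": rng.binomial(1, 0.4, n).astype(float)})
        fit = cox_fit(t, e, X)
        ref = CoxPHFitter().fit(
            pd.concat([pd.Series(t, name="t"), pd.Series(e, name="e"), X], axis=1), "t", "e"
        )
        np.testing.assert_allclose(fit.beta, ref.params_.to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(fit.se, ref.standard_errors_.to_numpy(), rtol=1e-6)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, rel=1e-9)

    def test_score_test_equals_logrank_without_ties(self, rng):
        t = rng.exponential(5, 40)  # continuous: no ties
        e = rng.binomial(1, 0.8, 40)
        e[:2] = 1
        g = rng.binomial(1, 0.5, 40).astype(float)
        g[:2] = [0, 1]
        order = np.argsort(t)
        _, grad, info = _cox_llgh(t[order], e[order], (g - g.mean())[order, None],
                                  np.zeros(1), "efron")
        score_stat = grad[0] ** 2 / info[0, 0]
        chi2 = _logrank_chi2(t, e, g == 1)
        # logrank variance uses the (n-d)/(n-1) factor; without ties d=1 at
        # every event time and the two coincide exactly
        assert score_stat == pytest.approx(chi2, rel=1e-10)

    def test_wald_p_uniform_under_null(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 60
            t = rng.exponential(5, n)
            e = rng.binomial(1, 0.8, n)
            e[:2] = 1
            x = rng.normal(0, 1, n)  # independent of survival
            pvals.append(cox_fit(t, e, x).p[0])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_loglik_improves_from_null(self, rng):
        n = 200
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))
        e = np.ones(n, int)
        fit = cox_fit(t, e, x)
        order = np.argsort(t)
        ll0, _, _ = _cox_llgh(t[order], e[order], (x - x.mean())[order, None],
                              np.zeros(1), "efron")
        assert fit.loglik >= ll0

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 1, 1], [1.0, 1.0, 1.0, 1.0])

    def test_separation_flagged_not_silent(self):
        # covariate perfectly orders event times -> monotone likelihood
        t = np.arange(1.0, 21.0)
        e = np.ones(20, int)
        x = np.arange(20.0)
        fit = cox_fit(t, e, x)
        assert fit.flagged

    def test_too_few_events(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit([1, 2, 3], [1, 0, 0], np.random.default_rng(0).normal(size=(3, 2)))

    def test_breslow_option(self, rng):
        t = np.ceil(rng.exponential(8, 60))
        e = rng.binomial(1, 0.7, 60)
        x = rng.normal(0, 1, 60)
        fit = cox_fit(t, e, x, ties="breslow")
        ref = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e"
        )
        # Breslow and Efron differ under ties but agree in direction
        assert np.sign(fit.beta[0]) == np.sign(ref.params_.iloc[0])
        assert fit.ties == "breslow"


class TestMaxstat:
    def _data(self, seed=0, n=20):
        rng = np.random.default_rng(seed)
        score = rng.normal(0, 1, n)
        hazard = 0.05 * np.exp(1.0 * score)
        t = rng.exponential(1.0 / hazard)
        e = rng.binomial(1, 0.8, n)
        e[:2] = 1
        return t, e, score

    def test_exhaustive_split_oracle(self):
        t, e, score = self._data(seed=5)
        res = maxstat_cutpoint(t, e, score, min_frac=0.1, n_permutations=0)
        best_stat, best_v = -1.0, None
        n = len(score)
        for v in np.unique(score):
            n_low = (score <= v).sum()
            if n_low < np.ceil(0.1 * n) or n_low > n - np.ceil(0.1 * n):
                continue
            stat = logrank_test(t, e, (score <= v).astype(int)).statistic
            if stat > best_stat:
                best_stat, best_v = stat, v
        assert res.statistic == pytest.approx(best_stat)
        assert res.threshold == pytest.approx(best_v)

    def test_translation_equivariance(self):
        t, e, score = self._data(seed=8)
        a = maxstat_cutpoint(t, e, score, n_permutations=0)
        b = maxstat_cutpoint(t, e, score + 100.0, n_permutations=0)
        assert b.threshold == pytest.approx(a.threshold + 100.0)
        assert b.statistic == pytest.approx(a.statistic)

    def test_planted_separation_threshold_in_gap(self):
        # score AND survival perfectly separate the planted high-risk group
        rng = np.random.default_rng(2)
        n = 60
        score = np.r_[rng.normal(-2, 0.1, 30), rng.normal(2, 0.1, 30)]
        t = np.r_[rng.uniform(50, 100, 30), rng.uniform(1, 5, 30)]
        e = np.ones(n, int)
        res = maxstat_cutpoint(t, e, score, n_permutations=200, seed=1)
        # chosen threshold lies in the gap: at/above every low-group score,
        # below every high-group score
        assert score[:30].max() - 1e-12 <= res.threshold < score[30:].min()
        assert res.p_value is not None and res.p_value < 0.05

    def test_beats_median_split(self):
        t, e, score = self._data(seed=11, n=40)
        res = maxstat_cutpoint(t, e, score, n_permutations=0)
        median_stat = logrank_test(t, e, (score <= np.median(score)).astype(int)).statistic
        assert res.statistic >= median_stat - 1e-12

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError):
            maxstat_cutpoint([1, 2, 3, 4], [1, 1, 1, 1], [5.0, 5.0, 5.0, 5.0],
                             n_permutations=0)

    def test_bad_min_frac(self):
        t, e, score = self._data()
        with pytest.raises(ValueError):
            maxstat_cutpoint(t, e, score, min_frac=0.6, n_permutations=0)
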