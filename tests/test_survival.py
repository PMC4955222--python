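"""Nonparametric curves, Cox / Fine-Gray regression and the screen."""

import numpy as np
import pytest
from scipy import optimize, stats

from sigstab import (aalen_johansen, bh_fdr, censoring_survival,
                     fit_cox_cause_specific, fit_fine_gray, interaction_check,
                     overall_survival, univariate_screen)
from sigstab.survival import StepFunction
from sigstab.synthetic import CohortSpec, generate_cohort

from conftest import make_dataset


# -- independent naive partial-likelihood oracles (loop-based, Breslow) ------

def naive_cox_loglik(beta, time, is_event, X):
    beta = np.atleast_1d(beta)
    ll = 0.0
    for i in np.flatnonzero(is_event):
        risk = time >= time[i]
        ll += X[i] @ beta - np.log(np.exp(X[risk] @ beta).sum())
    return ll


def naive_fg_loglik_uncensored(beta, time, event, etype, X, cause=1):
    """Fine-Gray partial likelihood without censoring: competing-event
    subjects stay in the risk set forever with weight 1."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for i in np.flatnonzero((event == 1) & (etype == cause)):
        risk = (time >= time[i]) | ((event == 1) & (etype != cause)
                                    & (time < time[i]))
        ll += X[i] @ beta - np.log(np.exp(X[risk] @ beta).sum())
    return ll


class TestCensoringSurvival:
    def test_no_censoring_gives_identity_one(self):
        ds = make_dataset([1, 2, 3], [1, 1, 1], [1, 2, 1])
        G = censoring_survival(ds)
        assert np.allclose(G([0.5, 1.5, 5.0]), 1.0)

    def test_all_censored_steps_down_product_limit(self):
        ds = make_dataset([1, 2, 3], [0, 0, 0], [0, 0, 0])
        G = censoring_survival(ds)
        np.testing.assert_allclose(G([1, 2, 3]), [2 / 3, 1 / 3, 0.0])

    def test_mixed_six_subject_hand_computation(self):
        # censoring at 2, 4, 5 with at-risk sets of 5, 3, 2
        ds = make_dataset([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 0, 1],
                          [1, 0, 2, 0, 0, 1])
        G = censoring_survival(ds)
        np.testing.assert_allclose(G([2, 4, 5]), [4 / 5, 4 / 5 * 2 / 3,
                                                  4 / 5 * 2 / 3 * 1 / 2])
        assert G.left_limit(2) == 1.0


class TestAalenJohansen:
    def test_single_cause_no_censoring_is_empirical_cdf(self):
        times = [3, 1, 4, 1, 5]
        ds = make_dataset(times, [1] * 5, [1] * 5)
        F = aalen_johansen(ds, 1)
        for t in (0.5, 1, 2, 3, 4, 5, 9):
            assert F(t) == pytest.approx(np.mean(np.asarray(times) <= t))

    def test_absent_cause_has_zero_incidence(self):
        ds = make_dataset([1, 2, 3], [1, 1, 0], [2, 2, 0])
        F1 = aalen_johansen(ds, 1)
        assert np.allclose(F1([1, 2, 3, 10]), 0.0)

    def test_eight_subject_two_cause_hand_computation(self):
        ds = make_dataset([1, 2, 3, 4, 5, 6, 7, 8],
                          [1, 1, 0, 1, 1, 0, 1, 1],
                          [1, 2, 0, 1, 1, 0, 2, 1])
        F1 = aalen_johansen(ds, 1)
        F2 = aalen_johansen(ds, 2)
        np.testing.assert_allclose(F1([1, 4, 5, 8]), [0.125, 0.275, 0.425, 0.65])
        np.testing.assert_allclose(F2([2, 7]), [0.125, 0.35])

    def test_incidences_monotone_and_bounded_by_one_minus_km(self, small_cohort):
        ds, _ = small_cohort
        F1, F2 = aalen_johansen(ds, 1), aalen_johansen(ds, 2)
        S = overall_survival(ds)
        grid = np.linspace(0, ds.time.max(), 60)
        for F in (F1, F2):
            assert np.all(np.diff(F(grid)) >= -1e-12)
        np.testing.assert_allclose(F1(grid) + F2(grid), 1 - S(grid), atol=1e-10)


class TestCoxFit:
    def test_null_covariate_estimates_near_zero(self):
        rng = np.random.default_rng(7)
        n = 1500
        x = rng.standard_normal(n)
        t = rng.exponential(10, n)
        ds = make_dataset(t, np.ones(n, int), np.ones(n, int), expression=x)
        fit = fit_cox_cause_specific(ds, ["f0"])
        assert abs(fit.coef[0] / fit.se[0]) < 3

    def test_two_group_log_hazard_ratio_recovery(self):
        rng = np.random.default_rng(8)
        n = 2000
        g = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / np.exp(0.7 * g))
        ds = make_dataset(t, np.ones(n, int), np.ones(n, int), expression=g)
        fit = fit_cox_cause_specific(ds, ["f0"])
        assert fit.coef[0] == pytest.approx(0.7, abs=0.15)

    def test_optimum_matches_derivative_free_oracle(self):
        rng = np.random.default_rng(9)
        n = 20
        X = rng.standard_normal((n, 2))
        t = rng.exponential(1 / np.exp(X @ [0.5, -0.3]))
        event = rng.binomial(1, 0.8, n)
        event[:2] = 1
        ds = make_dataset(t, event, event, expression=X)
        fit = fit_cox_cause_specific(ds, ["f0", "f1"])
        is_ev = event.astype(bool)
        res = optimize.minimize(lambda b: -naive_cox_loglik(b, t, is_ev, X),
                                np.zeros(2), method="Nelder-Mead",
                                options=dict(xatol=1e-10, fatol=1e-12,
                                             maxiter=20000))
        assert naive_cox_loglik(fit.coef, t, is_ev, X) >= -res.fun - 1e-6
        np.testing.assert_allclose(fit.coef, res.x, atol=1e-4)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self, small_cohort):
        ds, _ = small_cohort
        keep = np.flatnonzero(~((ds.event == 1) & (ds.event_type == 2)))
        ds1 = ds.subset(keep)
        fg = fit_fine_gray(ds1, ["age", "prior_cv"])
        cx = fit_cox_cause_specific(ds1, ["age", "prior_cv"])
        np.testing.assert_allclose(fg.coef, cx.coef, atol=1e-6)
        assert fg.loglik == pytest.approx(cx.loglik, abs=1e-6)

    def test_uncensored_optimum_matches_derivative_free_oracle(self):
        rng = np.random.default_rng(10)
        n = 22
        X = rng.standard_normal((n, 2))
        t = rng.exponential(1.0, n)
        etype = rng.choice([1, 2], n, p=[0.6, 0.4])
        ds = make_dataset(t, np.ones(n, int), etype, expression=X)
        fit = fit_fine_gray(ds, ["f0", "f1"])
        res = optimize.minimize(
            lambda b: -naive_fg_loglik_uncensored(b, t, np.ones(n, int),
                                                  etype, X),
            np.zeros(2), method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000))
        assert naive_fg_loglik_uncensored(fit.coef, t, np.ones(n, int),
                                          etype, X) >= -res.fun - 1e-6
        np.testing.assert_allclose(fit.coef, res.x, atol=1e-4)

    def test_positive_effect_recovered_with_positive_sign(self):
        hits = 0
        reps = 12
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            n = 300
            x = rng.standard_normal(n)
            t1 = rng.exponential(1 / (0.05 * np.exp(0.8 * x)))
            t2 = rng.exponential(1 / 0.05, n)
            t = np.minimum(np.minimum(t1, t2), 30.0)
            event = (np.minimum(t1, t2) <= 30.0).astype(int)
            etype = np.where(event == 0, 0, np.where(t1 <= t2, 1, 2))
            ds = make_dataset(t, event, etype, expression=x)
            fit = fit_fine_gray(ds, ["f0"])
            hits += fit.coef[0] > 0
        assert hits >= int(0.95 * reps)


class TestScreenAndFdr:
    def test_duplicated_feature_gets_identical_pvalue(self, small_cohort):
        ds, _ = small_cohort
        dup = ds.copy()
        dup.expression[:, 1] = dup.expression[:, 0]
        pv = univariate_screen(dup)
        assert pv[0] == pytest.approx(pv[1], abs=1e-10)

    def test_informative_features_rank_low(self, small_cohort):
        ds, gt = small_cohort
        pv = univariate_screen(ds)
        ranks = stats.rankdata(pv)
        null = np.setdiff1d(np.arange(ds.p),
                            gt.informative_cause1 + gt.informative_cause2)
        assert np.median(ranks[gt.informative_cause1]) < np.median(ranks[null])

    def test_bh_textbook_example(self):
        assert set(bh_fdr(np.array([0.001, 0.01, 0.02, 0.9]), 0.05)) == {0, 1, 2}

    def test_bh_all_ones_empty(self):
        assert bh_fdr(np.ones(10), 0.05).size == 0

    def test_bh_matches_brute_force_definition(self):
        rng = np.random.default_rng(3)

        def brute(p, q):
            m = len(p)
            order = np.argsort(p)
            ps = p[order]
            ks = np.flatnonzero(ps <= (np.arange(1, m + 1) * q / m))
            if ks.size == 0:
                return np.array([], dtype=int)
            return np.sort(order[:ks.max() + 1])

        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 40))
            q = rng.choice([0.01, 0.05, 0.1, 0.3])
            np.testing.assert_array_equal(np.sort(bh_fdr(p, q)), brute(p, q))


class TestInteractionCheck:
    def test_zero_expression_score_gives_null_interaction(self, small_cohort):
        ds, _ = small_cohort
        lp_c = ds.clinical["age"].to_numpy() / 10
        fit = interaction_check(ds, lp_c, np.zeros(ds.n))
        assert fit.coef[2] == pytest.approx(0.0, abs=1e-8)
        assert not fit.pvalues[2] < 0.05

    def test_true_product_effect_detected(self):
        detected = 0
        reps = 6
        for seed in range(reps):
            rng = np.random.default_rng(200 + seed)
            n = 400
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            lp = 0.3 * a + 0.3 * b + 0.8 * a * b
            t = rng.exponential(1 / (0.1 * np.exp(lp)))
            t = np.minimum(t, 20.0)
            event = (t < 20.0).astype(int)
            ds = make_dataset(t, event, event, expression=np.column_stack([a, b]))
            fit = interaction_check(ds, a, b)
            detected += fit.pvalues[2] < 0.05
        assert detected > reps / 2


def test_step_function_rejects_unsorted_times():
    with pytest.raises(ValueError):
        StepFunction(times=[2.0, 1.0], values=[0.5, 0.2])
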