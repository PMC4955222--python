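"""Subsampling, inclusion frequencies, joint-selection ORs, outlier flags and
the modeling-choice regression."""

import numpy as np
import pandas as pd
import pytest

from sigstab import (ModelingConfig, build_selection_matrix, draw_subsamples,
                     flag_outlier_observations, inclusion_frequencies,
                     joint_selection_odds_ratios, multi_feature_stability,
                     stability_regression)
from sigstab.core_data import config_grid
from sigstab.stability import (REGRESSION_TERMS, SelectionMatrix,
                               _config_design_row, implicated_from_odds_ratios)

from conftest import make_dataset


def _matrix_from_bool(inclusion, config=None, k=None):
    B, p = inclusion.shape
    return SelectionMatrix(
        config=config or ModelingConfig(),
        subsample_indices=[np.arange(5)] * B,
        inclusion=np.asarray(inclusion, dtype=bool),
        valid=np.ones(B, dtype=bool),
        feature_names=[f"f{j}" for j in range(p)],
        k_univariate=k)


class TestDrawSubsamples:
    def test_sets_have_exact_size_and_distinct_members(self):
        subs = draw_subsamples(10, 20, 0.5, seed=1)
        assert all(len(s) == 5 and len(set(s)) == 5 for s in subs)

    def test_seed_determinism(self):
        a = draw_subsamples(50, 10, 0.5, seed=9)
        b = draw_subsamples(50, 10, 0.5, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_per_subject_inclusion_rate_near_half(self):
        subs = draw_subsamples(100, 10000, 0.5, seed=2)
        counts = np.zeros(100)
        for s in subs:
            counts[s] += 1
        rates = counts / 10000
        assert np.all(np.abs(rates - 0.5) < 0.02)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            draw_subsamples(10, 5, 1.5)


class TestSelectionMatrix:
    def test_univariate_topk_selects_exactly_k(self, small_cohort):
        ds, _ = small_cohort
        subs = draw_subsamples(ds.n, 8, seed=3)
        cfg = ModelingConfig(selection_method="univariate_topk")
        m = build_selection_matrix(ds, cfg, subs, k_univariate=11)
        assert np.all(m.inclusion[m.valid].sum(axis=1) == 11)

    def test_informative_features_gain_higher_frequencies(self, small_cohort):
        ds, gt = small_cohort
        subs = draw_subsamples(ds.n, 25, seed=4)
        m = build_selection_matrix(ds, ModelingConfig(), subs, n_steps=100)
        fr = inclusion_frequencies(m)
        null = np.setdiff1d(np.arange(ds.p),
                            gt.informative_cause1 + gt.informative_cause2)
        assert (np.median(fr[gt.informative_cause1])
                > np.median(fr[null]))

    def test_duplicate_columns_compete_under_boosting(self, small_cohort):
        """Identical features get near-identical univariate inclusion but
        split (mutually exclusive) boosting inclusion."""
        ds, gt = small_cohort
        dup = ds.copy()
        # duplicate the feature boosting actually favours on this cohort
        from sigstab import boost
        ref = boost(ds, n_steps=100)
        j0 = int(np.argmax(np.abs(ref.coef)))
        twin = 1 if j0 != 1 else 2
        dup.expression[:, twin] = dup.expression[:, j0]
        subs = draw_subsamples(dup.n, 25, seed=5)
        m_uni = build_selection_matrix(
            dup, ModelingConfig(selection_method="univariate_topk"), subs,
            k_univariate=11)
        fr_uni = inclusion_frequencies(m_uni)
        # identical p-values, so the twins move (nearly) together
        assert abs(fr_uni[twin] - fr_uni[j0]) <= 0.25
        m_boost = build_selection_matrix(dup, ModelingConfig(), subs,
                                         n_steps=100)
        both = (m_boost.inclusion[:, twin] & m_boost.inclusion[:, j0]).mean()
        either = (m_boost.inclusion[:, twin] | m_boost.inclusion[:, j0]).mean()
        assert both < either  # the twins rarely enter together


class TestFrequenciesAndOddsRatios:
    def test_frequency_arithmetic(self):
        inc = np.zeros((10, 2), dtype=bool)
        inc[:3, 0] = True
        m = _matrix_from_bool(inc)
        np.testing.assert_allclose(inclusion_frequencies(m), [0.3, 0.0])

    def test_frequencies_invariant_under_row_permutation(self):
        rng = np.random.default_rng(6)
        inc = rng.random((40, 4)) < 0.4
        m1 = _matrix_from_bool(inc)
        m2 = _matrix_from_bool(inc[rng.permutation(40)])
        np.testing.assert_allclose(inclusion_frequencies(m1),
                                   inclusion_frequencies(m2))

    def test_or_cross_table_arithmetic(self):
        # counts (n11, n10, n01, n00) = (30, 20, 20, 30) -> OR = 2.25
        inc = np.zeros((100, 2), dtype=bool)
        inc[:30, :] = True          # n11
        inc[30:50, 0] = True        # n10
        inc[50:70, 1] = True        # n01
        m = _matrix_from_bool(inc)
        table = joint_selection_odds_ratios(m, min_frequency=0.1)
        assert table.iloc[0, 1] == pytest.approx(2.25)

    def test_zero_cell_gets_continuity_correction(self):
        # counts (10, 0, 5, 85) -> (10.5 * 85.5) / (0.5 * 5.5)
        inc = np.zeros((100, 2), dtype=bool)
        inc[:10, :] = True
        inc[10:15, 1] = True
        m = _matrix_from_bool(inc)
        table = joint_selection_odds_ratios(m, min_frequency=0.05)
        assert table.iloc[0, 1] == pytest.approx((10.5 * 85.5) / (0.5 * 5.5))

    def test_table_symmetric(self):
        rng = np.random.default_rng(7)
        inc = rng.random((200, 5)) < 0.3
        table = joint_selection_odds_ratios(_matrix_from_bool(inc), 0.05)
        v = table.to_numpy(float)
        np.testing.assert_allclose(v, v.T, equal_nan=True)

    def test_independent_columns_give_or_near_one(self):
        rng = np.random.default_rng(8)
        inc = rng.random((20000, 2)) < 0.3
        table = joint_selection_odds_ratios(_matrix_from_bool(inc), 0.05)
        assert table.iloc[0, 1] == pytest.approx(1.0, abs=0.15)


class TestOutlierFlagging:
    def test_constant_feature_skipped_without_flags(self, small_cohort):
        ds, _ = small_cohort
        flat = ds.copy()
        flat.expression[:, 0] = 1.0
        flagged, scores = flag_outlier_observations(flat, [0], 4.0)
        assert flagged.size == 0 and scores.empty

    def test_injected_outliers_flagged(self, outlier_cohort):
        ds, gt = outlier_cohort
        flagged, _ = flag_outlier_observations(ds, gt.outlier_features, 4.0)
        assert set(gt.outlier_indices) <= set(flagged.tolist())

    def test_false_flag_rate_on_clean_gaussian(self):
        rng = np.random.default_rng(9)
        ds = make_dataset(np.arange(1, 251), [1] * 125 + [0] * 125,
                          [1] * 125 + [0] * 125,
                          expression=rng.standard_normal((250, 20)))
        flagged, _ = flag_outlier_observations(ds, list(range(20)), 4.0)
        # expected false flags per feature < 1 at threshold 4
        assert flagged.size < 20

    def test_empty_feature_list_rejected(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ValueError):
            flag_outlier_observations(ds, [], 4.0)


class TestStabilityRegression:
    def test_flat_frequencies_give_null_effects(self):
        counts = {c: (40, 200) for c in config_grid()}
        res = stability_regression(counts)
        assert not res.degenerate
        np.testing.assert_allclose(res.estimates[1:], 0.0, atol=1e-8)

    def test_known_logistic_model_recovered(self):
        rng = np.random.default_rng(10)
        truth = np.array([-2.0, 0.5, -0.3, 1.2, -0.8, 0.0, 0.0, -0.6, 0.0, 0.2])
        B = 4000
        counts = {}
        for c in config_grid():
            eta = _config_design_row(c) @ truth
            pi = 1 / (1 + np.exp(-eta))
            counts[c] = (int(rng.binomial(B, pi)), B)
        res = stability_regression(counts)
        se_scale = 4 / np.sqrt(B)   # generous Monte-Carlo error allowance
        np.testing.assert_allclose(res.estimates, truth, atol=10 * se_scale)

    def test_always_selected_feature_flagged_degenerate(self):
        counts = {c: (200, 200) for c in config_grid()}
        res = stability_regression(counts)
        assert res.degenerate
        assert np.all(np.isnan(res.estimates))

    def test_optimum_matches_direct_likelihood_maximization(self):
        from scipy import optimize, special
        rng = np.random.default_rng(11)
        counts = {c: (int(rng.integers(5, 60)), 100) for c in config_grid()}
        res = stability_regression(counts)
        X = np.stack([_config_design_row(c) for c in counts])
        y = np.array([counts[c][0] for c in counts], dtype=float)
        ntot = np.array([counts[c][1] for c in counts], dtype=float)

        def negll(b):
            eta = X @ b
            return -(y * eta - ntot * np.logaddexp(0, eta)).sum()

        direct = optimize.minimize(negll, np.zeros(10), method="BFGS",
                                   options=dict(gtol=1e-12, maxiter=5000))
        assert negll(res.estimates) <= direct.fun + 1e-6
        np.testing.assert_allclose(res.estimates, direct.x, atol=1e-4)


class TestMultiFeatureStability:
    def _matrices(self, rng, p=6, B=150, boost_freq=0.4):
        mats = []
        for c in config_grid():
            freq = np.full(p, 0.05)
            freq[0] = boost_freq if c.endpoint == "original" else 0.1
            inc = rng.random((B, p)) < freq
            mats.append(_matrix_from_bool(inc, config=c))
        return mats

    def test_min_max_columns_are_rowwise_extrema(self):
        rng = np.random.default_rng(12)
        report = multi_feature_stability(self._matrices(rng), 0.05)
        cfg_cols = [c for c in report.frequencies.columns
                    if c not in ("min", "max")]
        np.testing.assert_allclose(report.frequencies["min"],
                                   report.frequencies[cfg_cols].min(axis=1))
        np.testing.assert_allclose(report.frequencies["max"],
                                   report.frequencies[cfg_cols].max(axis=1))

    def test_endpoint_effect_detected_for_driven_feature(self):
        rng = np.random.default_rng(13)
        report = multi_feature_stability(self._matrices(rng, B=400), 0.1)
        reg = report.regressions["f0"]
        t = list(REGRESSION_TERMS).index("original_endpoint")
        assert reg.estimates[t] > 0
        assert reg.pvalues[t] < 0.05 / max(len(report.regressions), 1)

    def test_null_features_produce_no_significant_terms(self):
        rng = np.random.default_rng(14)
        mats = []
        for c in config_grid():
            inc = rng.random((200, 5)) < 0.15
            mats.append(_matrix_from_bool(inc, config=c))
        report = multi_feature_stability(mats, 0.1)
        assert report.term_sign_counts[["sig_positive", "sig_negative"]
                                       ].to_numpy().sum() <= 1


def test_implicated_features_require_facilitation_and_exclusion():
    names = ["a", "b", "c", "d"]
    vals = np.array([[np.nan, 8.0, 0.2, 0.1],
                     [8.0, np.nan, 0.25, 0.3],
                     [0.2, 0.25, np.nan, 1.0],
                     [0.1, 0.3, 1.0, np.nan]])
    table = pd.DataFrame(vals, index=names, columns=names)
    assert implicated_from_odds_ratios(table) == ["a", "b"]
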