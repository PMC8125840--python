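"""Bootstrapped RFE: splits, logistic MLE, leave-one-out AUCs, ranking, rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import stsfrail as sf
import stsfrail.selection as sel

from conftest import CANDIDATES_8, OPTIMAL_TRIO, null_spec, planted_spec


class TestBootstrapPairs:
    def test_pair_counts_sizes_and_oob_disjointness(self):
        y = np.r_[np.zeros(42, int), np.ones(60, int)]
        cfg = sf.SelectionConfig(B=50, seed=0)
        splits = sf.make_bootstrap_pairs(y, cfg)
        assert len(splits) == 50
        for s in splits:
            assert len(s.train) == 102
            assert len(np.intersect1d(s.train, s.val)) == 0
            assert set(np.unique(y[s.val])) == {0, 1}

    def test_stratified_training_keeps_class_counts(self):
        y = np.r_[np.zeros(42, int), np.ones(60, int)]
        splits = sf.make_bootstrap_pairs(y, sf.SelectionConfig(B=20, seed=3))
        for s in splits:
            assert np.sum(y[s.train] == 0) == 42
            assert np.sum(y[s.train] == 1) == 60

    def test_same_seed_reproduces_splits_and_B_extends_them(self):
        """Counter-derived streams: pair b is identical whatever B is."""
        y = np.r_[np.zeros(20, int), np.ones(30, int)]
        a = sf.make_bootstrap_pairs(y, sf.SelectionConfig(B=10, seed=9))
        b = sf.make_bootstrap_pairs(y, sf.SelectionConfig(B=25, seed=9))
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.train, s2.train)
            np.testing.assert_array_equal(s1.val, s2.val)

    def test_unstratified_oob_fraction_matches_analytic_expectation(self):
        """E[OOB fraction] = (1 - 1/n)^n = 0.3661 at n = 102."""
        n = 102
        y = np.r_[np.zeros(42, int), np.ones(60, int)]
        cfg = sf.SelectionConfig(B=5000, seed=1, stratified=False)
        splits = sf.make_bootstrap_pairs(y, cfg)
        fracs = np.array([len(s.val) / n for s in splits])
        expected = (1 - 1 / n) ** n
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) < 3 * se + 1e-3

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            sf.make_bootstrap_pairs(np.ones(10, int), sf.SelectionConfig(B=2))


class TestFitLogistic:
    def test_uninformative_feature_gives_prevalence_intercept(self):
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        model = sf.fit_logistic(np.zeros((100, 1)), y)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)
        assert model.coef[0] == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_within_three_standard_errors(self):
        """1-D logistic with known generating slope, n = 200."""
        rng = np.random.default_rng(12)
        beta0, beta1 = -0.5, 1.2
        x = rng.normal(0, 1, 200)
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        y = (rng.random(200) < p).astype(int)
        model = sf.fit_logistic(x[:, None], y)
        assert model.converged
        assert abs(model.coef[0] - beta1) < 3 * model.se_coef[0]
        assert abs(model.intercept - beta0) < 3 * model.se_intercept

    def test_perfect_separation_flags_nonconvergence_with_auc_one(self):
        x = np.r_[np.linspace(-2, -1, 20), np.linspace(1, 2, 20)]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        model = sf.fit_logistic(x[:, None], y)
        assert not model.converged
        assert sf.roc_auc(model.predict_proba(x[:, None]), y) == 1.0

    def test_matches_statsmodels_mle(self):
        """Dual route: Newton-Raphson fit agrees with the statsmodels
        maximum-likelihood logistic fit on a well-conditioned dataset."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = rng.normal(size=(150, 3)) * [1.0, 5.0, 0.2]
        eta = 0.3 + X @ np.array([0.8, -0.2, 1.5])
        y = (rng.random(150) < 1 / (1 + np.exp(-eta))).astype(int)
        ours = sf.fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            [ours.intercept, *ours.coef], ref.params, rtol=1e-5, atol=1e-6
        )
        np.testing.assert_allclose(
            [ours.se_intercept, *ours.se_coef], ref.bse, rtol=1e-4, atol=1e-6
        )

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            sf.fit_logistic(np.random.default_rng(0).normal(size=(10, 1)),
                            np.zeros(10, int))


class TestLeaveOneOutAUC:
    def test_excluding_informative_feature_costs_auc(self):
        table = sf.generate_feature_table(
            sf.CohortSpec(seed=2, feature_effects={"duration_s": 2.0})
        )
        cfg = sf.SelectionConfig(B=50, seed=5)
        splits = sf.make_bootstrap_pairs(table["status"].to_numpy(), cfg)
        loo = sf.leave_one_out_auc(
            ["duration_s", "cv_hip_angle_range"], table, splits
        )
        # excluding the pure-noise feature leaves the informative model intact
        assert loo["cv_hip_angle_range"] > loo["duration_s"] + 0.15

    def test_fit_count_is_candidates_times_splits(self, monkeypatch):
        calls = {"n": 0}
        orig = sel.fit_logistic

        def counting(*a, **k):
            calls["n"] += 1
            return orig(*a, **k)

        monkeypatch.setattr(sel, "fit_logistic", counting)
        table = sf.generate_feature_table(null_spec(3, n_robust=10, n_frail=10))
        splits = sf.make_bootstrap_pairs(
            table["status"].to_numpy(), sf.SelectionConfig(B=1, seed=0)
        )
        sf.leave_one_out_auc(["duration_s", "mean_hip_angle_range"], table, splits)
        assert calls["n"] == 2

    def test_all_noise_features_give_null_aucs(self):
        table = sf.generate_feature_table(null_spec(4))
        splits = sf.make_bootstrap_pairs(
            table["status"].to_numpy(), sf.SelectionConfig(B=100, seed=1)
        )
        loo = sf.leave_one_out_auc(CANDIDATES_8[:4], table, splits)
        for auc in loo.values():
            assert abs(auc - 0.5) < 0.08


class TestCountModelFits:
    @pytest.mark.parametrize(
        "n_features,B,expected", [(8, 2000, 70_000), (2, 1, 2), (5, 10, 140)]
    )
    def test_closed_form_counts(self, n_features, B, expected):
        assert sf.count_model_fits(n_features, B) == expected

    @settings(deadline=None, derandomize=True)
    @given(n=st.integers(2, 12), B=st.integers(1, 50))
    def test_formula_matches_direct_summation(self, n, B):
        assert sf.count_model_fits(n, B) == B * sum(range(2, n + 1))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sf.count_model_fits(1, 10)
        with pytest.raises(ValueError):
            sf.count_model_fits(4, 0)


class TestRFERank:
    def test_smallest_case_two_features_single_split(self):
        table = sf.generate_feature_table(null_spec(5, n_robust=15, n_frail=15))
        cfg = sf.SelectionConfig(B=1, seed=2)
        trace, ranking = sf.rfe_rank(
            table, ["duration_s", "mean_hip_angle_range"], cfg
        )
        assert len(trace.loops) == 1
        assert trace.n_loo_fits == 2
        assert sorted(ranking.features) == sorted(
            ["duration_s", "mean_hip_angle_range"]
        )

    @pytest.mark.parametrize("n_feat,B", [(2, 5), (4, 5), (5, 1)])
    def test_executed_fits_match_count_formula(self, n_feat, B, monkeypatch):
        calls = {"n": 0}
        orig = sel.fit_logistic

        def counting(*a, **k):
            calls["n"] += 1
            return orig(*a, **k)

        monkeypatch.setattr(sel, "fit_logistic", counting)
        table = sf.generate_feature_table(null_spec(6, n_robust=12, n_frail=12))
        cfg = sf.SelectionConfig(B=B, seed=1)
        trace, _ = sf.rfe_rank(
            table, CANDIDATES_8[:n_feat], cfg, compute_subset_curve=False
        )
        assert trace.n_loo_fits == sf.count_model_fits(n_feat, B)
        assert calls["n"] == trace.n_loo_fits

    def test_identical_config_gives_identical_trace_and_ranking(self):
        table = sf.generate_feature_table(planted_spec(seed=13))
        cfg = sf.SelectionConfig(B=20, seed=4)
        t1, r1 = sf.rfe_rank(table, CANDIDATES_8[:4], cfg)
        t2, r2 = sf.rfe_rank(table, CANDIDATES_8[:4], cfg)
        assert r1.features == r2.features
        assert t1.loops == t2.loops
        assert r1.subset_auc == r2.subset_auc

    def test_feature_order_permutation_does_not_change_ranking(self):
        table = sf.generate_feature_table(planted_spec(seed=14, d=1.5))
        cfg = sf.SelectionConfig(B=25, seed=6)
        feats = CANDIDATES_8[:5]
        _, r1 = sf.rfe_rank(table, feats, cfg)
        _, r2 = sf.rfe_rank(table, feats[::-1], cfg)
        assert r1.features == r2.features

    def test_planted_features_rank_first(self):
        table = sf.generate_feature_table(planted_spec(seed=15, d=1.5))
        cfg = sf.SelectionConfig(B=60, seed=7)
        _, ranking = sf.rfe_rank(table, CANDIDATES_8, cfg)
        assert set(ranking.features[:3]) == set(OPTIMAL_TRIO)

    def test_literal_elimination_flag_flips_direction(self):
        """The literal reading removes the feature whose exclusion model has
        the LOWEST mean AUC, i.e. it discards the most informative feature
        first; with one dominant planted feature that feature must then be
        eliminated in the first loop."""
        table = sf.generate_feature_table(
            sf.CohortSpec(seed=16, feature_effects={"duration_s": 2.5})
        )
        cfg = sf.SelectionConfig(B=30, seed=8, literal_elimination=True)
        trace, _ = sf.rfe_rank(table, CANDIDATES_8[:4], cfg)
        assert trace.loops[0].eliminated == "duration_s"

    def test_null_first_elimination_is_exchangeable(self):
        """With all-noise features no candidate should be systematically
        eliminated first (chi-square over seeded runs, alpha = 0.01)."""
        feats = CANDIDATES_8[:4]
        counts = dict.fromkeys(feats, 0)
        for seed in range(150):
            table = sf.generate_feature_table(
                null_spec(1000 + seed, n_robust=21, n_frail=30)
            )
            cfg = sf.SelectionConfig(B=10, seed=seed)
            trace, _ = sf.rfe_rank(table, feats, cfg, compute_subset_curve=False)
            counts[trace.loops[0].eliminated] += 1
        chi2 = sps.chisquare(list(counts.values()))
        assert chi2.pvalue > 0.01


class TestSelectOptimal:
    @staticmethod
    def ranking(features, phenos, aucs):
        return sf.FeatureRanking(
            features=tuple(features),
            phenotypes=dict(zip(features, phenos)),
            subset_auc={k + 1: a for k, a in enumerate(aucs)},
        )

    def test_reference_scenario_selects_top_three(self):
        """Top-3 covering slowness/weakness/exhaustion with AUC 0.852 > 0.8
        is the smallest admissible prefix."""
        r = self.ranking(
            ["a", "b", "c", "d"],
            ["slowness", "weakness", "exhaustion", "exhaustion"],
            [0.78, 0.79, 0.852, 0.86],
        )
        res = sf.select_optimal(r, sf.SelectionConfig())
        assert res.admissible and res.k == 3
        assert res.selected == ("a", "b", "c")
        assert res.auc == pytest.approx(0.852)

    def test_single_phenotype_ranking_is_inadmissible(self):
        r = self.ranking(["a", "b"], ["slowness", "slowness"], [0.9, 0.95])
        res = sf.select_optimal(r, sf.SelectionConfig())
        assert not res.admissible
        assert res.selected == ()

    def test_coverage_and_threshold_first_met_at_k5(self):
        r = self.ranking(
            ["a", "b", "c", "d", "e"],
            ["slowness", "slowness", "weakness", "weakness", "exhaustion"],
            [0.7, 0.75, 0.78, 0.79, 0.81],
        )
        res = sf.select_optimal(r, sf.SelectionConfig())
        assert res.k == 5 and res.auc == pytest.approx(0.81)

    def test_auc_above_threshold_but_no_coverage_keeps_searching(self):
        r = self.ranking(
            ["a", "b", "c"],
            ["slowness", "weakness", "exhaustion"],
            [0.95, 0.96, 0.97],
        )
        res = sf.select_optimal(r, sf.SelectionConfig())
        assert res.k == 3  # coverage only complete at k=3 despite high AUCs
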