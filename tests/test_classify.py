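import dataclasses

import numpy as np
import pytest
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from braingut.classify import (
    FeatureSelectingClassifier,
    ModelSpec,
    auroc,
    cross_disease_specificity,
    cross_study_validation,
    feature_importance,
    leaky_cv_auroc,
    loco_cv,
    log_abundance,
    nested_cv,
    tune_final,
    univariate_auc_scores,
)
from braingut.simulate import SimulationParams, simulate_dataset

FAST = ModelSpec(family="lasso_logistic", search_budget=4)


class TestAurocOracle:
    def test_matches_mann_whitney_on_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.normal(size=n)
            u = stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided")
            n1, n0 = (y == 1).sum(), (y == 0).sum()
            oracle = u.statistic / (n1 * n0)
            assert auroc(y, s) == pytest.approx(oracle, abs=1e-12)

    def test_univariate_scores_identify_informative_feature(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 20))
        y = rng.integers(0, 2, 80)
        X[:, 7] += 2.0 * y
        assert univariate_auc_scores(X, y).argmax() == 7


class TestFeatureSelectingClassifier:
    def test_requires_both_classes(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError):
            FeatureSelectingClassifier(spec=FAST).fit(X, np.zeros(10))

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 30))
        y = rng.integers(0, 2, 40)
        a = FeatureSelectingClassifier(spec=FAST, random_state=5).fit(X, y)
        b = FeatureSelectingClassifier(spec=FAST, random_state=5).fit(X, y)
        np.testing.assert_array_equal(a.selected_features_, b.selected_features_)
        assert a.best_params_ == b.best_params_
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_sklearn_get_set_params_roundtrip(self):
        clf = FeatureSelectingClassifier(spec=FAST, inner_folds=3, random_state=9)
        params = clf.get_params(deep=False)
        clone = FeatureSelectingClassifier(**params)
        assert clone.inner_folds == 3 and clone.random_state == 9

    @pytest.mark.parametrize("family", ["lasso_logistic", "random_forest", "gradient_boosting"])
    def test_separable_feature_learned(self, family):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 10))
        y = rng.integers(0, 2, 60)
        X[:, 0] = y + rng.normal(0, 0.05, 60)
        spec = ModelSpec(family=family, search_budget=3)
        clf = FeatureSelectingClassifier(spec=spec, random_state=0).fit(X, y)
        assert auroc(y, clf.decision_scores(X)) >= 0.95


class TestNestedCV:
    def test_null_data_auroc_near_chance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 100))
        y = np.array([0, 1] * 30)
        rep = nested_cv(X, y, spec=FAST, repeats=2, outer_folds=5, seed=0)
        assert 0.35 <= rep.mean_auroc <= 0.65

    def test_separable_data_high_auroc(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 50))
        y = np.array([0, 1] * 30)
        X[:, 3] = y * 3 + rng.normal(0, 0.1, 60)
        rep = nested_cv(X, y, spec=FAST, repeats=1, outer_folds=5, seed=0)
        assert rep.mean_auroc >= 0.95

    def test_reproducibility_and_oof_coverage(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 20))
        y = np.array([0, 1] * 20)
        a = nested_cv(X, y, spec=FAST, repeats=2, outer_folds=4, seed=3)
        b = nested_cv(X, y, spec=FAST, repeats=2, outer_folds=4, seed=3)
        np.testing.assert_array_equal(a.fold_aurocs, b.fold_aurocs)
        np.testing.assert_array_equal(a.oof_probabilities, b.oof_probabilities)
        # every sample predicted exactly once per repeat
        assert not np.isnan(a.oof_probabilities).any()

    def test_outer_folds_stratified(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0] * 24 + [1] * 16)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        global_ratio = y.mean()
        for _, te in skf.split(np.zeros(40), y):
            assert abs(y[te].sum() - global_ratio * len(te)) <= 1

    def test_leakage_contrast(self):
        """Selection-before-CV inflates null AUROC; the nested procedure
        does not."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 500))
        y = np.array([0, 1] * 30)
        leaky = leaky_cv_auroc(X, y, k=32, folds=5, seed=0)
        safe = nested_cv(X, y, spec=FAST, repeats=2, outer_folds=5, seed=0).mean_auroc
        assert leaky > 0.7
        assert safe <= 0.6


class TestLOCO:
    def test_needs_three_cohorts(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 5))
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError, match="3 cohorts"):
            loco_cv(X, y, ["a"] * 10 + ["b"] * 10, spec=FAST)

    def test_homogeneous_strong_signal(self):
        ds = simulate_dataset(SimulationParams(
            n_studies=3, cases_per_study=30, controls_per_study=30,
            n_taxa=60, n_disease_taxa=8, effect_size=3.0, batch_sd=0.0, seed=51))
        X = log_abundance(ds.profiles.values)
        rep = loco_cv(X, ds.labels(), ds.studies(), spec=FAST, seed=0)
        assert all(v >= 0.9 for v in rep.cohort_aurocs.values())

    def test_inverted_cohort_detected(self):
        """A cohort whose planted effect is inverted scores below chance
        while the concordant cohorts stay high."""
        p = SimulationParams(n_studies=4, cases_per_study=30, controls_per_study=30,
                             n_taxa=60, n_disease_taxa=8, effect_size=3.0,
                             batch_sd=0.0, seed=52)
        ds = simulate_dataset(p)
        X = log_abundance(ds.profiles.values)
        y = ds.labels().copy()
        studies = ds.studies()
        y[studies == "study_4"] = 1 - y[studies == "study_4"]  # invert one cohort
        rep = loco_cv(X, y, studies, spec=FAST, seed=0)
        assert rep.cohort_aurocs["study_4"] < 0.5
        for c in ("study_1", "study_2", "study_3"):
            assert rep.cohort_aurocs[c] > 0.8

    def test_null_brackets_chance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(90, 40))
        y = np.array([0, 1] * 45)
        rep = loco_cv(X, y, ["a"] * 30 + ["b"] * 30 + ["c"] * 30, spec=FAST, seed=1)
        vals = list(rep.cohort_aurocs.values())
        assert min(vals) < 0.5 < max(vals) or all(abs(v - 0.5) < 0.15 for v in vals)


class TestFinalModelAndTiers:
    def test_tuning_and_fit_auroc_ordering_on_signal(self):
        ds = simulate_dataset(SimulationParams(
            n_studies=3, cases_per_study=25, controls_per_study=25,
            n_taxa=60, n_disease_taxa=8, effect_size=1.5, batch_sd=0.0, seed=53))
        X, y = log_abundance(ds.profiles.values), ds.labels()
        rep = nested_cv(X, y, spec=FAST, repeats=1, outer_folds=5, seed=0)
        feats = rep.consensus_features()
        model, tuning, fit = tune_final(X, y, feats, spec=FAST, seed=0)
        assert fit >= tuning - 0.02
        assert tuning >= rep.mean_auroc - 0.05

    def test_single_separable_feature_perfect_fit(self):
        rng = np.random.default_rng(10)
        y = np.array([0, 1] * 25)
        X = np.column_stack([y + rng.normal(0, 0.01, 50), rng.normal(size=50)])
        model, tuning, fit = tune_final(X, y, [0], spec=FAST, seed=0)
        assert fit == 1.0

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            tune_final(np.zeros((10, 2)), np.array([0, 1] * 5), [], spec=FAST)

    def test_cross_study_homogeneous_vs_batch_stressed(self):
        spec = FAST
        p = SimulationParams(n_studies=3, cases_per_study=30, controls_per_study=30,
                             n_taxa=60, n_disease_taxa=8, effect_size=2.0,
                             batch_sd=0.0, seed=54)
        homog = simulate_dataset(p)
        Xh = log_abundance(homog.profiles.values)
        mat = cross_study_validation(Xh, homog.labels(), homog.studies(),
                                     spec=spec, seed=0, nested_repeats=1)
        off = mat.values[~np.eye(3, dtype=bool)]
        diag = np.diag(mat.values)
        assert off.mean() >= diag.mean() - 0.1

        stressed = simulate_dataset(dataclasses.replace(
            p, effect_size=0.7, batch_sd=3.0, seed=55))
        Xs = stressed.profiles.values  # raw fractions: biases not log-additive
        mat2 = cross_study_validation(Xs, stressed.labels(), stressed.studies(),
                                      spec=spec, seed=0, nested_repeats=1)
        off2 = mat2.values[~np.eye(3, dtype=bool)]
        diag2 = np.diag(mat2.values)
        assert diag2.mean() - off2.mean() >= 0.1

    def test_cross_study_needs_two_studies(self):
        with pytest.raises(ValueError):
            cross_study_validation(np.zeros((10, 3)), np.array([0, 1] * 5),
                                   ["a"] * 10, spec=FAST)

    def test_cross_disease_specificity_near_chance_for_disjoint_taxa(self):
        p = SimulationParams(n_studies=1, cases_per_study=60, controls_per_study=60,
                             n_taxa=80, n_disease_taxa=8, effect_size=2.0,
                             batch_sd=0.0, seed=56)
        target = simulate_dataset(p)
        Xt, yt = log_abundance(target.profiles.values), target.labels()
        clf = FeatureSelectingClassifier(spec=FAST, random_state=0).fit(Xt, yt)
        model, _, _ = tune_final(Xt, yt, clf.selected_features_, spec=FAST, seed=0)
        foreign = simulate_dataset(dataclasses.replace(p, seed=57, disease="MDD"))
        Xf, yf = log_abundance(foreign.profiles.values), foreign.labels()
        res = cross_disease_specificity(model, [("MDD", Xf, yf)])
        assert 0.35 <= res["MDD"] <= 0.65


class TestFeatureImportance:
    def test_abs_coefficient_rule(self):
        est = LogisticRegression(max_iter=200)
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, 30)
        est.fit(X, y)
        imp = feature_importance(est, ["a", "b", "c"])
        assert imp.rule == "abs-coefficient"
        np.testing.assert_allclose(
            list(imp.scores.values()), np.abs(est.coef_[0]))

    def test_forest_planted_feature_dominates(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(100, 5))
        y = rng.integers(0, 2, 100)
        X[:, 2] += 3 * y
        est = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        imp = feature_importance(est, list("abcde"))
        assert max(imp.scores, key=imp.scores.get) == "c"
        assert imp.rule == "impurity-decrease"

    def test_normalized_view_sums_to_one(self):
        est = LogisticRegression(max_iter=200)
        rng = np.random.default_rng(13)
        X, y = rng.normal(size=(30, 4)), rng.integers(0, 2, 30)
        est.fit(X, y)
        norm = feature_importance(est, list("abcd")).normalized()
        assert sum(norm.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unfitted_model_errors(self):
        with pytest.raises(Exception):
            feature_importance(LogisticRegression(), ["a"])
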