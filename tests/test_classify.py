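import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cortigen as cg
from cortigen.classify import ConfusionCounts, round_half_up


class TestStratifiedFolds:
    def test_study_fold_structure(self):
        labels = np.r_[np.ones(27), np.zeros(117)].astype(int)
        folds = cg.stratified_folds(labels, k=5, seed=0)
        for f in range(5):
            size = (folds == f).sum()
            pos = labels[folds == f].sum()
            assert size in (28, 29)
            assert pos in (5, 6)

    def test_single_fold_degenerate(self):
        labels = np.array([0, 1, 0, 1])
        assert (cg.stratified_folds(labels, k=1) == 0).all()

    def test_deterministic(self):
        labels = (np.arange(60) % 3 == 0).astype(int)
        a = cg.stratified_folds(labels, k=5, seed=42)
        b = cg.stratified_folds(labels, k=5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            cg.stratified_folds(np.r_[np.ones(3), np.zeros(50)], k=5)


class TestComputeMetrics:
    def test_unbalanced_worked_example(self):
        """Counts implying sensitivity 14/27 and specificity 103/117
        give accuracy 0.8125, PPV 0.5, NPV 103/116, F ~0.509."""
        counts = ConfusionCounts(tp=14, fn=13, tn=103, fp=14)
        metrics, flags = cg.compute_metrics(counts)
        assert metrics["accuracy"] == pytest.approx(0.8125)
        assert metrics["ppv"] == pytest.approx(0.5)
        assert metrics["npv"] == pytest.approx(103 / 116)
        assert metrics["f_score"] == pytest.approx(0.50909, abs=1e-5)
        assert not flags
        rounded = {k: round_half_up(v) for k, v in metrics.items()}
        assert (rounded["accuracy"], rounded["ppv"], rounded["npv"],
                rounded["f_score"]) == (0.81, 0.50, 0.89, 0.51)

    def test_degenerate_all_negative_predictions(self):
        counts = ConfusionCounts(tp=0, fn=0, tn=10, fp=0)
        metrics, flags = cg.compute_metrics(counts)
        assert metrics["sensitivity"] == 0.0 and "sensitivity" in flags
        assert metrics["specificity"] == 1.0

    def test_harmonic_mean_identity(self):
        counts = ConfusionCounts(tp=5, fn=5, tn=5, fp=5)
        metrics, _ = cg.compute_metrics(counts)
        assert metrics["ppv"] == metrics["sensitivity"] == 0.5
        assert metrics["f_score"] == pytest.approx(0.5)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(derandomize=True, max_examples=200)
    def test_identities_against_counting_oracle(self, tp, fn, tn, fp):
        if tp + fn + tn + fp == 0:
            return
        y_true = np.r_[np.ones(tp + fn), np.zeros(tn + fp)].astype(int)
        y_pred = np.r_[np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)].astype(int)
        counts = ConfusionCounts.from_predictions(y_true, y_pred)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (tp, fn, tn, fp)
        metrics, _ = cg.compute_metrics(counts)
        assert metrics["accuracy"] == pytest.approx((tp + tn) / counts.n, abs=1e-12)
        if tp + fn:
            assert metrics["sensitivity"] == pytest.approx(tp / (tp + fn), abs=1e-12)
        if metrics["ppv"] + metrics["sensitivity"] > 0:
            expected_f = 2 * metrics["ppv"] * metrics["sensitivity"] / (
                metrics["ppv"] + metrics["sensitivity"])
            assert metrics["f_score"] == pytest.approx(expected_f, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, tn=0, fp=0)


class TestConfusionReconstruction:
    def test_unique_reconstruction_apoe(self):
        counts = cg.confusion_from_rates(0.52, 0.88, n_pos=27, n_neg=117)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (14, 13, 103, 14)

    def test_unique_reconstruction_mapt(self):
        counts = cg.confusion_from_rates(0.46, 0.71, n_pos=50, n_neg=94)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (23, 27, 67, 27)

    def test_ambiguous_rates_rejected(self):
        # at n_pos = 1000 many integers round to 0.50
        with pytest.raises(ValueError, match="unique"):
            cg.confusion_from_rates(0.50, 0.88, n_pos=1000, n_neg=117)


class TestCvClassify:
    def test_separable_classes_high_accuracy(self, cohort, covars):
        config = cg.EffectConfig(
            seed=21, noise_sd=0.02,
            main_effect_apoe={"thickness": -3.0, "curvature": 3.0},
        )
        feats = cg.generate_features(cohort, config)
        report, _, _ = cg.cv_classify(feats, cohort.apoe_pos, covars, seed=1)
        assert report.metrics["accuracy"] >= 0.95

    def test_null_auc_near_half(self, covars, cohort):
        rng = np.random.default_rng(0)
        aucs = []
        for r in range(50):
            X = rng.normal(size=(144, 40))
            y = rng.permutation(cohort.apoe_pos.to_numpy())
            rep, _, _ = cg.cv_classify(X, y, covars, seed=int(rng.integers(2**31)))
            aucs.append(rep.metrics["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_pooled_predictions_cover_everyone_once(self, cohort, features, covars):
        report, _, _ = cg.cv_classify(features, cohort.apoe_pos, covars, seed=3)
        assert report.y_pred.shape == (144,)
        assert np.isin(report.fold_assignment, range(5)).all()
        assert np.bincount(report.fold_assignment).sum() == 144

    def test_row_permutation_invariance(self, cohort, features, covars):
        """Reordering participants (with the fold assignment carried
        along) leaves the pooled metrics identical."""
        y = cohort.apoe_pos.to_numpy()
        folds = cg.stratified_folds(y, k=5, seed=9)
        X = features.to_numpy()
        C = covars.to_numpy(dtype=float)
        rep1, _, _ = cg.cv_classify(X, y, C, fold_assignment=folds)
        perm = np.random.default_rng(1).permutation(144)
        rep2, _, _ = cg.cv_classify(X[perm], y[perm], C[perm], fold_assignment=folds[perm])
        for m in rep1.metrics:
            assert rep1.metrics[m] == pytest.approx(rep2.metrics[m], abs=1e-12)

    def test_deterministic_given_seed(self, cohort, features, covars):
        a, _, _ = cg.cv_classify(features, cohort.apoe_pos, covars, seed=7)
        b, _, _ = cg.cv_classify(features, cohort.apoe_pos, covars, seed=7)
        assert a.metrics == b.metrics
        np.testing.assert_array_equal(a.y_pred, b.y_pred)


class TestPermutationTest:
    def test_strong_effect_gives_zero_strict_p(self, cohort, covars):
        config = cg.EffectConfig(
            seed=22, noise_sd=0.02,
            main_effect_apoe={"thickness": -3.0, "curvature": 3.0},
        )
        feats = cg.generate_features(cohort, config)
        report = cg.permutation_test(feats, cohort.apoe_pos, covars, n_perm=19, seed=5)
        assert report.permutation_pvalues["auc"] == 0.0

    def test_tie_case_strict_vs_plus_one(self):
        """All-constant features: every permutation yields the same
        majority-class collapse, so the strict rule gives p = 0 while the
        (r+1)/(n+1) correction gives p = 1."""
        rng = np.random.default_rng(3)
        y = (np.arange(40) % 4 == 0).astype(int)
        X = rng.normal(size=(40, 5)) * 0 + np.arange(5)  # constant columns
        covars = rng.normal(size=(40, 3))
        strict = cg.permutation_test(X, y, covars, n_perm=9, k=2, seed=1, tie_rule="strict")
        plus = cg.permutation_test(X, y, covars, n_perm=9, k=2, seed=1, tie_rule="plus_one")
        assert strict.permutation_pvalues["accuracy"] == 0.0
        assert plus.permutation_pvalues["accuracy"] == 1.0

    def test_invalid_tie_rule(self, cohort, features, covars):
        with pytest.raises(ValueError, match="tie_rule"):
            cg.permutation_test(features, cohort.apoe_pos, covars, n_perm=1, tie_rule="bogus")


class TestWeightSummaries:
    def test_all_zero_weights(self):
        names = ["left_precuneus_thickness", "left_precuneus_area"]
        wmap = cg.summarize_weights([np.zeros(2)], feature_names=names)
        assert (wmap.region_importance == 0).all()

    def test_single_weight_example(self):
        names = ["left_precuneus_thickness", "right_insula_curvature"]
        w = np.array([-0.8, 0.0])
        wmap = cg.summarize_weights([w], feature_names=names)
        assert wmap.region_importance["left_precuneus"] == pytest.approx(0.8)
        assert wmap.metric_negative_sum["thickness"] == pytest.approx(-0.8)
        assert wmap.metric_positive_sum["thickness"] == 0.0

    def test_hand_computed_ranking(self):
        names = [
            "left_insula_area", "left_insula_thickness",
            "right_cuneus_area", "right_cuneus_curvature",
            "left_hippocampus_volume",
        ]
        fold_w = [np.array([0.5, -0.5, 0.1, 0.0, 0.2]),
                  np.array([0.3, -0.7, 0.1, 0.2, 0.0])]
        wmap = cg.summarize_weights(fold_w, feature_names=names)
        # averaged: insula (0.4, -0.6) -> 1.0; cuneus (0.1, 0.1) -> 0.2; hc 0.1
        assert list(wmap.top_regions(3).index) == [
            "left_insula", "right_cuneus", "left_hippocampus"]
        assert wmap.region_importance["left_insula"] == pytest.approx(1.0)
        assert wmap.metric_positive_sum["area"] == pytest.approx(0.5)
        assert wmap.metric_negative_sum["thickness"] == pytest.approx(-0.6)

    def test_unknown_feature_name_rejected(self):
        with pytest.raises(ValueError):
            cg.summarize_weights([np.zeros(1)], feature_names=["middle_nowhere_oops"])

    def test_null_importance_has_no_stable_ranking(self, cohort, covars):
        """Without class structure the region importance ranking is not
        reproducible across reruns (rank correlation near zero)."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        maps = []
        for r in range(2):
            feats = cg.generate_features(
                cohort, cg.EffectConfig(seed=int(rng.integers(2**31))).null())
            y = rng.permutation(cohort.apoe_pos.to_numpy())
            _, fw, _ = cg.cv_classify(feats, y, covars, seed=int(rng.integers(2**31)))
            maps.append(cg.summarize_weights(fw, feature_names=list(feats.columns)))
        rho, _ = spearmanr(maps[0].region_importance, maps[1].region_importance)
        assert abs(rho) < 0.5
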