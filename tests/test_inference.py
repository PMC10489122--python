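import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cortigen as cg

from conftest import ols_oracle


def bh_brute_force(p):
    """Step-up Benjamini-Hochberg adjusted p-values by direct definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestCorrections:
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_bh_matches_brute_force(self, pvals):
        report = cg.adjust_pvalues(pvals, method="fdr_bh")
        np.testing.assert_allclose(report.adjusted_pvalues, bh_brute_force(pvals), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_bonferroni_matches_definition(self, pvals):
        report = cg.adjust_pvalues(pvals, method="bonferroni")
        expected = np.minimum(1.0, np.asarray(pvals) * len(pvals))
        np.testing.assert_allclose(report.adjusted_pvalues, expected, atol=1e-12)

    def test_single_test_identity(self):
        report = cg.adjust_pvalues([0.031], method="fdr_bh")
        assert report.adjusted_pvalues[0] == pytest.approx(0.031)
        report = cg.adjust_pvalues([0.031], method="bonferroni")
        assert report.adjusted_pvalues[0] == pytest.approx(0.031)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            cg.adjust_pvalues([0.5], method="fishing")


class TestUnivariateScan:
    def test_global_null_rarely_rejects(self):
        """Mirrors a mass-univariate scan on a null cohort: after FDR
        correction across 286 features, rejections are absent in at
        least 90% of simulated cohorts."""
        clean = 0
        runs = 20
        for seed in range(runs):
            cohort = cg.generate_cohort(seed=seed)
            feats = cg.generate_features(cohort, cg.EffectConfig(seed=seed).null())
            report = cg.univariate_scan(
                feats, cohort.apoe_pos, cohort[["age", "sex", "education", "tiv"]])
            clean += report.reject.sum() == 0
        assert clean / runs >= 0.9

    def test_massive_effect_is_detected(self, cohort):
        config = cg.EffectConfig(seed=1).null()
        feats = cg.generate_features(cohort, config)
        target = "left_insula_curvature"
        shift = feats[target].std() * 4
        feats.loc[cohort.apoe_pos == 1, target] += shift
        report = cg.univariate_scan(
            feats, cohort.apoe_pos, cohort[["age", "sex", "education", "tiv"]])
        frame = report.to_frame().set_index("name")
        assert bool(frame.loc[target, "reject"])

    def test_volume_features_use_tiv(self, cohort, features):
        # removing tiv must fail when volume features are present
        with pytest.raises(ValueError, match="intracranial"):
            cg.univariate_scan(features, cohort.apoe_pos,
                               cohort[["age", "sex", "education"]])

    def test_constant_feature_skipped_with_warning(self, cohort, features):
        feats = features.copy()
        feats["left_insula_area"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            report = cg.univariate_scan(
                feats, cohort.apoe_pos, cohort[["age", "sex", "education", "tiv"]])
        assert "left_insula_area" not in report.names


def _distance_fixture(cohort, planted_sd=0.0, cluster=0, seed=0, n_clusters=4):
    rng = np.random.default_rng(seed)
    n = len(cohort)
    d = rng.normal(1.0, 0.1, size=(n, n_clusters)) + rng.normal(0, 1, size=(n, n_clusters))
    double = ((cohort.apoe_pos == 1) & (cohort.mapt_pos == 1)).to_numpy()
    d[double, cluster] += planted_sd
    return pd.DataFrame(d, columns=[f"cluster_{c}" for c in range(n_clusters)])


class TestInteractionGLM:
    def test_matches_ols_oracle(self, cohort):
        dist = _distance_fixture(cohort, planted_sd=0.7, seed=1)
        results, _ = cg.interaction_glm(
            dist, cohort.apoe_pos, cohort.mapt_pos, cohort[["age", "sex", "education"]])
        r = results[0]
        design = np.column_stack([
            np.ones(len(cohort)), cohort.apoe_pos, cohort.mapt_pos,
            cohort.apoe_pos * cohort.mapt_pos,
            cohort.age, cohort.sex, cohort.education,
        ])
        # oracle design column order: const, apoe, mapt, interaction, covars
        _, t, p = ols_oracle(dist["cluster_0"], design)
        term = r.term("apoe:mapt")
        assert term["t"] == pytest.approx(t[3], abs=1e-8)
        assert term["p"] == pytest.approx(p[3], abs=1e-8)

    def test_planted_interaction_detected_with_sign(self, cohort):
        dist = _distance_fixture(cohort, planted_sd=2.0, cluster=1, seed=2)
        results, report = cg.interaction_glm(
            dist, cohort.apoe_pos, cohort.mapt_pos, cohort[["age", "sex", "education"]])
        assert report.reject[1]
        assert results[1].term("apoe:mapt")["estimate"] > 0

    def test_bonferroni_is_over_clusters(self, cohort):
        dist = _distance_fixture(cohort, seed=3)
        _, report = cg.interaction_glm(
            dist, cohort.apoe_pos, cohort.mapt_pos, cohort[["age", "sex", "education"]])
        np.testing.assert_allclose(
            report.adjusted_pvalues, np.minimum(1, report.raw_pvalues * 4), atol=1e-12)

    def test_empty_genotype_cell_rejected(self, cohort):
        sub = cohort[~((cohort.apoe_pos == 1) & (cohort.mapt_pos == 1))].reset_index(drop=True)
        dist = _distance_fixture(sub, seed=4)
        with pytest.raises(ValueError, match=r"empty genotype cell.*1, 1"):
            cg.interaction_glm(dist, sub.apoe_pos, sub.mapt_pos,
                               sub[["age", "sex", "education"]])

    def test_constant_distances_flagged_degenerate(self, cohort):
        dist = _distance_fixture(cohort, seed=5)
        dist["cluster_2"] = 1.0
        results, _ = cg.interaction_glm(
            dist, cohort.apoe_pos, cohort.mapt_pos, cohort[["age", "sex", "education"]])
        assert results[2].degenerate
        assert results[2].term("apoe:mapt")["t"] == 0.0


class TestClusterMetricGLM:
    @pytest.fixture()
    def assignment(self, features):
        prof = cg.zscore_profiles(features)
        model = cg.GHSOM(random_state=0).fit(prof.profiles)
        return cg.assign_regions(model, prof)

    def test_single_region_cluster_reduces_to_region_glm(self, cohort, features):
        region = "left_insula"
        assignment = cg.ghsom.ClusterAssignment(
            labels=pd.Series([0], index=[region]),
            centroids=pd.DataFrame([[0.0] * 4], columns=list(cg.atlas.CORTICAL_METRICS)),
            distance_to_centroid=pd.Series([0.0], index=[region]),
        )
        res = cg.cluster_metric_glm(
            features, assignment, 0, "curvature",
            cohort.apoe_pos, cohort.mapt_pos, cohort[["age", "sex", "education"]])
        design = np.column_stack([
            np.ones(len(cohort)), cohort.apoe_pos, cohort.mapt_pos,
            cohort.apoe_pos * cohort.mapt_pos, cohort.age, cohort.sex, cohort.education])
        _, t, _ = ols_oracle(features[f"{region}_curvature"], design)
        assert res.term("apoe:mapt")["t"] == pytest.approx(t[3], abs=1e-8)

    def test_planted_curvature_interaction_is_metric_specific(self, cohort, assignment):
        """An interaction planted only in curvature and folding index of
        the designated regions shows up in those metrics' cluster means
        and not in area or thickness."""
        config = cg.EffectConfig(
            seed=8,
            main_effect_apoe={}, main_effect_mapt={},
            interaction_effect={"curvature": 1.2, "folding_index": 1.2},
            covariate_slopes={},
        )
        feats = cg.generate_features(cg.generate_cohort(seed=8), config)
        cohort8 = cg.generate_cohort(seed=8)
        prof = cg.zscore_profiles(feats)
        model = cg.GHSOM(random_state=8).fit(prof.profiles)
        asg = cg.assign_regions(model, prof)
        # find the cluster holding the interaction regions
        target_region = config.interaction_regions[0]
        cluster = int(asg.labels[target_region])
        covars = cohort8[["age", "sex", "education"]]
        ps = {
            metric: cg.cluster_metric_glm(
                feats, asg, cluster, metric, cohort8.apoe_pos, cohort8.mapt_pos, covars
            ).term("apoe:mapt")["p"]
            for metric in ("curvature", "folding_index", "area", "thickness")
        }
        assert ps["curvature"] < 0.05 and ps["folding_index"] < 0.05
        assert ps["area"] > 0.05 and ps["thickness"] > 0.05

    def test_empty_cluster_rejected(self, cohort, features, assignment):
        with pytest.raises(ValueError, match="no member"):
            cg.cluster_metric_glm(
                features, assignment, 99, "curvature",
                cohort.apoe_pos, cohort.mapt_pos, cohort[["age", "sex", "education"]])
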