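"""Ward clustering, PCA views, cluster labeling, and the QC filter."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

import aostress as a
from aostress.cluster import (cluster_replicates, filter_experiments,
                              label_clusters, pca_profiles)
from aostress.normalize import normalize_cascade
from aostress.types import ClusterModel, NormalizedPanel, ValidationError


def _panel_from_values(values: pd.DataFrame, provenance: pd.DataFrame
                       ) -> NormalizedPanel:
    return NormalizedPanel(values=values, provenance=provenance,
                           control_means=pd.DataFrame())


def _fake_model(assignment: pd.Series, n_clusters: int) -> ClusterModel:
    return ClusterModel(assignment=assignment, n_clusters=n_clusters,
                        linkage=np.zeros((0, 4)), distance_space="log2")


class TestClustering:
    def test_two_clean_groups_recovered_exactly(self, two_group_panel):
        panel, truth = two_group_panel
        model = cluster_replicates(panel, n_clusters=2)
        planted = [truth.replicate_condition[r] for r in
                   model.assignment.index]
        assert adjusted_rand_score(planted, model.assignment) == 1.0

    def test_partition_invariant_to_replicate_order(self, two_group_panel):
        panel, _ = two_group_panel
        model = cluster_replicates(panel, n_clusters=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel.values.columns)
        shuffled = NormalizedPanel(values=panel.values[perm],
                                   provenance=panel.provenance.loc[perm],
                                   control_means=panel.control_means)
        model2 = cluster_replicates(shuffled, n_clusters=2)
        joined = pd.concat([model.assignment.rename("a"),
                            model2.assignment.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_identical_profiles_degenerate(self):
        values = pd.DataFrame(np.ones((4, 6)),
                              index=[f"G{i}" for i in range(4)],
                              columns=[f"E:S{j}" for j in range(6)])
        prov = pd.DataFrame({"experiment_id": "E", "condition": "control",
                             "stress_type": "none"}, index=values.columns)
        with pytest.raises(ValidationError, match="identical"):
            cluster_replicates(_panel_from_values(values, prov), 2)

    def test_too_many_clusters_rejected(self, two_group_panel):
        panel, _ = two_group_panel
        with pytest.raises(ValidationError, match="exceeds"):
            cluster_replicates(panel, n_clusters=1000)

    def test_merge_heights_nondecreasing(self, two_group_panel):
        panel, _ = two_group_panel
        model = cluster_replicates(panel, n_clusters=2)
        heights = model.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)


class TestPca:
    def test_explained_variance_sums_to_one(self, two_group_panel):
        panel, _ = two_group_panel
        _, evr = pca_profiles(panel)
        assert evr.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_matrix_single_component(self):
        col = np.array([1.0, 2.0, 4.0, 8.0])
        values = pd.DataFrame(np.outer([1.0, 1.0, 1.0], col),
                              index=[f"G{i}" for i in range(3)],
                              columns=[f"E:S{j}" for j in range(4)])
        prov = pd.DataFrame({"experiment_id": "E", "condition": "control",
                             "stress_type": "none"}, index=values.columns)
        _, evr = pca_profiles(_panel_from_values(values, prov),
                              space="linear")
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_preserve_pairwise_distances(self, two_group_panel):
        panel, _ = two_group_panel
        scores, _ = pca_profiles(panel)
        X = np.log2(panel.values.to_numpy().T + 1e-6)
        np.testing.assert_allclose(pdist(scores.to_numpy()), pdist(X),
                                   rtol=1e-9, atol=1e-9)

    def test_constant_matrix_rejected(self):
        values = pd.DataFrame(np.full((3, 4), 2.0),
                              index=[f"G{i}" for i in range(3)],
                              columns=[f"E:S{j}" for j in range(4)])
        prov = pd.DataFrame({"experiment_id": "E", "condition": "control",
                             "stress_type": "none"}, index=values.columns)
        with pytest.raises(ValidationError, match="constant"):
            pca_profiles(_panel_from_values(values, prov))


class TestLabeling:
    def _panel(self, conditions, stress_types):
        idx = [f"E:S{i}" for i in range(len(conditions))]
        prov = pd.DataFrame({"experiment_id": "E", "condition": conditions,
                             "stress_type": stress_types}, index=idx)
        values = pd.DataFrame(np.ones((2, len(idx))), columns=idx,
                              index=["G1", "G2"])
        return _panel_from_values(values, prov)

    def test_majority_control_cluster(self):
        panel = self._panel(["control"] * 5 + ["stress"],
                            ["none"] * 5 + ["cold"])
        model = _fake_model(pd.Series(1, index=panel.values.columns), 1)
        assert label_clusters(model, panel).cluster_types[1] == "control"

    def test_pure_cold_cluster_is_cr(self):
        panel = self._panel(["stress"] * 4, ["cold"] * 4)
        model = _fake_model(pd.Series(1, index=panel.values.columns), 1)
        assert label_clusters(model, panel).cluster_types[1] == "CR"

    def test_stress_type_tie_is_mixed(self):
        panel = self._panel(["stress"] * 4,
                            ["cold"] * 2 + ["water_deficiency"] * 2)
        model = _fake_model(pd.Series(1, index=panel.values.columns), 1)
        assert label_clusters(model, panel).cluster_types[1] == "mixed"


class TestFilter:
    def _setup(self, n_in_control):
        """One experiment, 10 stress reps, n_in_control of them clustered
        with the controls."""
        conditions = ["control"] * 4 + ["stress"] * 10
        idx = [f"E:S{i}" for i in range(14)]
        prov = pd.DataFrame(
            {"experiment_id": "E", "condition": conditions,
             "stress_type": ["none"] * 4 + ["cold"] * 10}, index=idx)
        values = pd.DataFrame(np.ones((2, 14)), columns=idx,
                              index=["G1", "G2"])
        panel = _panel_from_values(values, prov)
        labels = [1] * 4 + [1] * n_in_control + [2] * (10 - n_in_control)
        model = _fake_model(pd.Series(labels, index=idx), 2)
        return model, panel

    def test_exactly_half_retained(self):
        model, panel = self._setup(5)
        report = filter_experiments(model, panel)
        assert report.loc["E", "fraction"] == 0.5
        assert not report.loc["E", "excluded"]

    def test_strictly_above_half_excluded(self):
        model, panel = self._setup(6)
        report = filter_experiments(model, panel)
        assert report.loc["E", "fraction"] == pytest.approx(0.6)
        assert report.loc["E", "excluded"]

    def test_no_stress_replicates_flagged(self):
        conditions = ["control"] * 4
        idx = [f"E:S{i}" for i in range(4)]
        prov = pd.DataFrame({"experiment_id": "E", "condition": conditions,
                             "stress_type": ["none"] * 4}, index=idx)
        values = pd.DataFrame(np.ones((2, 4)), columns=idx,
                              index=["G1", "G2"])
        model = _fake_model(pd.Series([1] * 4, index=idx), 1)
        report = filter_experiments(model, _panel_from_values(values, prov))
        assert not report.loc["E", "excluded"]
        assert np.isnan(report.loc["E", "fraction"])
        assert report.loc["E", "flag"] == "no-stress-replicates"

    @pytest.mark.parametrize("start", [3, 4, 5])
    def test_filter_monotone_in_control_fraction(self, start):
        """Moving a stress replicate into a control cluster never rescues
        an excluded experiment."""
        m1, p1 = self._setup(start)
        m2, p2 = self._setup(start + 1)
        r1 = filter_experiments(m1, p1)
        r2 = filter_experiments(m2, p2)
        if r1.loc["E", "excluded"]:
            assert r2.loc["E", "excluded"]

    def test_planted_noisy_experiments_recovered(self):
        cfg = a.MetaSimConfig(seed=12, noisy_fraction=0.3)
        studies, truth = a.generate_meta_experiments(cfg)
        panel = normalize_cascade(studies)
        model = cluster_replicates(panel)
        report = filter_experiments(model, panel, rule="majority")
        assert set(report.index[report["excluded"]]) == \
            set(truth.noisy_experiments)

    def test_second_pass_excludes_only_stress_of_dropped(self):
        cfg = a.MetaSimConfig(seed=12, noisy_fraction=0.3)
        studies, truth = a.generate_meta_experiments(cfg)
        results = a.StressMetaAnalysis(
            studies, control_cluster_rule="majority").fit()
        prov2 = results.panel_retained.provenance
        for exp in truth.noisy_experiments:
            sub = prov2[prov2["experiment_id"] == exp]
            # controls of excluded experiments stay in the second pass
            assert (sub["condition"] == "control").all()
            assert len(sub) > 0
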