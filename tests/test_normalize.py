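"""Normalization cascade: formulas, invariants, I/O round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aostress as a
from aostress.io import read_meta_directory
from aostress.normalize import (control_relative_normalize, fpkm_normalize,
                                housekeeping_normalize, normalize_cascade)
from aostress.simulate import write_meta_experiments
from aostress.types import ValidationError

from conftest import make_study


class TestFpkm:
    def test_canonical_formula(self):
        # 10 counts on a 1 kb transcript in a library of 1e6 reads -> 10.0
        study = make_study([[10, 0], [999990, 1000000]],
                           ["control", "control"], platform="counts",
                           lengths=[1000.0, 2000.0], hk_index=1)
        out = fpkm_normalize(study)
        assert out.matrix.iloc[0, 0] == pytest.approx(10.0, abs=1e-12)
        assert out.matrix.iloc[0, 1] == 0.0
        assert out.platform == "intensity"

    def test_homogeneity_in_library_size(self):
        m = np.array([[10.0, 20.0], [40.0, 80.0], [50.0, 100.0]])
        study = make_study(m, ["control", "control"], platform="counts",
                           lengths=[500.0, 1500.0, 900.0], hk_index=2)
        out = fpkm_normalize(study)
        # second sample = first scaled by 2: identical FPKM values
        np.testing.assert_allclose(out.matrix.iloc[:, 0],
                                   out.matrix.iloc[:, 1])

    def test_intensity_passthrough_and_zero_total(self):
        study = make_study([[1.0, 2.0], [3.0, 4.0]], ["control", "control"])
        assert fpkm_normalize(study) is study
        bad = make_study([[0, 5], [0, 5]], ["control", "control"],
                         platform="counts")
        with pytest.raises(ValidationError, match="zero total"):
            fpkm_normalize(bad)


class TestHousekeeping:
    def test_division_and_self_normalization(self):
        study = make_study([[5.0, 2.0], [10.0, 8.0]], ["control", "control"])
        out = housekeeping_normalize(study)
        assert out.matrix.iloc[1, 0] == 2.0
        assert out.matrix.iloc[1, 1] == 4.0
        np.testing.assert_array_equal(out.matrix.iloc[0].to_numpy(),
                                      [1.0, 1.0])

    def test_idempotence(self):
        study = make_study([[5.0, 2.0], [10.0, 8.0]], ["control", "control"])
        once = housekeeping_normalize(study)
        twice = housekeeping_normalize(once)
        pd.testing.assert_frame_equal(once.matrix, twice.matrix)

    def test_zero_housekeeping_names_replicate(self):
        study = make_study([[5.0, 0.0], [10.0, 8.0]], ["control", "control"])
        with pytest.raises(ValidationError, match="S1"):
            housekeeping_normalize(study)


class TestControlRelative:
    def test_worked_example(self):
        # gene with control values (2, 4) and stress value 6
        study = make_study([[1.0, 1.0, 1.0], [2.0, 4.0, 6.0]],
                           ["control", "control", "stress"])
        panel = control_relative_normalize([study])
        np.testing.assert_allclose(
            panel.values.loc["G1"].to_numpy(),
            [2 / 3, 4 / 3, 2.0], atol=1e-12)

    def test_control_mean_is_one_by_construction(self, two_group_panel):
        panel, _ = two_group_panel
        for exp, sub in panel.provenance.groupby("experiment_id"):
            ctrl = sub.index[sub["condition"] == "control"]
            means = panel.values[list(ctrl)].mean(axis=1)
            np.testing.assert_allclose(means.to_numpy(), 1.0, atol=1e-9)

    def test_zero_control_mean_excluded_not_imputed(self):
        study = make_study([[1.0, 1.0, 1.0], [0.0, 0.0, 5.0], [2.0, 2.0, 4.0]],
                           ["control", "control", "stress"])
        panel = control_relative_normalize([study])
        assert ("G1", "EXP1") in panel.excluded
        assert panel.values.loc["G1"].isna().all()
        assert panel.values.loc["G2"].notna().all()

    def test_housekeeping_gene_dropped_from_panel(self):
        study = make_study([[1.0, 1.0], [2.0, 4.0]], ["control", "control"])
        panel = control_relative_normalize([study])
        assert "G0" not in panel.values.index

    def test_empty_study_list_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            control_relative_normalize([])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.1, 10.0), min_size=4, max_size=4))
    def test_batch_factor_invariance(self, factors):
        """Any per-replicate factor shared by all genes cancels out."""
        base = np.array([[8.0, 8.0, 8.0, 8.0],
                         [2.0, 3.0, 4.0, 5.0],
                         [7.0, 6.0, 2.0, 9.0]])
        conditions = ["control", "control", "stress", "stress"]
        s1 = make_study(base, conditions)
        s2 = make_study(base * np.array(factors)[None, :], conditions,
                        experiment_id="EXP1")
        p1 = control_relative_normalize([housekeeping_normalize(s1)])
        p2 = control_relative_normalize([housekeeping_normalize(s2)])
        np.testing.assert_allclose(p1.values.to_numpy(),
                                   p2.values.to_numpy(), rtol=1e-12)

    def test_two_batches_same_planted_fold_agree(self):
        """Experiments on different scales recover the same fold of 2."""
        cfg = a.MetaSimConfig(
            n_experiments=2, n_genes=5, n_control_reps=[3, 3],
            n_stress_reps=[3, 3], replicate_noise_sd=0.0,
            batch_scale_sd=2.0, signature_jitter_sd=0.0,
            count_dispersion=0.0, signature_fold={"cold": {1: 2.0}},
            stress_type_per_experiment=["cold", "cold"],
            platform_per_experiment=["intensity", "intensity"], seed=21)
        studies, truth = a.generate_meta_experiments(cfg)
        panel = normalize_cascade(studies)
        gene = truth.gene_ids[1]
        for exp in ("SIM000", "SIM001"):
            sub = panel.provenance.query(
                "experiment_id == @exp and condition == 'stress'")
            assert panel.values.loc[gene, list(sub.index)].mean() == \
                pytest.approx(2.0, rel=1e-9)

    def test_outputs_finite_and_nonnegative(self, two_group_panel):
        panel, _ = two_group_panel
        v = panel.values.to_numpy()
        assert np.isfinite(v).all() and (v >= 0).all()


class TestIo:
    def test_round_trip(self, tmp_path):
        studies, _ = a.generate_meta_experiments(a.MetaSimConfig(
            n_experiments=2, n_genes=5, n_control_reps=[2, 2],
            n_stress_reps=[2, 2], seed=13))
        write_meta_experiments(studies, tmp_path)
        back = read_meta_directory(tmp_path)
        assert len(back) == 2
        pd.testing.assert_frame_equal(back[0].matrix, studies[0].matrix)
        assert back[0].platform == studies[0].platform
        assert back[0].housekeeping_gene == studies[0].housekeeping_gene

    def test_missing_sample_column_named(self, tmp_path):
        studies, _ = a.generate_meta_experiments(a.MetaSimConfig(
            n_experiments=1, n_genes=4, n_control_reps=[2],
            n_stress_reps=[2], seed=13))
        write_meta_experiments(studies, tmp_path)
        samples = pd.read_csv(tmp_path / "samples.tsv", sep="\t",
                              index_col=0)
        samples.drop(index="S03").to_csv(tmp_path / "samples.tsv", sep="\t")
        with pytest.raises(ValidationError, match="S03"):
            read_meta_directory(tmp_path)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        studies, _ = a.generate_meta_experiments(a.MetaSimConfig(
            n_experiments=1, n_genes=4, n_control_reps=[2],
            n_stress_reps=[2], seed=13))
        write_meta_experiments(studies, tmp_path)
        mat = pd.read_csv(tmp_path / f"SIM000.matrix.tsv", sep="\t",
                          index_col=0)
        dup = pd.concat([mat, mat.iloc[[0]]])
        dup.to_csv(tmp_path / "SIM000.matrix.tsv", sep="\t")
        with pytest.raises(ValidationError, match="duplicated"):
            read_meta_directory(tmp_path)

    def test_nonnumeric_cells_rejected(self, tmp_path):
        studies, _ = a.generate_meta_experiments(a.MetaSimConfig(
            n_experiments=1, n_genes=4, n_control_reps=[2],
            n_stress_reps=[2], seed=13))
        write_meta_experiments(studies, tmp_path)
        path = tmp_path / "SIM000.matrix.tsv"
        mat = pd.read_csv(path, sep="\t", index_col=0).astype(object)
        mat.iloc[1, 1] = "abc"
        mat.to_csv(path, sep="\t")
        with pytest.raises(ValidationError, match="non-numeric"):
            read_meta_directory(tmp_path)

    def test_missing_housekeeping_rejected(self):
        with pytest.raises(ValidationError, match="housekeeping"):
            make_study([[1.0, 2.0]], ["control", "control"], hk_index=5)

    def test_fewer_than_two_controls_rejected(self):
        with pytest.raises(ValidationError, match=">=2 control"):
            make_study([[1.0, 2.0]], ["control", "stress"])
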