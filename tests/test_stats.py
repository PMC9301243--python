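import math

import numpy as np
import pandas as pd
import pytest

from flavomics import simulate as sim
from flavomics import stats as st


def _tiny_matrix(values, compounds, meta_rows):
    idx = pd.Index([r["sample_id"] for r in meta_rows], name="sample_id")
    vals = pd.DataFrame(values, index=idx, columns=compounds)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return st.IntensityMatrix(vals, meta)


def _meta(sample_id, cultivar="cv1", tissue="leaf", treatment="control",
          replicate=1, injection=1):
    return dict(sample_id=sample_id, cultivar=cultivar, tissue=tissue,
                treatment=treatment, replicate=replicate, injection=injection)


class TestIntensityMatrix:
    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="negative"):
            _tiny_matrix([[-1.0]], ["c1"], [_meta("s1")])

    def test_rejects_incomplete_meta(self):
        idx = pd.Index(["s1"], name="sample_id")
        vals = pd.DataFrame([[1.0]], index=idx, columns=["c1"])
        meta = pd.DataFrame({"cultivar": ["cv1"]}, index=idx)
        with pytest.raises(ValueError, match="missing metadata"):
            st.IntensityMatrix(vals, meta)

    def test_csv_roundtrip(self, tmp_path):
        m = _tiny_matrix([[1.5, 2.5]], ["c1", "c2"], [_meta("s1")])
        m.to_csv(tmp_path / "v.csv", tmp_path / "m.csv")
        back = st.IntensityMatrix.from_csv(tmp_path / "v.csv", tmp_path / "m.csv")
        pd.testing.assert_frame_equal(m.values, back.values)


class TestThresholds:
    def test_log2_threshold_derived_not_hardcoded(self):
        assert st.log2_threshold(2.5) == math.log2(2.5)
        assert st.log2_threshold(2.5) == pytest.approx(1.321928, abs=1e-6)
        assert round(st.log2_threshold(2.5), 1) == 1.3
        assert st.log2_threshold(0.4) == pytest.approx(-1.321928, abs=1e-6)

    def test_fc_gate_equivalence(self):
        # FC > 2.5 iff log2 FC > log2(2.5)
        for fc in (0.1, 0.4, 1.0, 2.5, 2.50001, 10.0):
            assert (fc > 2.5) == (math.log2(fc) > st.log2_threshold(2.5))


class TestFamilyRelativeAbundance:
    def test_two_equal_compounds(self):
        rows = [_meta("s1")]
        m = _tiny_matrix([[5.0, 5.0]], ["a", "b"], rows)
        pct = st.family_relative_abundance(m, {"a": "flavone", "b": "isoflavone"})
        assert pct.loc[("leaf", "cv1"), "flavone"] == pytest.approx(50.0)
        assert pct.loc[("leaf", "cv1"), "isoflavone"] == pytest.approx(50.0)

    def test_percentages_sum_to_100(self, lib):
        design = sim.StudyDesign()
        truth = sim.paper_like_truth(lib, design)
        m = sim.generate_intensities(design, truth, seed=2)
        fam = {c.name: c.family for c in lib.compounds}
        pct = st.family_relative_abundance(m, fam)
        np.testing.assert_allclose(pct.sum(axis=1), 100.0, atol=1e-9)

    def test_zero_total_errors(self):
        m = _tiny_matrix([[0.0, 0.0]], ["a", "b"], [_meta("s1")])
        with pytest.raises(ValueError, match="zero total"):
            st.family_relative_abundance(m, {"a": "flavone", "b": "flavone"})


class TestLeafRootRatio:
    def test_identical_tissues_ratio_one(self):
        rows = [_meta("s1", tissue="leaf"), _meta("s2", tissue="root")]
        m = _tiny_matrix([[3.0, 4.0], [3.0, 4.0]], ["a", "b"], rows)
        assert st.leaf_root_ratio(m)["cv1"] == pytest.approx(1.0)

    def test_sixteen_fold_preset(self, lib):
        design = sim.StudyDesign()
        truth = sim.make_truth(lib, design, biological_sd=0, technical_sd=0)
        m = sim.generate_intensities(design, truth, seed=0)
        ratios = st.leaf_root_ratio(m)
        assert ratios["LR4"] == pytest.approx(16.0)
        assert ratios["LR1"] == pytest.approx(4.6)
        # ordering mirrors the configured tolerance ordering
        assert ratios["LR1"] < ratios["LR2"] < ratios["LR3"] < ratios["LR4"]

    def test_missing_tissue_errors(self):
        m = _tiny_matrix([[1.0]], ["a"], [_meta("s1", tissue="leaf")])
        with pytest.raises(ValueError, match="both tissues"):
            st.leaf_root_ratio(m)


class TestGlycoProfile:
    def test_all_aglycone(self):
        m = _tiny_matrix([[1.0, 3.0]], ["a", "b"], [_meta("s1")])
        pct = st.glyco_profile(m, {"a": "Agly", "b": "Agly"})
        assert pct.loc[("leaf", "cv1"), "Agly"] == pytest.approx(100.0)

    def test_glyco_share_inversion(self, lib):
        design = sim.StudyDesign()
        shares = {
            "leaf": {"Agly": 0.1, "Gly": 0.5, "GlyGly": 0.3, "GlyGlyGly": 0.1},
            "root": {"Agly": 0.5, "Gly": 0.3, "GlyGly": 0.15, "GlyGlyGly": 0.05},
        }
        truth = sim.make_truth(lib, design, glyco_shares=shares,
                               biological_sd=0, technical_sd=0)
        m = sim.generate_intensities(design, truth, seed=0)
        glyco = {c.name: c.glyco_class for c in lib.compounds}
        acy = {c.name: c.acylated for c in lib.compounds}
        pct = st.glyco_profile(m, glyco, acy)
        assert pct.loc[("root", "LR1"), "Agly"] == pytest.approx(50.0)
        assert pct.loc[("leaf", "LR2"), "Gly"] == pytest.approx(50.0)
        classes = ["Agly", "Gly", "GlyGly", "GlyGlyGly"]
        np.testing.assert_allclose(pct[classes].sum(axis=1), 100.0, atol=1e-9)


class TestDifferentialTest:
    def _design_matrix(self, lib, effects=None, bio=0.0, tech=0.0, seed=0):
        design = sim.StudyDesign()
        truth = sim.make_truth(lib, design, effects=effects or {},
                               biological_sd=bio, technical_sd=tech)
        return sim.generate_intensities(design, truth, seed=seed)

    def test_identical_arms_unchanged(self, lib):
        m = self._design_matrix(lib)
        for r in st.differential_test(m, "leaf", "LR1"):
            assert r.fc == pytest.approx(1.0)
            assert r.regulation == "unchanged"
            assert r.p_value == 1.0

    def test_noise_free_daidzein_26(self, lib):
        m = self._design_matrix(lib, effects={"Daidzein": {("leaf", "LR1"): 2.6}})
        by = {r.compound: r for r in st.differential_test(m, "leaf", "LR1")}
        assert by["Daidzein"].log2fc == pytest.approx(2.6)
        assert by["Daidzein"].regulation == "up"

    def test_downregulation_flag(self, lib):
        m = self._design_matrix(lib, effects={"Daidzein": {("leaf", "LR1"): -2.0}})
        by = {r.compound: r for r in st.differential_test(m, "leaf", "LR1")}
        assert by["Daidzein"].fc == pytest.approx(0.25)
        assert by["Daidzein"].regulation == "down"

    def test_regulation_reproducible_from_thresholds(self, lib):
        design = sim.StudyDesign()
        truth = sim.paper_like_truth(lib, design)
        m = sim.generate_intensities(design, truth, seed=9)
        for r in st.differential_test(m, "root", "LR2"):
            expected = "unchanged"
            if r.p_value < 0.05 and r.fc > 2.5:
                expected = "up"
            elif r.p_value < 0.05 and r.fc < 0.4:
                expected = "down"
            assert r.regulation == expected
            assert r.log2fc == pytest.approx(math.log2(r.fc))
            assert r.fc == pytest.approx(r.mean_treated / r.mean_control)

    def test_too_few_replicates(self, lib):
        design = sim.StudyDesign(biological_replicates=1)
        truth = sim.make_truth(lib, design)
        m = sim.generate_intensities(design, truth, seed=0)
        with pytest.raises(ValueError, match="replicates"):
            st.differential_test(m, "leaf", "LR1")

    def test_differential_all_shape(self, lib):
        m = self._design_matrix(lib)
        table = st.differential_all(m)
        assert len(table) == 46 * 8
        assert set(table["regulation"]) == {"unchanged"}

    def test_benjamini_hochberg_monotone(self):
        p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
        adj = st.benjamini_hochberg(p)
        assert (adj >= p).all()
        assert (np.diff(adj[np.argsort(p)]) >= 0).all()


class TestAverageInjections:
    def test_means_and_shape(self, lib):
        design = sim.StudyDesign()
        truth = sim.make_truth(lib, design)
        m = sim.generate_intensities(design, truth, seed=1)
        avg = st.average_injections(m)
        assert len(avg.values) == 144 // 3
        sub = m.subset(cultivar="LR1", tissue="leaf", treatment="control", replicate=1)
        expected = sub.values.mean(axis=0)
        got = avg.subset(cultivar="LR1", tissue="leaf", treatment="control",
                         replicate=1).values.iloc[0]
        np.testing.assert_allclose(got.to_numpy(), expected.to_numpy())


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        data = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
            index=["a", "b", "c"],
        )
        res = st.hierarchical_cluster(data)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        x = np.array([1.0, 2.0, 3.0])
        assert st.pearson_distance(x, -x) == pytest.approx(2.0)
        assert st.pearson_distance(x, x) == pytest.approx(0.0)

    def test_zero_variance_row_excluded_with_warning(self):
        data = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
            index=["flat", "a", "b"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            res = st.hierarchical_cluster(data)
        assert res.excluded == ["flat"]
        assert len(res.labels) == 2

    def test_leaf_root_split(self, lib):
        # tissues have very different family composition; the top split of
        # the sample dendrogram must separate leaf from root
        design = sim.StudyDesign()
        truth = sim.paper_like_truth(lib, design)
        m = sim.generate_intensities(design, truth, seed=4)
        avg = st.average_injections(m)
        res = st.hierarchical_cluster(avg.values)
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(res.linkage, t=2, criterion="maxclust")
        tissues = avg.meta["tissue"].to_numpy()
        groups = {c: set(tissues[two == c]) for c in (1, 2)}
        assert groups[1] != groups[2]
        assert all(len(g) == 1 for g in groups.values())

    def test_newick_well_formed(self):
        data = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.1, 2.0, 2.9], [3.0, 1.0, 2.0], [2.9, 1.2, 2.0]],
            index=["a", "b", "c", "d"],
        )
        nwk = st.hierarchical_cluster(data).to_newick()
        assert nwk.endswith(";")
        assert nwk.count("(") == 3  # n-1 merges
        for label in "abcd":
            assert label in nwk


class TestPCA:
    def test_autoscaled_columns(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(5, 3, size=(20, 6)))
        xs = st.autoscale(data)
        np.testing.assert_allclose(xs.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(xs.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_rank_one_matrix_pc1_explains_all(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        data = pd.DataFrame(np.outer(base, [1.0, 2.0, -1.0]))
        res = st.pca_autoscaled(data)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(42)
        data = pd.DataFrame(rng.normal(size=(15, 8)))
        res = st.pca_autoscaled(data)
        # independent oracle: singular values of the autoscaled matrix
        xs = st.autoscale(data).to_numpy()
        sv = np.linalg.svd(xs, compute_uv=False)
        frac = sv**2 / (sv**2).sum()
        np.testing.assert_allclose(res.explained_variance, frac[: len(res.explained_variance)], atol=1e-9)

    def test_explained_variance_invariants(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(size=(12, 5)))
        ev = st.pca_autoscaled(data).explained_variance
        assert ((ev >= -1e-12) & (ev <= 1.0 + 1e-12)).all()
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 1.0 + 1e-9

    def test_scores_reconstruct_scaled_data(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(10, 4)))
        res = st.pca_autoscaled(data)
        xs = st.autoscale(data).to_numpy()
        np.testing.assert_allclose(res.scaled_reconstruction, xs, atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(10, 4)))
        loadings = st.pca_autoscaled(data).loadings.to_numpy()
        for j in range(loadings.shape[1]):
            assert loadings[np.argmax(np.abs(loadings[:, j])), j] > 0

    def test_zero_variance_variable_dropped(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        data["flat"] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = st.pca_autoscaled(data)
        assert res.dropped_variables == ["flat"]

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            st.pca_autoscaled(pd.DataFrame([[1.0, 2.0]]))
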