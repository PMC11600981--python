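import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from tmeflow import (build_cell_type_groups, cell_type_group_scores, combine_groups,
                     correlate_subgroups_modules)
from tmeflow.integration import CellTypeGroup


class TestCorrelate:
    def test_subgroup_equal_to_eigengene(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=100)
        idx = [f"s{i}" for i in range(100)]
        sg = pd.DataFrame({"NK.subgroup_1": v}, index=idx)
        eig = pd.DataFrame({"turquoise": v}, index=idx)
        r, p, surviving = correlate_subgroups_modules(sg, eig, 0.05)
        assert r.loc["NK.subgroup_1", "turquoise"] == pytest.approx(1.0)
        assert p.loc["NK.subgroup_1", "turquoise"] < 1e-10
        assert surviving == ["NK.subgroup_1"]

    def test_independent_noise_has_small_correlation(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(100)]
        sg = pd.DataFrame({"X.subgroup_1": rng.normal(size=100)}, index=idx)
        eig = pd.DataFrame({"turquoise": rng.normal(size=100)}, index=idx)
        r, _, _ = correlate_subgroups_modules(sg, eig, 0.05)
        assert abs(r.iloc[0, 0]) < 0.3

    def test_non_significant_subgroup_dropped(self):
        rng = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(100)]
        v = rng.normal(size=100)
        sg = pd.DataFrame({"A.subgroup_1": v, "B.subgroup_1": rng.normal(size=100)}, index=idx)
        eig = pd.DataFrame({"turquoise": v + rng.normal(0, 0.2, 100)}, index=idx)
        _, _, surviving = correlate_subgroups_modules(sg, eig, 1e-6)
        assert surviving == ["A.subgroup_1"]


class TestBuildGroups:
    def _corr_blocks(self):
        # two far-apart blocks of identical profiles
        rows = {
            "A.subgroup_1": [10.0, 10.0, 0.0],
            "B.subgroup_1": [10.0, 10.0, 0.0],
            "C.subgroup_1": [-10.0, 0.0, 10.0],
            "D.subgroup_1": [-10.0, 0.0, 10.0],
        }
        return pd.DataFrame(rows, index=["yellow", "blue", "green"]).T

    def test_two_blocks_two_groups_with_nomenclature(self):
        corr = self._corr_blocks()
        groups = build_cell_type_groups(
            corr, list(corr.index), {"yellow_blue_green": ["yellow", "blue", "green"]},
            cut_height=5.0, cut_mode="absolute")
        assert [g.group_id for g in groups] == [
            "Dendrogram_yellow_blue_green.group_1", "Dendrogram_yellow_blue_green.group_2"]
        member_sets = sorted(tuple(g.members) for g in groups)
        assert member_sets == [("A.subgroup_1", "B.subgroup_1"), ("C.subgroup_1", "D.subgroup_1")]

    def test_cut_above_root_gives_single_group(self):
        corr = self._corr_blocks()
        groups = build_cell_type_groups(
            corr, list(corr.index), {"yellow_blue_green": ["yellow", "blue", "green"]},
            cut_height=1e6, cut_mode="absolute")
        assert len(groups) == 1
        assert groups[0].group_id == "Dendrogram_yellow_blue_green.group_1"

    def test_partition_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        corr = pd.DataFrame(rng.normal(size=(10, 4)),
                            index=[f"X{i}.subgroup_1" for i in range(10)],
                            columns=["red", "turquoise", "black", "brown"])
        mg = {"red_turquoise_black_brown": list(corr.columns)}
        g1 = build_cell_type_groups(corr, list(corr.index), mg, cut_mode="quantile")
        perm = list(rng.permutation(corr.index))
        g2 = build_cell_type_groups(corr.loc[perm], perm, mg, cut_mode="quantile")
        assert sorted(tuple(g.members) for g in g1) == sorted(tuple(g.members) for g in g2)

    def test_ward_linkage_matches_r_hclust_ward_d2(self, tmp_path):
        """Cross-check the ward.D2 semantics against R's hclust on a fixed
        profile matrix: merge heights must agree."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(7, 3))
        Z = sch.linkage(X, method="ward")
        np.savetxt(tmp_path / "x.tsv", X, delimiter="\t")
        script = textwrap.dedent("""
            x <- as.matrix(read.table(commandArgs(TRUE)[1], sep="\\t"))
            h <- hclust(dist(x), method="ward.D2")
            cat(sprintf("%.10f\\n", h$height))
        """)
        (tmp_path / "ward.R").write_text(script)
        out = subprocess.run(["Rscript", str(tmp_path / "ward.R"), str(tmp_path / "x.tsv")],
                             capture_output=True, text=True, check=True)
        r_heights = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(r_heights), atol=1e-8)


class TestGroupScores:
    def test_single_member_group_is_z_scored_member(self):
        rng = np.random.default_rng(5)
        v = rng.normal(2, 3, size=40)
        sg = pd.DataFrame({"NK.subgroup_1": v}, index=[f"s{i}" for i in range(40)])
        groups = [CellTypeGroup("Dendrogram_red.group_1", "red", ["NK.subgroup_1"])]
        scores = cell_type_group_scores(groups, sg)
        np.testing.assert_allclose(scores.iloc[:, 0].values, (v - v.mean()) / v.std(), atol=1e-12)

    def test_duplicate_member_profile_equals_shared_vector(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=30)
        sg = pd.DataFrame({"A.subgroup_1": v, "B.subgroup_1": 5 * v + 2},
                          index=[f"s{i}" for i in range(30)])
        groups = [CellTypeGroup("Dendrogram_red.group_1", "red",
                                ["A.subgroup_1", "B.subgroup_1"])]
        scores = cell_type_group_scores(groups, sg)
        np.testing.assert_allclose(scores.iloc[:, 0].values, (v - v.mean()) / v.std(), atol=1e-12)

    def test_scores_zero_mean(self):
        rng = np.random.default_rng(7)
        sg = pd.DataFrame(rng.normal(size=(25, 3)), columns=["A.s1", "B.s1", "C.s1"],
                          index=[f"s{i}" for i in range(25)])
        groups = [CellTypeGroup("Dendrogram_red.group_1", "red", ["A.s1", "B.s1", "C.s1"])]
        scores = cell_type_group_scores(groups, sg)
        assert abs(scores.iloc[:, 0].mean()) < 1e-12

    def test_missing_member_errors_with_ids(self):
        sg = pd.DataFrame({"A.s1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        groups = [CellTypeGroup("Dendrogram_red.group_1", "red", ["A.s1", "GONE.s1"])]
        with pytest.raises(KeyError, match="GONE"):
            cell_type_group_scores(groups, sg)


class TestCombineGroups:
    def test_post_hoc_merge_naming(self):
        groups = [
            CellTypeGroup("Dendrogram_red_turquoise.group_1", "red_turquoise", ["A.s1"]),
            CellTypeGroup("Dendrogram_red_turquoise.group_2", "red_turquoise", ["B.s1"]),
            CellTypeGroup("Dendrogram_red_turquoise.group_3", "red_turquoise", ["C.s1"]),
        ]
        out = combine_groups(groups, [["Dendrogram_red_turquoise.group_1",
                                       "Dendrogram_red_turquoise.group_2"]])
        ids = sorted(g.group_id for g in out)
        assert ids == ["Dendrogram_red_turquoise.group_3",
                       "Dendrogram_red_turquoise.group_combined_1"]
        combined = [g for g in out if "combined" in g.group_id][0]
        assert combined.members == ["A.s1", "B.s1"]

    def test_cross_module_group_merge_rejected(self):
        groups = [CellTypeGroup("Dendrogram_red.group_1", "red", ["A.s1"]),
                  CellTypeGroup("Dendrogram_blue.group_1", "blue", ["B.s1"])]
        with pytest.raises(ValueError, match="same module group"):
            combine_groups(groups, [["Dendrogram_red.group_1", "Dendrogram_blue.group_1"]])
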