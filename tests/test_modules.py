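import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tmeflow import (coactivity_adjacency, detect_modules, hub_target_ora,
                     module_pathway_grouping, module_scores, select_hubs, tom_similarity)
from tmeflow.io import GeneSetCollection
from tmeflow.modules import GREY, hypergeom_ora_p


def _activity(values, tfs=None):
    values = np.asarray(values, dtype=float)
    tfs = tfs or [f"TF{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=tfs, columns=[f"s{i}" for i in range(values.shape[1])])


class TestAdjacency:
    def test_soft_threshold_values(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        act = _activity(np.vstack([base, base, -base, rng.normal(size=50)]))
        a = coactivity_adjacency(act, beta=6.0)
        assert a.iloc[0, 1] == pytest.approx(1.0)          # perfectly correlated
        assert a.iloc[0, 2] == pytest.approx(1.0)          # unsigned network
        assert np.allclose(np.diag(a.values), 0.0)

    def test_known_power_value(self):
        # construct y with exact r = 0.5 against x, so a = 0.5^6 = 0.015625
        rng = np.random.default_rng(1)
        x = np.array([1.0, -1.0, 1.0, -1.0, 2.0, -2.0, 0, 0])
        xs = x - x.mean()
        z = rng.normal(size=8)
        z = z - z.mean()
        z = z - xs * (xs @ z) / (xs @ xs)          # orthogonal to x
        y = 0.5 * xs / np.linalg.norm(xs) + math.sqrt(1 - 0.25) * z / np.linalg.norm(z)
        act = _activity(np.vstack([x, y]))
        a = coactivity_adjacency(act, beta=6.0)
        assert a.iloc[0, 1] == pytest.approx(0.5**6, abs=1e-12)

    def test_constant_row_errors(self):
        act = _activity([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="constant"):
            coactivity_adjacency(act)


class TestTom:
    def test_range_symmetry_diagonal(self):
        rng = np.random.default_rng(2)
        act = _activity(rng.normal(size=(12, 40)))
        tom = tom_similarity(coactivity_adjacency(act))
        assert ((tom.values >= 0) & (tom.values <= 1 + 1e-12)).all()
        assert np.allclose(tom.values, tom.values.T)
        assert np.allclose(np.diag(tom.values), 1.0)


class TestDetectModules:
    def _block_adjacency(self, sizes, within=0.9**6, between=0.0):
        n = sum(sizes)
        A = np.full((n, n), between)
        start = 0
        for s in sizes:
            A[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(A, 0.0)
        tfs = [f"TF{i:02d}" for i in range(n)]
        return pd.DataFrame(A, index=tfs, columns=tfs)

    def test_two_planted_blocks_recovered(self):
        adj = self._block_adjacency([10, 10])
        modules = detect_modules(adj, min_module_size=5)
        non_grey = {k: v for k, v in modules.items() if k != GREY}
        assert len(non_grey) == 2
        sets = sorted(frozenset(v) for v in non_grey.values())
        expected = sorted([frozenset(adj.index[:10]), frozenset(adj.index[10:])])
        assert sets == expected

    def test_all_zero_adjacency_is_all_grey(self):
        adj = self._block_adjacency([10, 10], within=0.0)
        modules = detect_modules(adj, min_module_size=5)
        assert set(modules) == {GREY}
        assert len(modules[GREY]) == 20

    def test_fewer_tfs_than_min_size_grey(self):
        adj = self._block_adjacency([3])
        modules = detect_modules(adj, min_module_size=5)
        assert set(modules) == {GREY}

    def test_color_names_by_decreasing_size(self):
        adj = self._block_adjacency([12, 7])
        modules = detect_modules(adj, min_module_size=5)
        assert len(modules["turquoise"]) == 12
        assert len(modules["blue"]) == 7


class TestModuleScores:
    def test_identical_members_give_unit_kme(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=30)
        act = _activity(np.vstack([base, base, -base]), ["a", "b", "c"])
        eig, kme = module_scores({"turquoise": ["a", "b"]}, act)
        z = (base - base.mean()) / base.std()
        np.testing.assert_allclose(eig["turquoise"].values, z, atol=1e-9)
        assert kme.loc["a", "turquoise"] == pytest.approx(1.0)
        assert kme.loc["c", "turquoise"] == pytest.approx(-1.0)  # anti-member

    def test_orientation_positive_with_mean_member_activity(self, default_cohort):
        from tmeflow import tf_activity_ulm
        from tmeflow.io import filter_regulons
        c = default_cohort
        act = tf_activity_ulm(c.expression, filter_regulons(c.regulons, c.expression.index))
        adj = coactivity_adjacency(act)
        modules = detect_modules(adj, tf_activity=act)
        eig, _ = module_scores(modules, act)
        for label, members in modules.items():
            if label == GREY:
                continue
            X = act.loc[members]
            z = (X.sub(X.mean(axis=1), axis=0)).div(X.std(axis=1), axis=0)
            assert np.corrcoef(eig[label].values, z.mean(axis=0).values)[0, 1] >= 0

    def test_eigengene_explains_at_least_average_member_variance(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=40)
        act = _activity(np.vstack([base + rng.normal(0, 0.5, 40) for _ in range(6)]))
        members = list(act.index)
        X = act.sub(act.mean(axis=1), axis=0).div(act.std(axis=1), axis=0).values.T
        _, s, _ = np.linalg.svd(X - X.mean(0), full_matrices=False)
        var_explained = s[0] ** 2 / (s ** 2).sum()
        assert var_explained >= 1.0 / len(members)


class TestHubs:
    def _setup(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=60)
        rows = [base + rng.normal(0, 0.2, 60) for _ in range(8)]
        rows += [rng.normal(size=60) for _ in range(12)]
        act = _activity(np.vstack(rows))
        adj = coactivity_adjacency(act)
        modules = {"turquoise": list(act.index[:8])}
        eig, kme = module_scores(modules, act)
        return act, adj, modules, kme

    def test_hub_needs_both_kme_and_degree(self):
        act, adj, modules, kme = self._setup()
        hubs = select_hubs(modules, kme, adj, kme_threshold=0.8, degree_quantile=0.6)
        assert hubs["turquoise"]
        for tf in hubs["turquoise"]:
            assert kme.loc[tf, "turquoise"] > 0.8
        degrees = adj.sum(axis=1)
        thr = np.quantile(degrees.values, 0.6)
        assert all(degrees[tf] >= thr for tf in hubs["turquoise"])

    def test_high_kme_low_degree_is_not_hub(self):
        act, adj, modules, kme = self._setup()
        # degree quantile so high no member passes
        hubs = select_hubs(modules, kme, adj, kme_threshold=0.8, degree_quantile=0.999)
        assert hubs["turquoise"] == [] or len(hubs["turquoise"]) <= 1

    def test_empty_hub_set_is_not_an_error(self):
        act, adj, modules, kme = self._setup()
        hubs = select_hubs(modules, kme, adj, kme_threshold=0.9999, degree_quantile=0.9)
        assert hubs["turquoise"] == []


class TestModulePathwayGrouping:
    def test_opposite_profile_module_isolated(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=40)
        w = rng.normal(size=40)
        eig = pd.DataFrame({"red": v, "turquoise": v + rng.normal(0, 0.05, 40), "brown": -v},
                           index=[f"s{i}" for i in range(40)])
        pw = pd.DataFrame(np.vstack([v, w]), index=["P1", "P2"], columns=eig.index)
        table, groups = module_pathway_grouping(eig, pw)
        assert set(groups) == {"red_turquoise", "brown"}
        assert sorted(groups["red_turquoise"]) == ["red", "turquoise"]

    def test_identical_module_and_pathway_correlate_perfectly(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=30)
        eig = pd.DataFrame({"red": v, "blue": rng.normal(size=30)},
                           index=[f"s{i}" for i in range(30)])
        pw = pd.DataFrame(v[None, :], index=["P1"], columns=eig.index)
        table, groups = module_pathway_grouping(eig, pw)
        row = table[(table["module"] == "red") & (table["pathway"] == "P1")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert set(groups) == {"red_blue"}    # < 3 modules: single group

    def test_too_few_samples_rejected(self):
        eig = pd.DataFrame({"red": [1, 2, 3]}, index=["a", "b", "c"])
        pw = pd.DataFrame([[1, 2, 3]], index=["P"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="shared samples"):
            module_pathway_grouping(eig, pw)


def brute_force_hypergeom(k, n, K, N):
    """Upper-tail overlap probability by exhaustive enumeration of all
    C(N, n) draws."""
    universe = range(N)
    in_set = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(in_set.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestOra:
    @pytest.mark.parametrize("k,n,K,N", [
        (4, 4, 5, 10),       # 5/210
        (0, 4, 5, 10),
        (2, 5, 6, 12),
        (3, 6, 8, 14),
        (1, 3, 2, 9),
    ])
    def test_hypergeometric_matches_enumeration(self, k, n, K, N):
        assert hypergeom_ora_p(k, n, K, N) == pytest.approx(brute_force_hypergeom(k, n, K, N), abs=1e-10)

    def test_printed_example_value(self):
        assert hypergeom_ora_p(4, 4, 5, 10) == pytest.approx(5 / 210, abs=1e-12)

    def test_minimum_overlap_gives_p_one(self):
        assert hypergeom_ora_p(0, 4, 5, 10) == pytest.approx(1.0)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_ora_p(5, 4, 5, 10)

    def _ora_inputs(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i:02d}" for i in range(30)]
        expr = pd.DataFrame(rng.uniform(0, 8, size=(30, 10)), index=genes,
                            columns=[f"s{i}" for i in range(10)])
        edges = [("TF1", g, 1.0) for g in genes[:8]]
        edges += [("TF2", g, 1.0) for g in genes[6:14]]   # overlap on g06, g07
        reg = pd.DataFrame(edges, columns=["source", "target", "weight"])
        sets = GeneSetCollection({"S1": genes[:10], "S2": genes[20:28]})
        return expr, reg, sets

    def test_shared_targets_excluded_from_both_modules(self):
        expr, reg, sets = self._ora_inputs()
        hubs = {"red": ["TF1"], "blue": ["TF2"]}
        res = hub_target_ora(hubs, reg, expr, sets, variability_quantile=0.0)
        # unique targets: red has g00-g05 (6), blue g08-g13 (6); shared g06, g07 dropped
        assert set(res[res["module"] == "red"]["n"]) == {6}
        assert set(res[res["module"] == "blue"]["n"]) == {6}

    def test_bh_q_monotone_and_at_least_p(self):
        expr, reg, sets = self._ora_inputs()
        res = hub_target_ora({"red": ["TF1"], "blue": ["TF2"]}, reg, expr, sets,
                             variability_quantile=0.0)
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()

    def test_no_hubs_anywhere_errors(self):
        expr, reg, sets = self._ora_inputs()
        with pytest.raises(ValueError, match="no module has hub TFs"):
            hub_target_ora({"red": []}, reg, expr, sets)
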