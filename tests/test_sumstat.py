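"""SUMSTAT statistic, normal null, elim decorrelation and empirical FDR."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from possel.lrt_processing import bh_fdr
from possel.ontology import GeneSetCollection, OntologyGraph
from possel.sumstat_enrichment import (
    elim_enrichment,
    empirical_null,
    null_params,
    outlier_diagnostic,
    permutation_fdr,
    sumstat_test,
)
from conftest import make_collection


def enumerate_null(scores, n):
    """Exhaustive without-replacement oracle: all C(N, n) set sums."""
    sums = [sum(c) for c in itertools.combinations(scores, n)]
    return np.mean(sums), np.var(sums)


class TestNullParams:
    def test_toy_enumeration_oracle(self, toy_background):
        # background {0,1,2,3}, n=2: sums {1,2,3,3,4,5} -> mean 3, var 5/3
        p = null_params(2, toy_background.to_numpy())
        assert p.mean == pytest.approx(3.0)
        assert p.var == pytest.approx(5.0 / 3.0)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6, 7])
    def test_enumeration_equivalence_on_small_backgrounds(self, n):
        rng = np.random.default_rng(42)
        scores = rng.gamma(2.0, 1.0, size=8)
        mean_o, var_o = enumerate_null(scores, n)
        p = null_params(n, scores)
        assert p.mean == pytest.approx(mean_o)
        assert p.var == pytest.approx(var_o)

    def test_full_background_has_zero_variance(self, toy_background):
        assert null_params(4, toy_background.to_numpy()).var == 0.0

    def test_iid_mode(self, toy_background):
        p = null_params(2, toy_background.to_numpy(), mode="iid")
        assert p.var == pytest.approx(2 * np.var([0, 1, 2, 3]))


class TestSumstatTest:
    def test_set_at_null_mean_gives_half(self, toy_background):
        res = sumstat_test(["g0", "g3"], toy_background)  # S = 3 = null mean
        assert res.p_enrich == pytest.approx(0.5)
        assert res.p_deplete == pytest.approx(0.5)

    def test_directional_pvalues_complementary(self, toy_background):
        res = sumstat_test(["g2", "g3"], toy_background)
        assert res.p_enrich + res.p_deplete == pytest.approx(1.0)
        assert res.p_enrich < 0.5  # S = 5 above null mean 3

    def test_degenerate_background_rejected(self):
        scores = pd.Series([2.0] * 6, index=[f"g{i}" for i in range(6)])
        with pytest.raises(ValueError, match="degenerate"):
            sumstat_test(["g0", "g1"], scores)

    def test_empty_set_and_outside_background_rejected(self, toy_background):
        with pytest.raises(ValueError, match="empty"):
            sumstat_test([], toy_background)
        with pytest.raises(ValueError, match="outside"):
            sumstat_test(["gX"], toy_background)

    def test_calibration_on_null_sets(self, null_scores_5000):
        # random sets from a null background: ~5% of tests at p < 0.05
        rng = np.random.default_rng(99)
        n_tests, hits = 2500, 0
        idx = null_scores_5000.index.to_numpy()
        for _ in range(n_tests):
            members = rng.choice(idx, size=25, replace=False)
            if sumstat_test(members, null_scores_5000).p_enrich < 0.05:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / n_tests)
        assert abs(hits / n_tests - 0.05) < 3 * se + 1e-3


class TestEmpiricalNull:
    def test_moments_match_fpc_params(self, toy_background):
        scores = toy_background.to_numpy()
        sample = empirical_null(2, scores, B=20000, seed=7)
        p = null_params(2, scores)
        assert sample.mean() == pytest.approx(p.mean, abs=4 * np.sqrt(p.var / 20000))
        assert sample.var() == pytest.approx(p.var, rel=0.05)

    def test_n_equal_one_recovers_background(self, toy_background):
        sample = empirical_null(1, toy_background.to_numpy(), B=4000, seed=3)
        assert set(np.unique(sample)) == {0.0, 1.0, 2.0, 3.0}

    @pytest.mark.parametrize("n", [11, 25, 100])
    def test_normal_approximation_ks(self, n, null_scores_5000):
        scores = null_scores_5000.to_numpy()
        sample = empirical_null(n, scores, B=10000, seed=n)
        p = null_params(n, scores)
        ks = stats.kstest(sample, "norm", args=(p.mean, np.sqrt(p.var))).statistic
        assert ks < 0.02

    def test_deterministic_under_seed(self, toy_background):
        a = empirical_null(2, toy_background.to_numpy(), B=50, seed=5)
        b = empirical_null(2, toy_background.to_numpy(), B=50, seed=5)
        np.testing.assert_array_equal(a, b)


def two_level_graph():
    g = nx.DiGraph()
    for t in ("root", "parent", "child", "other"):
        g.add_node(t, name=t, namespace="bp")
    g.add_edge("child", "parent")
    g.add_edge("parent", "root")
    g.add_edge("other", "root")
    return OntologyGraph(graph=g)


class TestElim:
    def _setup(self, rng, child_shift=2.0, n_child=20, n_neutral=20, n_bg=500):
        genes = [f"g{i}" for i in range(n_bg)]
        scores = pd.Series(rng.gamma(2.0, 0.5, n_bg), index=genes)
        child = genes[:n_child]
        scores.loc[child] += child_shift
        parent = genes[: n_child + n_neutral]
        coll = make_collection(
            {"child": child, "parent": parent, "other": genes[100:140],
             "root": genes},
            background=genes, min_size=5,
        )
        return coll, scores

    def test_significant_child_genes_removed_from_parent(self):
        rng = np.random.default_rng(0)
        coll, scores = self._setup(rng)
        res = elim_enrichment(coll, two_level_graph(), scores,
                              elim_alpha=0.01, min_size=5)
        res = res.set_index("term_id")
        assert res.loc["child", "p_enrich"] < 1e-6
        assert res.loc["parent", "genes_removed_by_elim"] == 20
        assert res.loc["parent", "n"] == 20  # only the neutral remainder

    def test_parent_calibrated_after_removal(self):
        # planted child, neutral parent remainder: parent significant at most
        # ~alpha of the time over replicates
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            coll, scores = self._setup(rng)
            res = elim_enrichment(coll, two_level_graph(), scores,
                                  elim_alpha=0.01, min_size=5)
            res = res.set_index("term_id")
            assert res.loc["child", "p_enrich"] < 0.01
            if res.loc["parent", "p_enrich"] < 0.05:
                hits += 1
        assert hits <= 4  # ~ alpha * reps plus slack

    def test_alpha_zero_equals_plain_tests(self):
        rng = np.random.default_rng(2)
        coll, scores = self._setup(rng)
        res = elim_enrichment(coll, two_level_graph(), scores,
                              elim_alpha=0.0, min_size=5).set_index("term_id")
        assert (res["genes_removed_by_elim"] == 0).all()
        for term in ("child", "parent", "other"):
            plain = sumstat_test(coll.sets[term], scores, term_id=term)
            assert res.loc[term, "p_enrich"] == pytest.approx(plain.p_enrich)

    def test_sibling_removals_take_union(self):
        g = nx.DiGraph()
        for t in ("root", "parent", "s1", "s2"):
            g.add_node(t, name=t, namespace="bp")
        g.add_edge("s1", "parent")
        g.add_edge("s2", "parent")
        g.add_edge("parent", "root")
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(400)]
        scores = pd.Series(rng.gamma(2.0, 0.5, 400), index=genes)
        shared = genes[:10]
        s1 = genes[:25]
        s2 = shared + genes[25:40]
        scores.loc[sorted(set(s1) | set(s2))] += 3.0
        coll = make_collection(
            {"s1": s1, "s2": s2, "parent": genes[:80], "root": genes},
            background=genes, min_size=5)
        res = elim_enrichment(coll, OntologyGraph(graph=g), scores,
                              elim_alpha=0.01, min_size=5).set_index("term_id")
        assert res.loc["parent", "genes_removed_by_elim"] == len(set(s1) | set(s2))

    def test_parent_below_min_size_reported_untested(self):
        rng = np.random.default_rng(4)
        coll, scores = self._setup(rng, n_neutral=3)
        res = elim_enrichment(coll, two_level_graph(), scores,
                              elim_alpha=0.01, min_size=5).set_index("term_id")
        assert not res.loc["parent", "tested"]
        assert np.isnan(res.loc["parent", "p_enrich"])


class TestPermutationFdr:
    def _observed(self, pvals):
        return pd.DataFrame({"term_id": [f"t{i}" for i in range(len(pvals))],
                             "p_enrich": pvals})

    def test_formula_arithmetic(self):
        # closure yields exactly 1 permutation positive on average at the
        # threshold where 10 observed terms are positive -> FDR 0.1
        obs = self._observed([0.001] * 10 + [0.9] * 40)
        scores = pd.Series(np.arange(50, dtype=float), index=range(50))

        calls = itertools.count()

        def closure(_):
            # one permutation p below 0.001, everything else at 0.5
            next(calls)
            return np.array([0.0005] + [0.5] * 49)

        out = permutation_fdr(obs, scores, closure, B=4, seed=0)
        assert out.loc[0, "fdr_empirical"] == pytest.approx(1 / 10)
        assert next(calls) == 4

    def test_fdr_clamped_to_one(self):
        obs = self._observed([0.04])
        scores = pd.Series(np.arange(10, dtype=float), index=range(10))
        out = permutation_fdr(obs, scores,
                              lambda _: np.array([0.001, 0.002, 0.003]),
                              B=2, seed=0)
        assert out.loc[0, "fdr_empirical"] == 1.0

    def test_invalid_b_rejected(self, toy_background):
        with pytest.raises(ValueError):
            permutation_fdr(self._observed([0.5]), toy_background,
                            lambda _: np.array([0.5]), B=0)

    def test_deterministic_under_seed(self, null_scores_5000):
        scores = null_scores_5000.iloc[:300]
        genes = scores.index.to_numpy()
        coll = make_collection(
            {f"t{i}": genes[15 * i: 15 * (i + 1)] for i in range(12)},
            background=genes, min_size=5)
        g = nx.DiGraph()
        for t in coll.sets:
            g.add_node(t)
        graph = OntologyGraph(graph=g)

        def closure(perm):
            return elim_enrichment(coll, graph, perm,
                                   min_size=5)["p_enrich"].to_numpy()

        obs = elim_enrichment(coll, graph, scores, min_size=5)
        a = permutation_fdr(obs, scores, closure, B=20, seed=11)
        b = permutation_fdr(obs, scores, closure, B=20, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_agrees_with_bh_on_null_data(self, null_scores_5000):
        # the empirical permutation FDR should track BH on null simulations
        max_diffs = []
        for rep in range(3):
            rng = np.random.default_rng(500 + rep)
            scores = null_scores_5000.sample(n=1000, random_state=rep)
            genes = scores.index.to_numpy()
            sets = {}
            for i in range(60):
                size = int(rng.integers(12, 40))
                sets[f"t{i:02d}"] = rng.choice(genes, size=size, replace=False)
            coll = make_collection(sets, background=genes, min_size=11)
            g = nx.DiGraph()
            for t in coll.sets:
                g.add_node(t)
            graph = OntologyGraph(graph=g)

            def closure(perm):
                return elim_enrichment(coll, graph, perm)["p_enrich"].to_numpy()

            obs = elim_enrichment(coll, graph, scores)
            out = permutation_fdr(obs, scores, closure, B=100, seed=rep)
            q = bh_fdr(out["p_enrich"].to_numpy())
            diffs = np.abs(out["fdr_empirical"].to_numpy() - q)
            max_diffs.append(diffs.max())
        assert max(max_diffs) <= 0.1


class TestOutlierDiagnostic:
    def test_reports_both_pvalues(self, null_scores_5000):
        scores = null_scores_5000.iloc[:200].copy()
        members = list(scores.index[:15])
        scores.loc[members[0]] = 10.0  # single outlier drives the set
        out = outlier_diagnostic(members, scores)
        assert out["dropped_gene"] == members[0]
        assert out["p_enrich_full"] < 0.01
        assert out["p_enrich_drop_top"] > 0.05
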