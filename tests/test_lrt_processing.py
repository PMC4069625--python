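"""Reconciliation, convergence filtering, chi-square p-values and BH FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from possel.lrt_processing import (
    ReplicateRuns,
    attach_pvalues,
    bh_fdr,
    convergence_filter,
    lrt_pvalue,
    process_runs,
    reconcile,
    reconcile_table,
    tabulate,
)


def make_runs(null, alt, fam="F1", br="#1"):
    return ReplicateRuns(fam, br, tuple(null), tuple(alt))


class TestReconcile:
    def test_best_run_difference_and_d(self):
        rec = reconcile(make_runs([-103.0, -103.0, -103.0],
                                  [-100.2, -100.25, -100.21]))
        assert rec.delta_lnl == pytest.approx(2.8)
        assert rec.d == pytest.approx(0.05)
        assert not rec.clamped

    def test_negative_ratio_clamped_to_zero(self):
        rec = reconcile(make_runs([-100.0] * 3, [-100.5] * 3))
        assert rec.delta_lnl == 0.0
        assert rec.lrt == 0.0
        assert rec.clamped

    def test_identical_runs_give_d_zero(self):
        rec = reconcile(make_runs([-50.0] * 3, [-49.0] * 3))
        assert rec.d == 0.0

    def test_run_order_invariance(self):
        null, alt = [-103.0, -102.5, -102.9], [-100.2, -100.25, -100.21]
        base = reconcile(make_runs(null, alt))
        for pn, pa in itertools.product(itertools.permutations(null),
                                        itertools.permutations(alt)):
            rec = reconcile(make_runs(list(pn), list(pa)))
            assert rec.delta_lnl == base.delta_lnl
            assert rec.d == base.d

    def test_wrong_run_count_rejected(self):
        with pytest.raises(ValueError, match="exactly 3"):
            ReplicateRuns("F1", "#1", (-1.0, -2.0), (-1.0, -2.0, -3.0))

    def test_nonfinite_lnl_rejected_with_family(self):
        with pytest.raises(ValueError, match="F9"):
            ReplicateRuns("F9", "#1", (-1.0, np.nan, -2.0), (-1.0, -2.0, -3.0))

    def test_table_reconciliation_matches_recordwise(self):
        rng = np.random.default_rng(5)
        rows = []
        expected = {}
        for i in range(20):
            null = (-1000 + rng.normal(0, 5, 3)).tolist()
            alt = (-1000 + rng.normal(0, 5, 3)).tolist()
            fam = f"F{i}"
            expected[fam] = reconcile(make_runs(null, alt, fam=fam))
            for r, v in enumerate(null):
                rows.append((fam, "#1", "null", r + 1, v))
            for r, v in enumerate(alt):
                rows.append((fam, "#1", "alt", r + 1, v))
        table = pd.DataFrame(rows, columns=["family_id", "branch_id",
                                            "hypothesis", "run", "lnl"])
        out = reconcile_table(table).set_index("family_id")
        for fam, rec in expected.items():
            assert out.loc[fam, "delta_lnl"] == pytest.approx(rec.delta_lnl)
            assert out.loc[fam, "d"] == pytest.approx(rec.d)
            assert bool(out.loc[fam, "clamped"]) == rec.clamped


class TestConvergenceFilter:
    def _records(self, ds):
        return pd.DataFrame({
            "family_id": [f"F{i}" for i in range(len(ds))],
            "branch_id": "#1",
            "delta_lnl": 1.0, "lrt": 2.0, "clamped": False,
            "d": ds,
        })

    def test_above_cutoff_excluded_boundary_kept(self):
        rec = convergence_filter(self._records([0.05, 0.004, 0.0039, 0.0]))
        assert rec["converged"].tolist() == [False, True, True, True]

    def test_infinite_cutoff_retains_all(self):
        rec = convergence_filter(self._records([0.05, 10.0]), cutoff=np.inf)
        assert rec["converged"].all()

    def test_records_conserved(self):
        rec = convergence_filter(self._records([0.05, 0.001, 0.2, 0.0]))
        assert rec["converged"].sum() + (~rec["converged"]).sum() == len(rec)


class TestLrtPvalue:
    @pytest.mark.parametrize("delta,expected", [
        (16.1, 1.4e-8),   # top branch-site hit
        (10.9, 3.0e-6),
        (8.3, 4.6e-5),    # top site-test hits
        (9.6, 1.2e-5),
        (8.9, 2.4e-5),
    ])
    def test_published_pvalues_reproduced(self, delta, expected):
        assert lrt_pvalue(delta) == pytest.approx(expected, rel=0.05)

    def test_zero_statistic_gives_p_one(self):
        assert lrt_pvalue(0.0) == 1.0

    def test_agrees_with_chi2_sf_oracle(self):
        grid = np.linspace(0, 50, 501)
        np.testing.assert_allclose(lrt_pvalue(grid), stats.chi2.sf(2 * grid, 1),
                                   rtol=1e-10)

    def test_strictly_decreasing(self):
        grid = np.linspace(0, 30, 301)
        assert np.all(np.diff(lrt_pvalue(grid)) < 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            lrt_pvalue(-0.1)


def bh_reference(p):
    """Independent step-up implementation (textbook formula)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([1e-4, 0.01, 0.03, 0.04]),
                                   [4e-4, 0.02, 0.04, 0.04])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_single_p_is_identity(self):
        assert bh_fdr([0.031])[0] == pytest.approx(0.031)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True, database=None)
    def test_matches_independent_step_up(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_reference(pvals), rtol=1e-10)


class TestTabulate:
    def _records(self):
        # F1 significant on Acep; F2 significant only on a merged branch in #6;
        # F3 not significant anywhere
        return pd.DataFrame({
            "family_id": ["F1", "F2", "F3", "F1"],
            "branch_id": ["Acep", "merged:#6", "Acep", "#1"],
            "delta_lnl": [10.0, 10.0, 0.1, 0.2],
            "lrt": [20.0, 20.0, 0.2, 0.4],
            "d": 0.0, "clamped": False, "converged": True,
        })

    def test_merged_counts_for_lineage_not_branch(self):
        out = tabulate(self._records(),
                       lineages={"formicidae": {"Acep", "#1", "#6"}})
        assert "merged:#6" not in out["per_branch"].index
        assert out["per_branch"].loc["Acep", "n_significant"] == 1
        assert out["per_lineage"]["formicidae"] == 2  # F1 + merged F2
        assert out["n_families_significant_any"] == 2

    def test_zero_significant_gives_zero_fractions(self):
        rec = self._records()
        rec["delta_lnl"] = 0.0
        rec["lrt"] = 0.0
        out = tabulate(rec)
        assert (out["per_branch"]["fraction"] == 0).all()
        assert out["n_families_significant_any"] == 0

    def test_unknown_branch_label_raises(self):
        with pytest.raises(ValueError, match="Nope"):
            rec = self._records()
            rec.loc[0, "branch_id"] = "Nope"
            tabulate(rec, known_branches={"Acep", "#1", "#6"})


class TestPipelineConservation:
    def test_pooled_series_includes_clamped_tests(self):
        rows = []
        for i, (null, alt) in enumerate([
            ([-100.0] * 3, [-98.0] * 3),       # delta 2
            ([-100.0] * 3, [-100.5] * 3),      # clamped
            ([-100.0, -100.0, -99.0], [-97.0, -98.5, -98.0]),  # d=1, excluded
        ]):
            for r, v in enumerate(null):
                rows.append((f"F{i}", "#1", "null", r + 1, v))
            for r, v in enumerate(alt):
                rows.append((f"F{i}", "#1", "alt", r + 1, v))
        runs = pd.DataFrame(rows, columns=["family_id", "branch_id",
                                           "hypothesis", "run", "lnl"])
        rec = process_runs(runs)
        assert len(rec) == 3
        assert rec["converged"].sum() == 2
        clamped = rec[rec["clamped"]]
        assert (clamped["p"] == 1.0).all()            # clamped test is in the series
        assert rec.loc[~rec["converged"], "p"].isna().all()
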