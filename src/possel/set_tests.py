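"""Fisher's-exact composition tests and targeted SUMSTAT tests with
permutation p-values.

Two complementary set-level analyses:

* composition tests — 2x2 Fisher's exact tests of term membership against
  membership in a gene subset (e.g. "is the analysed dataset biased in its
  functional makeup relative to the full annotated genome?"), combined with
  the same deepest-first elim gene removal used for score enrichment;

* targeted SUMSTAT tests — a handful of externally defined gene sets (e.g.
  caste-biased expression sets, aging contrasts) tested for enrichment of
  positive selection with an empirical permutation p-value and a Bonferroni
  threshold for the small number of planned tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from possel.ontology import GeneSetCollection, OntologyGraph, depth_order
from possel.sumstat_enrichment import empirical_null

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts (a, b; c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")


@dataclass
class TargetedSetResult:
    """Permutation SUMSTAT result for one externally defined gene set."""

    name: str
    n: int
    sumstat: float
    p: float
    direction: str  # "enrichment" or "depletion"
    bonferroni_alpha: float
    effect_size: float  # observed / expected SUMSTAT ratio


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p_two_sided)`` where the odds ratio is the sample
    ratio a*d / (b*c) (inf when b*c = 0 and a*d > 0) and the p-value sums the
    hypergeometric probabilities of tables at most as probable as the
    observed one (conditional on the margins).

    Raises on an all-zero row or column margin, where the test is undefined.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
        ContingencyTable2x2(a, b, c, d)  # validate
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError(f"zero margin in table [[{a},{b}],[{c},{d}]]")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return float(odds) if np.isfinite(odds) else odds, p


def composition_test(
    collection: GeneSetCollection,
    graph: OntologyGraph,
    subset: Iterable[str],
    reference: Iterable[str] | None = None,
    elim_alpha: float = 0.01,
    min_size: int | None = None,
) -> pd.DataFrame:
    """Per-term over/under-representation of ``subset`` within ``reference``.

    Each term contributes the 2x2 table (in subset & in term, in subset & not
    in term; not in subset & in term, not in subset & not in term), tested
    two-sided by Fisher's exact test.  Terms are processed deepest-first; the
    genes of a term with p < elim_alpha are removed from all its ancestors'
    sets before those are tested (topGO elim semantics).  BH FDR is attached
    across the tested terms and both directions are reported.
    """
    ref = frozenset(reference) if reference is not None else collection.background
    sub = frozenset(subset) & ref
    if not sub:
        raise ValueError("subset is empty (after intersecting with the reference)")
    if reference is not None and not frozenset(subset) <= ref:
        outside = len(frozenset(subset) - ref)
        logger.warning("composition_test: %d subset gene(s) outside the reference "
                       "were dropped", outside)
    if min_size is None:
        min_size = collection.min_size

    order = depth_order(graph, [t for t in collection.sets if t in graph.graph])
    removed: dict[str, set[str]] = {t: set() for t in order}
    n_sub, n_ref = len(sub), len(ref)
    rows = []
    for term in order:
        current = (collection.sets[term] & ref) - removed[term]
        if len(current) < min_size:
            rows.append({"term_id": term, "n": len(current), "tested": False,
                         "a": np.nan, "odds_ratio": np.nan, "p": np.nan,
                         "direction": ""})
            continue
        a = len(current & sub)
        b = n_sub - a
        c = len(current) - a
        d = (n_ref - n_sub) - c
        if min(a + b, c + d, a + c, b + d) == 0:
            # degenerate margin (e.g. subset = reference): no information
            odds, p = np.nan, 1.0
        else:
            odds, p = fisher_exact([[a, b], [c, d]])
        expected = n_sub * len(current) / n_ref
        rows.append({
            "term_id": term, "n": len(current), "tested": True,
            "a": a, "odds_ratio": odds, "p": p,
            "direction": "over" if a >= expected else "under",
        })
        if elim_alpha > 0 and p < elim_alpha:
            for anc in graph.ancestors(term):
                if anc in removed:
                    removed[anc] |= current
    out = pd.DataFrame(rows)
    from possel.lrt_processing import bh_fdr

    pvals = out["p"].to_numpy(dtype=float)
    mask = np.isfinite(pvals)
    q = np.full(pvals.shape, np.nan)
    if mask.any():
        q[mask] = bh_fdr(pvals[mask])
    out["fdr_bh"] = q
    return out


def targeted_set_test(
    gene_set: Iterable[str],
    scores: pd.Series,
    B: int = 10000,
    seed=None,
    k_tests: int = 1,
    name: str = "",
) -> TargetedSetResult:
    """Permutation SUMSTAT test of one externally defined gene set.

    The observed SUMSTAT S (sum of transformed scores of set members present
    in the background) is compared to B sums of equally sized random sets
    drawn without replacement.  The enrichment p-value uses the add-one
    convention p = (1 + #{permutation sums >= S}) / (1 + B), so p is never 0
    and its resolution is 1/(B+1).  The reported direction is the tail the
    observed S falls in; the depletion p is computed symmetrically.  A
    Bonferroni threshold 0.05/k_tests for the planned family of tests and the
    observed/expected ratio S/(n*mu_G) (a descriptive effect size) are
    attached.
    """
    if B < 100:
        warnings.warn(f"B={B} gives a coarse p-value resolution of 1/{B + 1}")
    members = sorted(set(gene_set) & set(scores.index))
    if not members:
        raise ValueError(f"gene set {name or '<unnamed>'} has no member in the background")
    n = len(members)
    s = float(scores.loc[members].sum())
    null = empirical_null(n, scores.to_numpy(dtype=float), B=B, seed=seed)
    p_enrich = (1 + int((null >= s).sum())) / (1 + B)
    p_deplete = (1 + int((null <= s).sum())) / (1 + B)
    expected = n * float(scores.mean())
    if p_enrich <= p_deplete:
        direction, p = "enrichment", p_enrich
    else:
        direction, p = "depletion", p_deplete
    return TargetedSetResult(
        name=name,
        n=n,
        sumstat=s,
        p=p,
        direction=direction,
        bonferroni_alpha=0.05 / k_tests,
        effect_size=s / expected if expected > 0 else np.nan,
    )


def targeted_set_tests(
    gene_sets: dict[str, Sequence[str]],
    scores: pd.Series,
    B: int = 10000,
    seed=None,
) -> pd.DataFrame:
    """Run targeted_set_test on each named set; k_tests = number of sets."""
    rng = np.random.default_rng(seed)
    k = len(gene_sets)
    rows = []
    for set_name in sorted(gene_sets):
        res = targeted_set_test(
            gene_sets[set_name], scores, B=B,
            seed=rng.integers(2**31), k_tests=k, name=set_name,
        )
        rows.append({
            "name": res.name, "n": res.n, "sumstat": res.sumstat,
            "p": res.p, "direction": res.direction,
            "bonferroni_alpha": res.bonferroni_alpha,
            "effect_size": res.effect_size,
            "significant": res.p < res.bonferroni_alpha,
        })
    return pd.DataFrame(rows)
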