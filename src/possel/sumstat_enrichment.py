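"""SUMSTAT gene-set enrichment with a CLT normal null, elim decorrelation and
permutation-based empirical FDR.

The SUMSTAT statistic of a gene set is the sum of the (fourth-root
transformed) selection scores of its n member genes.  Under the null that the
set is an exchangeable draw from the scored background G of size N, the sum
of n scores sampled without replacement is asymptotically normal with

    mean = n * mu_G
    var  = n * sigma2_G * (N - n) / (N - 1)     (finite-population form)

where mu_G and sigma2_G are the population mean and variance (divide-by-N) of
the background scores.  Bidirectional one-sided tests against this normal
give enrichment (upper tail) and depletion (lower tail) p-values.  An
``iid`` mode with var = n * sigma2_G is available for comparison.

Because ontology term sets are nested, raw results are highly redundant; the
elim procedure tests terms deepest-first and removes the genes of each
significant term from all of its ancestors' sets before those are tested.
Dependence among tests also makes analytic FDR doubtful, so an empirical FDR
is computed from permutations of the gene scores: at each observed p-value
threshold t, FDR(t) = N0(t) / Nt(t) with N0 the mean permutation positive
count and Nt the observed positive count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from possel.ontology import GeneSetCollection, OntologyGraph, depth_order

logger = logging.getLogger(__name__)

#: Default elim significance threshold (conventional default of the procedure).
ELIM_ALPHA = 0.01

#: Report sets below this empirical FDR.
FDR_REPORT_THRESHOLD = 0.20


@dataclass(frozen=True)
class NullParams:
    """Normal null of the SUMSTAT statistic for a set of size n."""

    n: int
    N: int
    mu_g: float
    var_g: float
    mean: float
    var: float


@dataclass
class EnrichmentResult:
    """SUMSTAT test result for one gene set."""

    term_id: str
    n: int
    sumstat: float
    z: float
    p_enrich: float
    p_deplete: float
    fdr_empirical: float = float("nan")
    fdr_bh: float = float("nan")
    genes_removed_by_elim: int = 0


def null_params(n: int, scores: np.ndarray, mode: str = "fpc") -> NullParams:
    """Null mean and variance of a SUMSTAT of n scores from background `scores`.

    ``mode="fpc"`` uses the without-replacement (finite population correction)
    variance n*sigma2*(N-n)/(N-1); ``mode="iid"`` uses n*sigma2.  sigma2 is
    the population variance (divide by N).
    """
    scores = np.asarray(scores, dtype=float)
    N = scores.size
    if not 1 <= n <= N:
        raise ValueError(f"set size n={n} out of range for background N={N}")
    mu = float(scores.mean())
    var_g = float(scores.var())  # population convention
    if mode == "fpc":
        if n == N:
            var = 0.0
        else:
            var = n * var_g * (N - n) / (N - 1)
    elif mode == "iid":
        var = n * var_g
    else:
        raise ValueError(f"unknown variance mode {mode!r} (expected 'fpc' or 'iid')")
    return NullParams(n=n, N=N, mu_g=mu, var_g=var_g, mean=n * mu, var=var)


def sumstat_test(
    term_genes: Iterable[str],
    scores: pd.Series,
    mode: str = "fpc",
    term_id: str = "",
) -> EnrichmentResult:
    """Bidirectional SUMSTAT test of one gene set against the normal null.

    Parameters
    ----------
    term_genes
        Member gene ids; must be a subset of ``scores.index`` (the background).
    scores
        Transformed selection scores indexed by gene id.
    mode
        Null variance mode, ``"fpc"`` or ``"iid"``.
    """
    members = list(term_genes)
    if not members:
        raise ValueError(f"term {term_id or '<unnamed>'}: empty gene set")
    missing = set(members) - set(scores.index)
    if missing:
        raise ValueError(
            f"term {term_id or '<unnamed>'}: {len(missing)} member(s) outside the "
            f"background, e.g. {sorted(missing)[:3]}"
        )
    vals = scores.to_numpy(dtype=float)
    params = null_params(len(members), vals, mode=mode)
    if params.var <= 0:
        raise ValueError(
            f"term {term_id or '<unnamed>'}: degenerate null (variance {params.var}); "
            "background scores all equal or n = N in without-replacement mode"
        )
    s = float(scores.loc[members].sum())
    z = (s - params.mean) / np.sqrt(params.var)
    return EnrichmentResult(
        term_id=term_id,
        n=len(members),
        sumstat=s,
        z=float(z),
        p_enrich=float(stats.norm.sf(z)),
        p_deplete=float(stats.norm.cdf(z)),
    )


def elim_enrichment(
    collection: GeneSetCollection,
    graph: OntologyGraph,
    scores: pd.Series,
    elim_alpha: float = ELIM_ALPHA,
    mode: str = "fpc",
    min_size: int | None = None,
) -> pd.DataFrame:
    """SUMSTAT tests over all terms with deepest-first elim decorrelation.

    Terms are processed deepest-first (longest-path depth, lexicographic tie
    break).  When a term's enrichment p-value falls below ``elim_alpha``, its
    member genes are removed from the sets of all its ancestors before those
    are tested.  Ancestors whose set drops below ``min_size`` after removal
    are reported with ``tested=False``.  Namespaces are kept separate by
    construction (terms of different namespaces share no ancestors).

    Setting ``elim_alpha=0`` disables all removals (plain per-term tests).

    Returns a DataFrame with one row per term: ``term_id, namespace, n,
    sumstat, z, p_enrich, p_deplete, genes_removed_by_elim, tested``.
    """
    if min_size is None:
        min_size = collection.min_size
    order = depth_order(graph, [t for t in collection.sets if t in graph.graph])
    dropped = set(collection.sets) - set(order)
    if dropped:
        logger.warning("elim_enrichment: %d term(s) absent from the ontology graph "
                       "were skipped", len(dropped))
    removed: dict[str, set[str]] = {t: set() for t in order}
    rows = []
    for term in order:
        current = collection.sets[term] - removed[term]
        n_removed = len(collection.sets[term]) - len(current)
        if len(current) < min_size:
            rows.append({
                "term_id": term,
                "namespace": collection.namespaces.get(term, ""),
                "n": len(current),
                "sumstat": np.nan, "z": np.nan,
                "p_enrich": np.nan, "p_deplete": np.nan,
                "genes_removed_by_elim": n_removed,
                "tested": False,
            })
            continue
        if mode == "fpc" and len(current) == len(collection.background):
            # n = N: the set is the whole background, the null is degenerate
            rows.append({
                "term_id": term,
                "namespace": collection.namespaces.get(term, ""),
                "n": len(current),
                "sumstat": float(scores.loc[sorted(current)].sum()), "z": np.nan,
                "p_enrich": np.nan, "p_deplete": np.nan,
                "genes_removed_by_elim": n_removed,
                "tested": False,
            })
            continue
        res = sumstat_test(current, scores, mode=mode, term_id=term)
        rows.append({
            "term_id": term,
            "namespace": collection.namespaces.get(term, ""),
            "n": res.n,
            "sumstat": res.sumstat, "z": res.z,
            "p_enrich": res.p_enrich, "p_deplete": res.p_deplete,
            "genes_removed_by_elim": n_removed,
            "tested": True,
        })
        if elim_alpha > 0 and res.p_enrich < elim_alpha:
            for anc in graph.ancestors(term):
                if anc in removed:
                    removed[anc] |= current
    return pd.DataFrame(rows)


def empirical_null(
    n: int,
    scores: np.ndarray,
    B: int = 10000,
    seed=None,
) -> np.ndarray:
    """B SUMSTAT values of random size-n sets drawn without replacement.

    Used to validate the normal approximation (e.g. by a KS distance against
    Normal(NullParams.mean, sqrt(NullParams.var))).
    """
    scores = np.asarray(scores, dtype=float)
    N = scores.size
    if not 1 <= n < N:
        raise ValueError(f"need 1 <= n < N, got n={n}, N={N}")
    rng = np.random.default_rng(seed)
    out = np.empty(B)
    for b in range(B):
        out[b] = scores[rng.choice(N, size=n, replace=False)].sum()
    return out


def permutation_fdr(
    observed: pd.DataFrame,
    scores: pd.Series,
    pipeline_closure: Callable[[pd.Series], np.ndarray],
    B: int = 100,
    seed=None,
    p_column: str = "p_enrich",
    monotone: bool = True,
) -> pd.DataFrame:
    """Empirical FDR at each observed p-value threshold via score permutation.

    Parameters
    ----------
    observed
        Enrichment results with a ``p_column`` of per-term p-values (NaN rows
        are ignored).
    scores
        The transformed background scores (index = gene ids); each
        permutation shuffles the score values over the same gene ids.
    pipeline_closure
        Callable rerunning the full enrichment (including elim) on a permuted
        score Series, returning the array of per-term p-values.
    B
        Number of permutations.
    monotone
        Enforce that the FDR is nondecreasing in the threshold (step-up
        minimum from the largest threshold down, as in q-value estimation),
        making the estimate directly comparable to BH-adjusted values.

    Returns
    -------
    ``observed`` with an added ``fdr_empirical`` column:
    FDR(t) = clamp(N0(t) / Nt(t), 0, 1) at t = each observed p, where N0 is
    the mean permutation count of p <= t and Nt the observed count; Nt = 0
    gives FDR 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    obs_p = observed[p_column].to_numpy(dtype=float)
    finite = np.isfinite(obs_p)
    thresholds = np.sort(obs_p[finite])

    perm_counts = np.zeros(thresholds.size)
    values = scores.to_numpy(dtype=float)
    for _ in range(B):
        permuted = pd.Series(rng.permutation(values), index=scores.index)
        p_perm = np.asarray(pipeline_closure(permuted), dtype=float)
        p_perm = p_perm[np.isfinite(p_perm)]
        # count permutation p-values <= each threshold
        perm_counts += np.searchsorted(np.sort(p_perm), thresholds, side="right")
    n0 = perm_counts / B

    # FDR at the k-th smallest observed p: N0 / k, optionally step-up
    # monotonized so the estimate cannot decrease as the threshold grows
    nt_at = np.arange(1, thresholds.size + 1, dtype=float)
    fdr_at = np.minimum(1.0, n0 / nt_at)
    if monotone:
        fdr_at = np.minimum.accumulate(fdr_at[::-1])[::-1]

    out = observed.copy()
    fdr = np.full(obs_p.shape, np.nan)
    for i, p in enumerate(obs_p):
        if not np.isfinite(p):
            continue
        nt = int(np.searchsorted(thresholds, p, side="right"))
        fdr[i] = 0.0 if nt == 0 else fdr_at[nt - 1]
    out["fdr_empirical"] = fdr
    return out


def attach_bh(observed: pd.DataFrame, p_column: str = "p_enrich") -> pd.DataFrame:
    """BH-adjusted values over the tested terms (NaN rows passed through)."""
    from possel.lrt_processing import bh_fdr

    out = observed.copy()
    p = out[p_column].to_numpy(dtype=float)
    mask = np.isfinite(p)
    q = np.full(p.shape, np.nan)
    if mask.any():
        q[mask] = bh_fdr(p[mask])
    out["fdr_bh"] = q
    return out


def outlier_diagnostic(
    term_genes: Iterable[str],
    scores: pd.Series,
    mode: str = "fpc",
    term_id: str = "",
) -> dict:
    """Recompute the enrichment p after dropping the set's top-scoring gene.

    Guards against a term looking significant only because of a single
    outlier member.  Returns both p-values and the removed gene id.
    """
    members = list(term_genes)
    full = sumstat_test(members, scores, mode=mode, term_id=term_id)
    top = max(members, key=lambda g: scores.loc[g])
    reduced_members = [g for g in members if g != top]
    if not reduced_members:
        raise ValueError(f"term {term_id or '<unnamed>'}: cannot drop the only member")
    reduced = sumstat_test(reduced_members, scores, mode=mode, term_id=term_id)
    return {
        "term_id": term_id,
        "p_enrich_full": full.p_enrich,
        "p_enrich_drop_top": reduced.p_enrich,
        "dropped_gene": top,
        "dropped_score": float(scores.loc[top]),
    }
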