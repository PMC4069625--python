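"""Reconciliation, convergence filtering and FDR control for replicated LRTs.

Codon-model likelihood optimisation is prone to convergence failures, so each
branch-site (or site) test is run three times per hypothesis.  The functions
here take the triplicate log-likelihoods, keep the best run of each
hypothesis, clamp negative log-likelihood ratios to zero, flag tests whose
within-hypothesis run discrepancy ``d`` exceeds a cutoff (default 0.004 nats,
which separates the well-converged mode at d = 0 from the failure mode at
d ~ 1), map the surviving statistics through the chi-square(1 df) upper tail,
and apply Benjamini-Hochberg FDR over the pooled series of all converged
tests.  Per-branch and per-lineage significance tallies account for "merged"
branches of gene trees with missing taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Default convergence cutoff on the run-discrepancy diagnostic d (nats).
D_CUTOFF = 0.004

#: Default significance threshold on BH-adjusted q-values.
Q_THRESHOLD = 0.10


@dataclass(frozen=True)
class ReplicateRuns:
    """Triplicate log-likelihoods of one test (one family, one foreground branch)."""

    family_id: str
    branch_id: str
    lnl_null: tuple[float, float, float]
    lnl_alt: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, vals in (("lnl_null", self.lnl_null), ("lnl_alt", self.lnl_alt)):
            if len(vals) != 3:
                raise ValueError(
                    f"{self.family_id}/{self.branch_id}: {name} must hold exactly "
                    f"3 runs, got {len(vals)}"
                )
            if not all(np.isfinite(v) for v in vals):
                raise ValueError(
                    f"{self.family_id}/{self.branch_id}: non-finite {name} {vals}"
                )


@dataclass
class TestRecord:
    """One reconciled branch-site (or site) test."""

    family_id: str
    branch_id: str
    delta_lnl: float          # reconciled max(lnL_alt) - max(lnL_null), clamped at 0
    lrt: float                # 2 * delta_lnl
    d: float                  # largest within-hypothesis run discrepancy (nats)
    clamped: bool             # raw delta_lnl was negative
    converged: bool = True    # d <= cutoff
    p: float = float("nan")
    q: float = float("nan")
    significant: bool = False
    extra: dict = field(default_factory=dict)  # ds_foreground, omega2, beb_max, ...


def reconcile(runs: ReplicateRuns) -> TestRecord:
    """Reconcile one triplicate test: best run per hypothesis, clamp, diagnostic d."""
    best_null = max(runs.lnl_null)
    best_alt = max(runs.lnl_alt)
    raw = best_alt - best_null
    clamped = raw < 0
    delta = 0.0 if clamped else raw
    d = max(best_null - min(runs.lnl_null), best_alt - min(runs.lnl_alt))
    return TestRecord(
        family_id=runs.family_id,
        branch_id=runs.branch_id,
        delta_lnl=delta,
        lrt=2.0 * delta,
        d=d,
        clamped=clamped,
    )


def reconcile_table(runs: pd.DataFrame) -> pd.DataFrame:
    """Vectorised reconciliation of a replicate-runs table.

    Parameters
    ----------
    runs
        Long-format table with columns ``family_id, branch_id, hypothesis,
        run, lnl`` where hypothesis is ``null`` or ``alt`` and each
        (family, branch, hypothesis) appears exactly 3 times.

    Returns
    -------
    One row per (family_id, branch_id) with columns
    ``delta_lnl, lrt, d, clamped``.
    """
    required = {"family_id", "branch_id", "hypothesis", "run", "lnl"}
    missing = required - set(runs.columns)
    if missing:
        raise ValueError(f"replicate-runs table missing columns: {sorted(missing)}")
    if not np.isfinite(runs["lnl"]).all():
        bad = runs.loc[~np.isfinite(runs["lnl"]), ["family_id", "branch_id"]]
        raise ValueError(
            "non-finite log-likelihoods for: "
            + ", ".join(f"{r.family_id}/{r.branch_id}" for r in bad.itertuples())
        )
    counts = runs.groupby(["family_id", "branch_id", "hypothesis"], sort=False).size()
    if (counts != 3).any():
        bad = counts[counts != 3].index.tolist()[:5]
        raise ValueError(f"expected exactly 3 runs per hypothesis; offending keys: {bad}")

    g = runs.groupby(["family_id", "branch_id", "hypothesis"], sort=False)["lnl"]
    agg = g.agg(["max", "min"]).unstack("hypothesis")
    best = agg["max"]
    rng = agg["max"] - agg["min"]
    raw = best["alt"] - best["null"]
    out = pd.DataFrame(
        {
            "delta_lnl": raw.clip(lower=0.0),
            "lrt": 2.0 * raw.clip(lower=0.0),
            "d": rng.max(axis=1),
            "clamped": raw < 0,
        }
    ).reset_index()
    return out


def convergence_filter(records: pd.DataFrame, cutoff: float = D_CUTOFF) -> pd.DataFrame:
    """Mark tests with run discrepancy d > cutoff as non-converged.

    The filter is strict: d equal to the cutoff is retained.  Non-converged
    records are kept in the table (for accounting) but must be excluded from
    the p-value/FDR series downstream; ``attach_pvalues`` does so.
    """
    records = records.copy()
    records["converged"] = records["d"] <= cutoff
    n_excl = int((~records["converged"]).sum())
    if n_excl:
        logger.info("convergence filter: excluded %d of %d tests (d > %g)",
                    n_excl, len(records), cutoff)
    return records


def lrt_pvalue(delta_lnl):
    """Upper-tail chi-square(1 df) probability of the statistic 2*delta_lnl.

    ``delta_lnl`` must already be clamped to be non-negative; p = 1 exactly
    when delta_lnl = 0 (a clamped, non-significant test).
    """
    arr = np.asarray(delta_lnl, dtype=float)
    if np.any(arr < 0):
        raise ValueError("delta_lnl must be non-negative (clamp upstream)")
    p = stats.chi2.sf(2.0 * arr, df=1)
    return float(p) if np.isscalar(delta_lnl) else p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values for one pooled p-value series."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_pvalues(
    records: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Compute p over converged records and BH q over the single pooled series.

    All converged tests — including clamped ones, whose p is exactly 1 — form
    one series (number of branches tested x number of families tested).
    Non-converged records get NaN p/q and are never significant.
    """
    records = records.copy()
    if "converged" not in records.columns:
        records["converged"] = True
    records["p"] = np.nan
    records["q"] = np.nan
    conv = records["converged"].to_numpy()
    records.loc[conv, "p"] = lrt_pvalue(records.loc[conv, "delta_lnl"].to_numpy())
    if conv.any():
        records.loc[conv, "q"] = bh_fdr(records.loc[conv, "p"].to_numpy())
    records["significant"] = (records["q"] <= q_threshold) & conv
    return records


def process_runs(
    runs: pd.DataFrame,
    d_cutoff: float = D_CUTOFF,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Full reconcile -> convergence-filter -> p/FDR pipeline on a runs table."""
    rec = reconcile_table(runs)
    rec = convergence_filter(rec, cutoff=d_cutoff)
    return attach_pvalues(rec, q_threshold=q_threshold)


# ---------------------------------------------------------------------------
# Tallies

MERGED_PREFIX = "merged:"


def _merged_container(branch_id: str) -> str | None:
    """Canonical label of the smallest clade containing a merged branch, else None."""
    if branch_id.startswith(MERGED_PREFIX):
        return branch_id[len(MERGED_PREFIX):]
    return None


def tabulate(
    records: pd.DataFrame,
    lineages: Mapping[str, Iterable[str]] | None = None,
    q_threshold: float = Q_THRESHOLD,
    known_branches: Iterable[str] | None = None,
) -> dict:
    """Per-branch and per-lineage significance tallies.

    Branch-specific counts cover canonical branches only; a family significant
    on a merged branch is not counted for any single branch but does count for
    every lineage whose branch set contains the merged branch's containing
    clade.  Fractions are relative to the number of families with a converged
    test on that branch.

    Parameters
    ----------
    records
        Output of :func:`attach_pvalues` with a ``branch_id`` column whose
        values are canonical labels or ``merged:<clade label>``.
    lineages
        Mapping lineage name -> set of canonical branch labels.  A family is
        counted for a lineage if it is significant on >= 1 branch of the set,
        merged branches included.
    known_branches
        Optional whitelist of canonical labels; an unknown (non-merged) label
        raises.
    """
    if "significant" not in records.columns:
        records = attach_pvalues(records, q_threshold=q_threshold)
    is_merged = records["branch_id"].str.startswith(MERGED_PREFIX)
    if known_branches is not None:
        known = set(known_branches)
        unknown = set(records.loc[~is_merged, "branch_id"]) - known
        if unknown:
            raise ValueError(f"unknown branch label(s): {sorted(unknown)}")

    canon = records[~is_merged]
    per_branch = (
        canon[canon["converged"]]
        .groupby("branch_id")
        .agg(
            n_tested=("family_id", "nunique"),
            n_significant=("significant", "sum"),
        )
    )
    per_branch["fraction"] = np.where(
        per_branch["n_tested"] > 0,
        per_branch["n_significant"] / per_branch["n_tested"],
        0.0,
    )

    sig = records[records["significant"]]
    per_lineage = {}
    if lineages:
        for name, branch_set in lineages.items():
            bset = set(branch_set)

            def in_lineage(b: str, bset=bset) -> bool:
                container = _merged_container(b)
                return (b in bset) if container is None else (container in bset)

            fams = sig.loc[sig["branch_id"].map(in_lineage), "family_id"].nunique()
            per_lineage[name] = int(fams)

    return {
        "per_branch": per_branch,
        "per_lineage": per_lineage,
        "n_families_significant_any": int(sig["family_id"].nunique()),
        "n_families_tested": int(records["family_id"].nunique()),
    }


def top_hits_filter(
    records: pd.DataFrame,
    internal_branches: Iterable[str] | None = None,
    max_ds: float = 1.0,
    min_beb: float = 0.9,
) -> pd.DataFrame:
    """Composable top-hit predicates: internal branches, dS < max_ds, BEB > min_beb.

    Columns ``ds_foreground`` and ``beb_max`` are optional; a predicate is only
    applied when its column is present.
    """
    mask = pd.Series(True, index=records.index)
    if internal_branches is not None:
        mask &= records["branch_id"].isin(set(internal_branches))
    if "ds_foreground" in records.columns:
        mask &= records["ds_foreground"] < max_ds
    if "beb_max" in records.columns:
        mask &= records["beb_max"] > min_beb
    return records[mask].sort_values("delta_lnl", ascending=False)
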