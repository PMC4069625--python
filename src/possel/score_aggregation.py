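"""Lineage-level per-family selection scores.

Each gene family carries one branch-site LRT per tested branch.  For gene-set
enrichment a single number per family is needed that summarises the evidence
for positive selection across a whole lineage: the arithmetic mean of the LRT
(2*delta lnL) over the converged tests on the lineage's branches, followed by
a fourth-root variance-stabilising transform.  The fourth root is strictly
monotone on [0, inf) so ranks are preserved; it is applied AFTER averaging.

Merged branches (gene-tree branches spanning several species-tree branches
because of missing taxa) are included in the mean when their containing clade
lies inside the lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from possel.lrt_processing import MERGED_PREFIX

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilyScore:
    """Lineage-level selection score of one gene family."""

    family_id: str
    n_branches_used: int
    mean_lrt: float
    transformed: float  # mean_lrt ** 0.25


def transform(scores):
    """Fourth-root variance-stabilising transform (rank-preserving)."""
    arr = np.asarray(scores, dtype=float)
    if np.any(arr < 0):
        raise ValueError("scores must be non-negative")
    out = arr ** 0.25
    return float(out) if np.isscalar(scores) else out


def _branch_in_lineage(branch_id: str, branch_set: set[str], include_merged: bool) -> bool:
    if branch_id.startswith(MERGED_PREFIX):
        return include_merged and branch_id[len(MERGED_PREFIX):] in branch_set
    return branch_id in branch_set


def lineage_score(
    records: pd.DataFrame,
    branch_set: Iterable[str],
    include_merged: bool = True,
    denominator: str = "available",
    use_delta_lnl: bool = False,
) -> FamilyScore:
    """Aggregate one family's converged branch tests into a FamilyScore.

    Parameters
    ----------
    records
        Test records of a single family (columns ``family_id, branch_id,
        lrt, delta_lnl, converged``).
    branch_set
        Canonical branch labels defining the lineage (e.g. the 13 ant
        branches).
    include_merged
        Count ``merged:<clade>`` branches whose containing clade is in
        branch_set.
    denominator
        ``"available"`` (mean over usable branches, the default) or
        ``"fixed"`` (divide by len(branch_set), treating absent branches
        as 0).
    use_delta_lnl
        Aggregate delta lnL instead of the LRT = 2*delta lnL scale.

    Raises
    ------
    ValueError
        If the family has no converged test on a branch of the lineage.
    """
    fam_ids = records["family_id"].unique()
    if len(fam_ids) != 1:
        raise ValueError(f"lineage_score expects one family, got {fam_ids!r}")
    bset = set(branch_set)
    usable = records[
        records["converged"]
        & records["branch_id"].map(lambda b: _branch_in_lineage(b, bset, include_merged))
    ]
    if usable.empty:
        raise ValueError(f"family {fam_ids[0]}: no converged test on lineage branches")
    col = "delta_lnl" if use_delta_lnl else "lrt"
    total = float(usable[col].sum())
    n_used = len(usable)
    denom = n_used if denominator == "available" else len(bset)
    if denominator not in ("available", "fixed"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    mean = total / denom
    return FamilyScore(
        family_id=str(fam_ids[0]),
        n_branches_used=n_used,
        mean_lrt=mean,
        transformed=transform(mean),
    )


def aggregate_scores(
    records: pd.DataFrame,
    branch_set: Iterable[str],
    include_merged: bool = True,
    denominator: str = "available",
    use_delta_lnl: bool = False,
) -> pd.DataFrame:
    """Vectorised lineage scores for all families in a test-record table.

    Families without any usable branch are dropped (logged).  Returns a frame
    with columns ``family_id, n_branches_used, mean_lrt, transformed``.
    """
    if denominator not in ("available", "fixed"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    bset = set(branch_set)
    usable = records[
        records["converged"]
        & records["branch_id"].map(lambda b: _branch_in_lineage(b, bset, include_merged))
    ]
    n_total = records["family_id"].nunique()
    col = "delta_lnl" if use_delta_lnl else "lrt"
    g = usable.groupby("family_id")[col].agg(["sum", "count"])
    dropped = n_total - len(g)
    if dropped:
        logger.info("aggregate_scores: %d of %d families had no usable branch and were dropped",
                    dropped, n_total)
    denom = g["count"] if denominator == "available" else len(bset)
    out = pd.DataFrame(
        {
            "family_id": g.index,
            "n_branches_used": g["count"].to_numpy(),
            "mean_lrt": (g["sum"] / denom).to_numpy(),
        }
    ).reset_index(drop=True)
    out["transformed"] = transform(out["mean_lrt"].to_numpy())
    return out
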