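"""End-to-end pipeline driver: process -> aggregate -> enrich.

`run_pipeline` wires the stages together on files in the formats of
:mod:`possel.formats`, writes every intermediate table, logs counts at each
stage and drops a resolved-configuration JSON next to the outputs so runs are
self-documenting and reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from possel import formats
from possel.lrt_processing import D_CUTOFF, Q_THRESHOLD, process_runs, tabulate
from possel.ontology import DEFAULT_MIN_SIZE, OntologyGraph, filter_sets, propagate
from possel.score_aggregation import aggregate_scores
from possel.sumstat_enrichment import (
    ELIM_ALPHA,
    FDR_REPORT_THRESHOLD,
    attach_bh,
    elim_enrichment,
    permutation_fdr,
)
from possel.synthetic_data import ANT_BRANCHES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and constants of one pipeline run.

    Defaults are the study constants: d cutoff 0.004 nats, 10% test FDR, 20%
    enrichment-reporting FDR, sets of more than 10 genes (more than 5 in
    phenotype mode), elim alpha 0.01, 100 score permutations for the
    empirical FDR, 10,000 permutations for targeted set tests.
    """

    input_dir: str = "."
    output_dir: str = "results"
    d_cutoff: float = D_CUTOFF
    fdr_threshold: float = Q_THRESHOLD
    enrich_fdr_threshold: float = FDR_REPORT_THRESHOLD
    min_set_size: int = DEFAULT_MIN_SIZE
    elim_alpha: float = ELIM_ALPHA
    fdr_perms: int = 100
    settest_perms: int = 10000
    variance_mode: str = "fpc"
    branch_set: tuple[str, ...] = ANT_BRANCHES
    seed: int = 0


def run_pipeline(config: PipelineConfig) -> dict:
    """Run process -> aggregate -> enrich on the files in ``config.input_dir``.

    Expects ``replicate_runs.tsv``, ``ontology.obo`` and ``associations.tsv``
    (the layout written by :func:`possel.formats.write_dataset`).  Returns a
    dict of stage summaries; writes ``test_records.tsv``,
    ``family_scores.tsv``, ``enrichment.tsv``, ``depletion.tsv`` and
    ``config.json`` under ``config.output_dir``.
    """
    ind, outd = Path(config.input_dir), Path(config.output_dir)
    outd.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    # stage 1: reconcile, filter, p/FDR
    runs = formats.read_runs(ind / "replicate_runs.tsv")
    records = process_runs(runs, d_cutoff=config.d_cutoff,
                           q_threshold=config.fdr_threshold)
    counts["tests_read"] = int(len(records))
    counts["tests_excluded_convergence"] = int((~records["converged"]).sum())
    counts["tests_clamped"] = int(records["clamped"].sum())
    counts["tests_significant"] = int(records["significant"].sum())
    formats.write_records(records, outd / "test_records.tsv")
    tallies = tabulate(records, q_threshold=config.fdr_threshold)
    counts["families_significant_any"] = tallies["n_families_significant_any"]

    # stage 2: lineage scores
    scores_df = aggregate_scores(records, config.branch_set)
    counts["families_scored"] = int(len(scores_df))
    formats.write_scores(scores_df, outd / "family_scores.tsv")

    # stage 3: SUMSTAT enrichment with elim + permutation FDR
    graph = OntologyGraph.from_obo(str(ind / "ontology.obo"))
    assoc = formats.read_associations(ind / "associations.tsv")
    collection = propagate(graph, assoc)
    scores = scores_df.set_index("family_id")["transformed"]
    background = [g for g in collection.background if g in scores.index]
    collection = filter_sets(collection, min_size=config.min_set_size,
                             background=background)
    counts["terms_testable"] = len(collection)
    scores = scores.loc[sorted(collection.background)]

    def closure(permuted: pd.Series) -> np.ndarray:
        res = elim_enrichment(collection, graph, permuted,
                              elim_alpha=config.elim_alpha,
                              mode=config.variance_mode)
        return res["p_enrich"].to_numpy()

    observed = elim_enrichment(collection, graph, scores,
                               elim_alpha=config.elim_alpha,
                               mode=config.variance_mode)
    observed = attach_bh(observed)
    observed = permutation_fdr(observed, scores, closure,
                               B=config.fdr_perms, seed=config.seed)
    reported = observed[observed["fdr_empirical"] < config.enrich_fdr_threshold]
    counts["terms_reported"] = int(len(reported))
    formats.write_enrichment(observed, outd / "enrichment.tsv")

    depletion = attach_bh(observed.drop(columns=["fdr_bh", "fdr_empirical"]),
                          p_column="p_deplete")
    formats.write_enrichment(depletion, outd / "depletion.tsv")

    formats.write_config(
        {**dataclasses.asdict(config), "counts": counts},
        outd / "config.json",
    )
    for key, val in counts.items():
        logger.info("pipeline %s = %s", key, val)
    return {"counts": counts, "tallies": tallies, "enrichment": observed,
            "records": records, "scores": scores_df}
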