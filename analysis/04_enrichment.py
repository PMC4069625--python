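#!/usr/bin/env python
"""SUMSTAT gene-set enrichment with elim decorrelation and empirical FDR.

Propagates the synthetic GO annotations up the DAG, keeps terms with more
than 10 scored genes, tests each term's SUMSTAT (sum of transformed member
scores) against its CLT normal null with deepest-first elim gene removal,
and attaches both a 100-permutation empirical FDR and BH values.  Writes
results/enrichment.tsv and results/depletion.tsv; reports terms at
empirical FDR < 20%.
"""

from pathlib import Path

from possel import formats
from possel.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = run_pipeline(PipelineConfig(
        input_dir=str(ROOT / "simulated_scan"),
        output_dir=str(ROOT),
        fdr_perms=100,
        seed=20240902,
    ))
    enr = out["enrichment"]
    tested = enr[enr["tested"]]
    print(f"{len(tested)} terms tested (of {len(enr)} testable); "
          f"elim removed genes from "
          f"{(enr['genes_removed_by_elim'] > 0).sum()} parent terms")
    reported = tested[tested["fdr_empirical"] < 0.20].sort_values("p_enrich")
    cols = ["term_id", "n", "sumstat", "z", "p_enrich", "fdr_empirical",
            "fdr_bh"]
    print(f"\n{len(reported)} term(s) enriched at empirical FDR < 20%:")
    print(reported[cols].to_string(index=False,
                                   float_format=lambda v: f"{v:.3g}"))
    if "GO:9999001" in set(reported["term_id"]):
        print("\nthe planted positive-control term GO:9999001 is recovered")
    else:
        print("\nWARNING: planted term GO:9999001 not recovered at FDR < 20%")


if __name__ == "__main__":
    main()
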