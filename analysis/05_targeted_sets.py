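#!/usr/bin/env python
"""Targeted SUMSTAT tests on externally defined gene sets.

Mimics the caste-biased-expression and aging-gene analyses: six
"caste" sets and four "aging" sets are drawn from the scored families (one
caste set is spiked with high-scoring genes as a positive control), each is
tested with a 10,000-permutation SUMSTAT p-value, and significance is
declared at the Bonferroni threshold for its family of planned tests
(0.05/6 and 0.05/4).  Writes results/targeted_sets.tsv.
"""

from pathlib import Path

import numpy as np

from possel import formats
from possel.set_tests import targeted_set_tests

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240903


def main() -> None:
    scores = formats.read_scores(ROOT / "family_scores.tsv") \
        .set_index("family_id")["transformed"]
    rng = np.random.default_rng(SEED)
    genes = scores.index.to_numpy()

    caste_sets = {
        f"{stage}_{caste}": list(rng.choice(genes, size=60, replace=False))
        for stage in ("pupal", "adult")
        for caste in ("male", "queen", "worker")
    }
    # positive control: adult queens get the top-scoring genes
    caste_sets["adult_queen"] = list(scores.nlargest(60).index)
    aging_sets = {
        f"aging_{direction}_{contrast}":
            list(rng.choice(genes, size=40, replace=False))
        for direction in ("up", "down")
        for contrast in ("age", "oxygen")
    }

    caste = targeted_set_tests(caste_sets, scores, B=10000, seed=SEED + 1)
    aging = targeted_set_tests(aging_sets, scores, B=10000, seed=SEED + 2)
    out = caste.assign(family="caste").merge(
        aging.assign(family="aging"), how="outer")
    formats.write_tsv(out, ROOT / "targeted_sets.tsv")

    for name, table, k in (("caste", caste, 6), ("aging", aging, 4)):
        print(f"\n{name} sets (Bonferroni alpha = 0.05/{k} = {0.05 / k:.4g}):")
        print(table.to_string(index=False,
                              float_format=lambda v: f"{v:.4g}"))
    hits = caste[caste["significant"]]
    print(f"\n{len(hits)} caste set(s) significant "
          f"(expected: the spiked adult_queen control only)")


if __name__ == "__main__":
    main()
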