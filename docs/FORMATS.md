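# File formats

All tabular files are tab-separated with a header row. Whole lines starting
with `#` are comments; a `#` inside a field (branch labels such as `#1`) is
data. Floats are written with 10 significant digits so repeated runs are
byte-identical.

## replicate_runs.tsv

One row per optimisation run. Each (family_id, branch_id, hypothesis) must
appear exactly three times.

| column     | type  | meaning                                        |
|------------|-------|------------------------------------------------|
| family_id  | str   | gene family identifier                         |
| branch_id  | str   | foreground branch label (canonical or `merged:<clade>`) |
| hypothesis | str   | `null` or `alt`                                |
| run        | int   | run index 1-3                                  |
| lnl        | float | maximised log-likelihood (nats)                |

## test_records.tsv

One row per reconciled test (family x branch).

| column      | meaning                                                   |
|-------------|-----------------------------------------------------------|
| family_id, branch_id | test identity                                    |
| delta_lnl   | max(lnL_alt) - max(lnL_null), clamped at 0                |
| lrt         | 2 * delta_lnl                                             |
| d           | largest within-hypothesis run discrepancy (nats)          |
| clamped     | raw delta_lnl was negative                                |
| converged   | d <= cutoff (default 0.004)                               |
| p           | chi-square(1 df) upper tail of lrt; NaN if not converged  |
| q           | BH-adjusted value over the pooled converged series        |
| significant | q <= threshold (default 0.10) and converged               |

## family_scores.tsv

| column          | meaning                                          |
|-----------------|--------------------------------------------------|
| family_id       | gene family                                      |
| n_branches_used | converged lineage branches entering the mean     |
| mean_lrt        | mean LRT over those branches                     |
| transformed     | mean_lrt ** 0.25                                 |

## associations.tsv

Two columns `gene`, `term`: direct (unpropagated) gene-to-term annotations.

## ontology.obo

OBO subset: `[Term]` stanzas with `id`, `name`, `namespace`, `is_a`,
`relationship: part_of`, `is_obsolete`. Obsolete terms are skipped on read.

## enrichment.tsv / depletion.tsv

One row per testable term: `term_id`, `namespace`, `n` (set size after elim
removal), `sumstat` (S, sum of transformed member scores), `z`,
`p_enrich`, `p_deplete`, `genes_removed_by_elim`, `tested`,
`fdr_bh`, `fdr_empirical`. In depletion.tsv the BH column is computed on
`p_deplete`.

## Gene-set definition file

Header `name`, `genes`; one row per set, `genes` a comma-separated list of
gene ids.

## Trees

Newick. Family trees carry species labels on leaves; internal node labels
hold canonical branch names on the species tree, or bootstrap supports on
gene trees. GC3 values are supplied separately as a TSV with columns
`node`, `gc3` keyed by leaf/internal node labels.

## truth_tests.tsv / truth_terms.tsv (simulator output)

`truth_tests.tsv`: `family_id`, `branch_id`, `selected` (bool), `true_lrt`
(the LRT drawn before run synthesis). `truth_terms.tsv`: `term`, `planted`,
`member_sel_fraction`, `noncentrality`.

## config.json

The resolved pipeline configuration plus stage counts, written next to the
outputs of every run.
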