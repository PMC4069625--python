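# Methods

This package implements the statistical layer of a genome-wide scan for
episodic positive selection: everything downstream of the codon-model
likelihood optimisations (which are treated as inputs) up to gene-set level
biological conclusions. This note records the models, the defaults and the
design choices, and what the synthetic data can and cannot certify.

## Branch-site test post-processing

Each gene family is tested once per foreground branch with a branch-site
likelihood-ratio test; because the optimiser is prone to convergence
failures, both hypotheses are run three times. Per test:

* **Reconciliation.** ΔlnL = max over runs of the alternative log-likelihood
  minus max over runs of the null. Negative ΔlnL (possible only through
  optimisation noise, since the models are nested) is clamped to 0 and
  flagged; a clamped test is non-significant by construction (p = 1).
* **Convergence diagnostic.** d = the larger of the two within-hypothesis
  run ranges (max − min over the three runs). The observed distribution of d
  is bimodal — a major mode at 0 and a minor failure mode near 1 nat — and a
  strict cutoff d > 0.004 removes the failure mode; d equal to the cutoff is
  retained.
* **p-values.** The statistic 2ΔlnL is referred to the χ² distribution with
  1 df. This is conservative for the branch-site test (the boundary null is
  a 50:50 mixture of a point mass at 0 and χ²₁) but is the convention the
  scan follows.
* **FDR.** Benjamini–Hochberg over the single pooled series of all converged
  tests (families × branches), clamped tests included with p = 1; the
  default significance threshold is q ≤ 0.10. A per-lineage series is
  available by subsetting records before `attach_pvalues`.

Families whose gene tree lacks some species have collapsed ("merged")
branches that correspond to no single species-tree branch.
`tree_tools.map_branches` labels each gene-tree branch with its canonical
species-tree branch, or `merged:<clade>` where `<clade>` is the most
ancestral collapsed branch — the smallest canonical clade containing the
merged branch. Tallies count merged-branch hits for lineages but never for
individual branches.

## Lineage scores and the fourth-root transform

For gene-set testing each family gets one score: the arithmetic mean of the
LRT (2ΔlnL scale) over its converged tests on the lineage's branches
(the 13 ant branches by default; merged branches inside the lineage are
included). The mean is over *available* branches — families missing genes
have fewer usable branches and treating absent branches as zeros would
conflate gene loss with purifying selection; `n_branches_used` is retained
so either convention can be audited, and a fixed-denominator mode is
provided. The score is then fourth-root transformed, a variance-stabilising
map for the heavily right-skewed LRT mixture that preserves ranks. The
transform is applied after averaging, not per branch.

## SUMSTAT enrichment

The SUMSTAT statistic of a gene set is the sum of the transformed scores of
its n members. Under the null that the set is exchangeable with the scored
background G (|G| = N, population mean μ_G and variance σ²_G), the sum of n
scores drawn without replacement is asymptotically normal with

    E[S]   = n μ_G
    Var[S] = n σ²_G (N − n) / (N − 1)

The finite-population variance is the default (`mode="fpc"`) because the
null is a random subset of the fixed score list; an iid mode (n σ²_G) is
available. Both moments are validated against exhaustive enumeration on
small backgrounds, and `empirical_null` draws 10,000 random same-size sets
to measure the KS distance between the realised null and the fitted normal
(< 0.02 for n ≥ 11 on a 5,000-family background; the normal approximation
is the reason the method needs no per-set randomisation). Enrichment and
depletion are two one-sided tails, computed and reported separately.

**Degenerate cases.** A set equal to the whole background (the namespace
root) has zero null variance without replacement and is reported untested;
a constant background is an error.

## elim decorrelation

Ontology term sets are nested, so raw per-term results are redundant. Terms
are processed deepest-first, where depth is the *longest* path from the
namespace root — this guarantees every term is tested before any of its
ancestors regardless of DAG shortcuts; ties are broken lexicographically so
the procedure is deterministic. When a term's enrichment p-value falls
below `elim_alpha` (default 0.01, the conventional default of the
procedure; always reported with results), its current member genes are
removed from all ancestors' sets before those are tested. Ancestors that
fall below the size filter after removal are reported untested. Removals by
several significant children take the set union. Flat collections (e.g.
KEGG-style pathways, which have little hierarchy) run with elim disabled
(`elim_alpha=0`).

Annotation is propagated child→parent over `is_a` and `part_of` edges (the
whitelist is configurable); namespaces are kept separate. Terms with more
than 10 scored genes are testable (more than 5 in the sparser
phenotype-ontology mode).

## Empirical FDR

Because nearby terms are dependent even after elim, the FDR is also
estimated by permutation: the gene scores are shuffled over the same gene
ids, the full elim pipeline is rerun (default B = 100), and at each observed
p-value threshold t, FDR(t) = N₀(t)/N_t(t), with N₀ the mean permutation
count of p ≤ t and N_t the observed count; N_t = 0 defines FDR 0 and values
above 1 are clamped. The raw ratio is not monotone in t, while BH-adjusted
values are step-up monotonized; the estimator therefore applies the same
step-up minimum from the largest threshold down (as in q-value estimation;
`monotone=False` recovers the raw ratio). With monotonization the empirical
FDR tracks BH within ±0.1 at every observed p on null simulations. Sets at
empirical FDR < 20% are reported. A per-term outlier diagnostic recomputes
the p-value with the set's single highest-scoring gene removed, guarding
against single-gene artefacts.

## Targeted set tests and composition tests

Small families of planned gene sets (caste-biased expression, aging
contrasts) are tested by direct permutation: B = 10,000 random same-size
sets, p = (1 + #{perm ≥ S}) / (1 + B) (the add-one convention, so p is never
0 and has resolution 1/(B+1)), with a Bonferroni threshold 0.05/k for the k
planned tests. The reported effect size S/(n μ_G) is a descriptive
observed/expected ratio — the source analyses do not define their effect
size, so this value is not comparable across methods.

Composition biases (is a dataset functionally unrepresentative?) use
per-term 2×2 Fisher's exact tests (two-sided by probability-mass summation,
odds ratio ad/bc) with the same deepest-first elim removal and BH across
terms. A degenerate margin (e.g. subset = reference) yields p = 1 rather
than an error.

## Tree utilities

* `split_tree` partitions an oversized gene tree into subtrees of fewer than
  `max_leaves` (default 100) leaves: repeatedly cut the branch with maximal
  bootstrap support among those leaving both components with at least
  `min_component` (default 5) leaves; ties go to the most balanced cut, then
  to the lexicographically smallest leaf label. The source procedure is
  described only qualitatively ("branches with as high as possible bootstrap
  support"); this greedy operationalisation is deterministic and
  brute-force-verified on random trees, but a particular historical split
  (e.g. an exact 16-way partition) is not reproducible from the description.
* `gc3_shifts` reports GC3(child) − GC3(parent) per branch from externally
  estimated node GC3 values; shifts telescope along root-to-leaf paths.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, with
ground truth:

* **Null LRTs**: π₀ δ₀ + (1 − π₀) χ²₁ with π₀ = 0.5 (the standard boundary
  result for a one-parameter constraint); π₀ is configurable because the
  scan's χ²₁ convention corresponds to π₀ = 0.
* **Alternatives**: noncentral χ²₁(λ). The sources never model alternatives;
  this is the simplest one-parameter effect-size family. Defaults λ = 10 and
  a 3% per-test selection fraction give per-branch significant fractions of
  ~2% at q ≤ 0.10, in the range real scans report; any power statement must
  cite the λ used.
* **Replicate runs**: each run is the true optimum depressed by
  |N(0, jitter_sd)| (jitter_sd = 0.001 nats, keeping d's main mode well
  below the 0.004 cutoff); with probability 0.02 one run of one random
  hypothesis is further depressed by ~N(1, 0.1) truncated at 0, recreating
  the d ≈ 1 failure mode at about the observed exclusion rate.
* **Gene loss**: each species is dropped independently (default p = 0.1),
  re-drawn until at least 4 of 7 ants and 3 of 5 outgroups remain (the
  composition range of the emulated families); the family tree is the
  pruned species topology, so merged branches arise exactly as in real
  single-copy families.
* **Ontology**: a layered random DAG (default 150 terms, depth 4, 1–2
  parents per term) with genes annotated to leaves only; propagation is the
  ontology module's job. Planted terms are extra leaves with a chosen number
  of members, of which a chosen fraction is put under selection (noncentral
  draws on all ant branches); the background random stream is independent of
  planting, so planted and unplanted datasets with one seed are paired on
  all non-member families.
* All randomness derives from one seed with per-family substreams; output
  is byte-identical for a fixed seed.

`simulate_scores` is a fast score-level path (no replicate-run or tree
layer) for calibration studies where reconciliation is not under test.

What the synthetic data does *not* emulate: real codon alignments and their
length/composition effects on the LRT, correlation of selection across
branches within a family, the empirical GO annotation distribution (term
sizes are homogeneous), and dS saturation or GC-biased gene conversion
confounders. Passing tests certify the statistical machinery, not the
biological robustness of the upstream codon models.

## Problem sizes used in the shipped checks

Simulation-based checks run at reduced but statistically meaningful sizes
chosen for desk-scale reproducibility: 5,000-family backgrounds for the
normal-approximation and power checks (25 replicates for power, planted
term of 50 genes with 30% members at λ = 10), 20 replicates of 250-family
null scans for FDR control, 60-term flat collections with B = 100
permutations for the empirical-FDR/BH comparison, and 2,500 random sets for
type-I calibration. The genome-scale headline numbers of the emulated study
(1,832 significant families etc.) depend on the original alignments and are
recomputed here only where they are pure arithmetic on published values.
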