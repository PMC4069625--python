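"""Synthetic inputs for the whole pipeline, with ground truth.

The generator emulates the statistical structure of a genome-wide branch-site
scan over single-copy ortholog families on a fixed species phylogeny of seven
ant species and five outgroups:

* null LRT scores drawn from the boundary mixture pi0 * delta_0 +
  (1 - pi0) * chi2(1 df) (the constrained parameter sits on the boundary of
  the alternative's parameter space, so about half the null mass is an exact
  zero);
* tests under positive selection drawn from a noncentral chi2(1 df, lambda) —
  the simplest one-parameter family giving a tunable effect size;
* triplicate optimisation runs per hypothesis, reconstructed from the true
  LRT with small run-to-run jitter plus a rare "blow-up" mode in which one
  run of one hypothesis is depressed by about `blowup_scale` nats (the
  convergence-failure mode that the d > 0.004 filter removes);
* per-family gene loss that prunes taxa from the species tree and thereby
  merges canonical branches;
* a layered random ontology DAG with gene annotations on leaf terms, plus
  optional planted terms whose members are enriched in selected genes.

All randomness flows from one seed; per-family substreams are derived
deterministically so planted and unplanted runs stay paired on the
background.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from possel.tree_tools import map_branches, read_tree

logger = logging.getLogger(__name__)

#: Species topology: 7 ants + 5 outgroups; internal labels #1..#8 are the
#: tested internal branches (Attini, Myrmicinae x2, Formicoid x2, Formicidae,
#: Aculeata, Apocrita).
SPECIES_NEWICK = (
    "((((((((Acep,Aech)#1,Sinv)#2,Pbar)#3,(Cflo,Lhum)#4)#5,Hsal)#6,Amel)#7,"
    "Nvit)#8,(Dmel,(Tcas,Phum)));"
)

ANT_TERMINALS = ("Acep", "Aech", "Sinv", "Pbar", "Cflo", "Lhum", "Hsal")
OUTGROUPS = ("Amel", "Nvit", "Dmel", "Tcas", "Phum")

#: The 15 tested branches: 7 terminal ant branches and internals #1-#8.
TESTED_BRANCHES = ANT_TERMINALS + tuple(f"#{i}" for i in range(1, 9))

#: The 13 ant-lineage branches (tested branches minus the two basal
#: hymenopteran internals #7 and #8).
ANT_BRANCHES = ANT_TERMINALS + tuple(f"#{i}" for i in range(1, 7))


@dataclass(frozen=True)
class PlantedTerm:
    """An ontology term whose members are enriched in selected genes."""

    term_id: str
    n_members: int
    member_sel_fraction: float
    noncentrality: float


@dataclass
class SimulationConfig:
    """Free parameters of the synthetic scan.

    Defaults follow the emulated study where it fixes them (4,261 families,
    15 tested branches, triplicate runs, the d blow-up mode near 1 nat) and
    otherwise use values typical of such scans (see docs/methods.md).
    """

    n_families: int = 4261
    branch_labels: tuple[str, ...] = TESTED_BRANCHES
    pi0: float = 0.5
    sel_fraction: float = 0.03
    noncentrality: float = 10.0
    jitter_sd: float = 0.001
    blowup_prob: float = 0.02
    blowup_scale: float = 1.0
    missing_taxon_prob: float = 0.1
    n_terms: int = 150
    n_genes_per_term: int = 8
    dag_depth: int = 4
    planted_terms: tuple[PlantedTerm, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi0", "sel_fraction", "blowup_prob", "missing_taxon_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for p in self.planted_terms:
            if not 0.0 <= p.member_sel_fraction <= 1.0:
                raise ValueError(
                    f"member_sel_fraction must be in [0, 1], got {p.member_sel_fraction}"
                )
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.noncentrality < 0:
            raise ValueError("noncentrality must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """Complete simulated inputs plus ground-truth labels."""

    replicate_runs: pd.DataFrame     # family_id, branch_id, hypothesis, run, lnl
    family_trees: dict[str, str]     # family_id -> newick
    annotations: pd.DataFrame        # gene, term
    ontology_obo: str
    truth_tests: pd.DataFrame        # family_id, branch_id, selected, true_lrt
    truth_terms: pd.DataFrame        # term, planted, member_sel_fraction, noncentrality
    species_newick: str = SPECIES_NEWICK
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# Samplers


def sample_lrt(n: int, pi0: float, noncentrality: float, seed=None) -> np.ndarray:
    """Draw n LRT values (2*delta lnL scale).

    With noncentrality 0 each value is exactly 0 with probability pi0 and a
    central chi2(1) draw otherwise; with noncentrality lambda > 0 values are
    noncentral chi2(1, lambda) draws (the alternative has no boundary mass).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError(f"pi0 must be a probability in [0, 1], got {pi0}")
    if noncentrality < 0:
        raise ValueError("noncentrality must be >= 0")
    rng = np.random.default_rng(seed)
    if noncentrality > 0:
        return rng.noncentral_chisquare(1.0, noncentrality, size=n)
    vals = rng.chisquare(1.0, size=n)
    vals[rng.random(n) < pi0] = 0.0
    return vals


def synthesize_runs(
    true_lrt: float,
    base_lnl: float,
    jitter_sd: float = 0.001,
    blowup_prob: float = 0.0,
    blowup_scale: float = 1.0,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Triplicate (null, alt) log-likelihoods consistent with a true LRT.

    The best null run sits at ``base_lnl`` and the best alternative run at
    ``base_lnl + true_lrt / 2`` (the LRT is on the 2*delta lnL scale); each
    run is depressed by |N(0, jitter_sd)| so the per-hypothesis maximum stays
    at the true optimum up to jitter.  With probability ``blowup_prob`` one
    run of one randomly chosen hypothesis is additionally depressed by
    ~N(blowup_scale, blowup_scale/10) truncated at 0, recreating the
    convergence-failure mode at d ~ blowup_scale.

    Returns ``(lnl_null, lnl_alt)`` arrays of length 3.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if not 0.0 <= blowup_prob <= 1.0:
        raise ValueError(f"blowup_prob must be a probability in [0, 1], got {blowup_prob}")
    rng = np.random.default_rng(seed)
    lnl_null = base_lnl - np.abs(rng.normal(0.0, jitter_sd, size=3))
    lnl_alt = base_lnl + true_lrt / 2.0 - np.abs(rng.normal(0.0, jitter_sd, size=3))
    if rng.random() < blowup_prob:
        depress = -1.0
        while depress < 0:
            depress = rng.normal(blowup_scale, blowup_scale / 10.0)
        target = lnl_null if rng.random() < 0.5 else lnl_alt
        target[rng.integers(3)] -= depress
    return lnl_null, lnl_alt


# ---------------------------------------------------------------------------
# Ontology generation


def _make_ontology(
    n_terms: int,
    dag_depth: int,
    planted_ids: Sequence[str],
    rng: np.random.Generator,
    namespace: str = "biological_process",
) -> tuple[str, list[str], dict[str, list[str]]]:
    """Layered random DAG written as OBO text.

    Layer 0 is a single root; each of ``dag_depth`` lower layers holds a
    share of the n_terms terms, and every non-root term has 1-2 parents in
    the layer above.  Planted term ids are appended as extra leaves under a
    bottom-layer parent.  Returns (obo_text, leaf_term_ids, parents).
    """
    if dag_depth < 1:
        logger.warning("dag_depth < 1 requested; using a root-only ontology")
        dag_depth = 0
    root = "GO:0000000"
    layers: list[list[str]] = [[root]]
    next_id = 1
    remaining = n_terms
    for level in range(1, dag_depth + 1):
        levels_left = dag_depth - level + 1
        size = max(1, remaining // levels_left) if remaining > 0 else 0
        if size == 0:
            logger.warning("ontology generation stopped at depth %d (terms exhausted)",
                           level - 1)
            break
        layer = [f"GO:{next_id + i:07d}" for i in range(size)]
        next_id += size
        remaining -= size
        layers.append(layer)

    parents: dict[str, list[str]] = {root: []}
    for level in range(1, len(layers)):
        above = layers[level - 1]
        for term in layers[level]:
            k = 1 if len(above) == 1 else int(rng.integers(1, 3))
            k = min(k, len(above))
            parents[term] = sorted(rng.choice(above, size=k, replace=False).tolist())

    bottom = layers[-1]
    for pid in planted_ids:
        host = bottom[int(rng.integers(len(bottom)))] if len(layers) > 1 else root
        parents[pid] = [host if len(layers) > 1 else root]

    all_terms = [t for layer in layers for t in layer] + list(planted_ids)
    has_child = {p for plist in parents.values() for p in plist}
    leaves = [t for t in all_terms if t not in has_child and t != root]

    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: synthetic\n")
    for term in all_terms:
        buf.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
        buf.write(f"namespace: {namespace}\n")
        for p in parents[term]:
            buf.write(f"is_a: {p} ! synthetic term {p}\n")
    return buf.getvalue(), leaves, parents


# ---------------------------------------------------------------------------
# Dataset assembly


def _prune_species_tree(
    species_tree: dendropy.Tree,
    present: Sequence[str],
) -> str:
    """Newick of the species tree restricted to the present taxa."""
    t = dendropy.Tree(species_tree)
    t.retain_taxa_with_labels(sorted(present))
    return t.as_string(schema="newick", suppress_rooting=True).strip()


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic scan dataset with ground truth.

    See the module docstring for the generative model.  With the seed fixed
    the output is byte-identical; the background (non-planted) random stream
    does not depend on ``planted_terms``, so planted and unplanted datasets
    with the same seed are paired on all non-member families.
    """
    species_tree = read_tree(SPECIES_NEWICK)
    families = [f"F{i:06d}" for i in range(config.n_families)]
    tested = set(config.branch_labels)

    # ontology + annotations (stream 1)
    rng_ont = np.random.default_rng([config.seed, 1])
    planted_ids = [p.term_id for p in config.planted_terms]
    obo_text, leaves, _ = _make_ontology(
        config.n_terms, config.dag_depth, planted_ids, rng_ont
    )
    assoc_rows: list[tuple[str, str]] = []
    for term in leaves:
        if term in planted_ids:
            continue
        members = rng_ont.choice(families, size=min(config.n_genes_per_term,
                                                    len(families)), replace=False)
        assoc_rows += [(g, term) for g in members]

    # planted terms (stream 3): membership and selected members
    rng_plant = np.random.default_rng([config.seed, 3])
    planted_sel: dict[str, set[str]] = {}
    planted_members: dict[str, list[str]] = {}
    for p in config.planted_terms:
        members = rng_plant.choice(families, size=p.n_members, replace=False).tolist()
        planted_members[p.term_id] = members
        n_sel = int(round(p.member_sel_fraction * p.n_members))
        planted_sel[p.term_id] = set(members[:n_sel])  # members already random order
        assoc_rows += [(g, p.term_id) for g in members]

    # selected-family -> noncentrality for planted members (all ant branches)
    planted_lambda: dict[str, float] = {}
    for p in config.planted_terms:
        for fam in planted_sel[p.term_id]:
            planted_lambda[fam] = p.noncentrality

    # per-family trees, tests and replicate runs (stream 2, per family)
    run_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    family_trees: dict[str, str] = {}
    prune_cache: dict[frozenset[str], tuple[str, list[str]]] = {}
    all_species = ANT_TERMINALS + OUTGROUPS

    for idx, fam in enumerate(families):
        rng = np.random.default_rng([config.seed, 2, idx])
        # gene loss, re-drawn until the family keeps >= 4 ants and >= 3 outgroups
        while True:
            keep = [s for s in all_species
                    if rng.random() >= config.missing_taxon_prob]
            if (sum(s in ANT_TERMINALS for s in keep) >= 4
                    and sum(s in OUTGROUPS for s in keep) >= 3):
                break
        key = frozenset(keep)
        if key not in prune_cache:
            newick = _prune_species_tree(species_tree, keep)
            labels = sorted(map_branches(newick, species_tree).values())
            prune_cache[key] = (newick, labels)
        newick, labels = prune_cache[key]
        family_trees[fam] = newick

        # testable branches: canonical tested branches + merged branches whose
        # containing clade is itself tested
        branches = [b for b in labels
                    if (b in tested) or
                    (b.startswith("merged:") and b.split(":", 1)[1] in tested)]
        base_lnl = -float(rng.uniform(1000.0, 20000.0))
        lam_planted = planted_lambda.get(fam)
        for br in branches:
            on_ant_lineage = (br in ANT_BRANCHES or
                              (br.startswith("merged:") and
                               br.split(":", 1)[1] in ANT_BRANCHES))
            if lam_planted is not None and on_ant_lineage:
                selected, lam = True, lam_planted
            else:
                selected = bool(rng.random() < config.sel_fraction)
                lam = config.noncentrality if selected else 0.0
            true_lrt = float(sample_lrt(1, config.pi0, lam, seed=rng)[0])
            lnl_null, lnl_alt = synthesize_runs(
                true_lrt, base_lnl,
                jitter_sd=config.jitter_sd,
                blowup_prob=config.blowup_prob,
                blowup_scale=config.blowup_scale,
                seed=rng,
            )
            for r in range(3):
                run_rows.append((fam, br, "null", r + 1, lnl_null[r]))
                run_rows.append((fam, br, "alt", r + 1, lnl_alt[r]))
            truth_rows.append((fam, br, selected, true_lrt))

    replicate_runs = pd.DataFrame(
        run_rows, columns=["family_id", "branch_id", "hypothesis", "run", "lnl"]
    )
    truth_tests = pd.DataFrame(
        truth_rows, columns=["family_id", "branch_id", "selected", "true_lrt"]
    )
    annotations = pd.DataFrame(sorted(set(assoc_rows)), columns=["gene", "term"])
    truth_terms = pd.DataFrame(
        [
            {
                "term": p.term_id,
                "planted": True,
                "member_sel_fraction": p.member_sel_fraction,
                "noncentrality": p.noncentrality,
            }
            for p in config.planted_terms
        ],
        columns=["term", "planted", "member_sel_fraction", "noncentrality"],
    )
    return SyntheticDataset(
        replicate_runs=replicate_runs,
        family_trees=family_trees,
        annotations=annotations,
        ontology_obo=obo_text,
        truth_tests=truth_tests,
        truth_terms=truth_terms,
        config=config,
    )


def simulate_scores(
    n_families: int,
    n_branches: int = 13,
    pi0: float = 0.5,
    sel_fraction: float = 0.0,
    noncentrality: float = 0.0,
    seed=None,
) -> pd.Series:
    """Fast path: transformed lineage scores without the replicate-run layer.

    Draws per-branch LRTs directly from the null mixture (or noncentral
    alternative for a ``sel_fraction`` of families, on every branch), averages
    over branches and applies the fourth-root transform.  Used for
    score-level calibration studies where the reconciliation layer is not
    under test.
    """
    rng = np.random.default_rng(seed)
    lrts = rng.chisquare(1.0, size=(n_families, n_branches))
    lrts[rng.random((n_families, n_branches)) < pi0] = 0.0
    if sel_fraction > 0 and noncentrality > 0:
        sel = rng.random(n_families) < sel_fraction
        if sel.any():
            lrts[sel] = rng.noncentral_chisquare(
                1.0, noncentrality, size=(int(sel.sum()), n_branches)
            )
    scores = lrts.mean(axis=1) ** 0.25
    return pd.Series(scores, index=[f"F{i:06d}" for i in range(n_families)])
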