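"""Newick tree utilities: canonical branch mapping, subtree splitting, GC3 shifts.

Single-copy gene family trees are assumed to follow the species topology, but
taxa missing from a family collapse species-tree branches into one gene-tree
branch.  ``map_branches`` labels every gene-tree branch either with the
canonical species-tree branch it corresponds to, or as
``merged:<clade label>`` when two or more canonical branches were elided into
it.  ``split_tree`` partitions an oversized gene tree into subtrees of
bounded size, preferring cuts at branches with high bootstrap support.
``gc3_shifts`` turns per-node GC3 (third-codon-position G+C) values into
per-branch shifts.
"""

from __future__ import annotations

import logging
from typing import Mapping

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

MERGED_PREFIX = "merged:"


def read_tree(source: str) -> dendropy.Tree:
    """Parse a newick string or a path to a newick file (rooted as given)."""
    if "(" in source:
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def _clade_leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Leaf-label set below each non-root node (one entry per branch)."""
    out: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset([node.taxon.label])
        else:
            out[node] = frozenset().union(*(out[c] for c in node.child_nodes()))
    out.pop(tree.seed_node, None)
    return out


def _branch_label(node: dendropy.Node, clade: frozenset[str]) -> str:
    """Canonical label of a species-tree branch: leaf taxon, node label, or
    a deterministic fallback built from the clade's leaves."""
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return str(node.label)
    return "|".join(sorted(clade))


def map_branches(
    family_tree: dendropy.Tree | str,
    species_tree: dendropy.Tree | str,
) -> dict[frozenset[str], str]:
    """Label each family-tree branch with its canonical species-tree branch.

    A family branch (identified by the species set below it) gets the
    canonical label L iff exactly one species-tree branch restricts to the
    same species set; when several nested species-tree branches collapse onto
    it (their clades differ only by missing taxa) it is labelled
    ``merged:<L_top>`` where L_top is the most ancestral collapsed branch —
    the smallest canonical clade containing the merged branch.

    Returns a dict keyed by the frozenset of species below the family branch.

    Raises if a species occurs twice in the family tree (single-copy
    contract) or if a family branch matches no species-tree branch (the
    family does not follow the species topology).
    """
    if isinstance(family_tree, str):
        family_tree = read_tree(family_tree)
    if isinstance(species_tree, str):
        species_tree = read_tree(species_tree)

    fam_leaves = [lf.taxon.label for lf in family_tree.leaf_node_iter()]
    if len(fam_leaves) != len(set(fam_leaves)):
        dups = sorted({x for x in fam_leaves if fam_leaves.count(x) > 1})
        raise ValueError(f"duplicate species in family tree (single-copy violated): {dups}")
    present = frozenset(fam_leaves)

    sp_clades = _clade_leafsets(species_tree)
    # restricted species clade -> list of (full clade, label), nested chains only
    restricted: dict[frozenset[str], list[tuple[frozenset[str], str]]] = {}
    for node, clade in sp_clades.items():
        r = clade & present
        if r:
            restricted.setdefault(r, []).append((clade, _branch_label(node, clade)))

    labels: dict[frozenset[str], str] = {}
    for node, fclade in _clade_leafsets(family_tree).items():
        matches = restricted.get(fclade)
        if not matches:
            raise ValueError(
                f"family branch below {sorted(fclade)} matches no species-tree branch"
            )
        if len(matches) == 1:
            labels[fclade] = matches[0][1]
        else:
            top = max(matches, key=lambda m: len(m[0]))  # most ancestral collapsed branch
            labels[fclade] = MERGED_PREFIX + top[1]
    return labels


def branch_labels(
    family_tree: dendropy.Tree | str,
    species_tree: dendropy.Tree | str,
) -> list[str]:
    """Convenience: the sorted list of labels from :func:`map_branches`."""
    return sorted(map_branches(family_tree, species_tree).values())


# ---------------------------------------------------------------------------
# Tree splitting


def _bootstrap(node: dendropy.Node) -> float:
    """Bootstrap support of the branch above `node` (internal node label); 0 if absent."""
    if node.label is None:
        return 0.0
    try:
        return float(node.label)
    except ValueError:
        return 0.0


def split_tree(
    tree: dendropy.Tree | str,
    max_leaves: int = 100,
    min_component: int = 5,
) -> list[dendropy.Tree]:
    """Partition a tree into subtrees each with fewer than ``max_leaves`` leaves.

    While any component has >= max_leaves leaves, the branch cut is the one
    that (i) leaves both components with >= min_component leaves and (ii) has
    maximal bootstrap support (missing support treated as 0); ties are broken
    by the most balanced split, then by the lexicographically smallest leaf
    label below the cut.  The returned components partition the input leaf
    set.
    """
    if max_leaves < 2 * min_component:
        raise ValueError(
            f"max_leaves={max_leaves} must be >= 2*min_component={2 * min_component}"
        )
    if isinstance(tree, str):
        tree = read_tree(tree)

    def recurse(component: dendropy.Tree) -> list[dendropy.Tree]:
        n_total = sum(1 for _ in component.leaf_node_iter())
        if n_total < max_leaves:
            return [component]
        clades = _clade_leafsets(component)
        candidates = []
        for node, clade in clades.items():
            below, above = len(clade), n_total - len(clade)
            if below >= min_component and above >= min_component:
                candidates.append(
                    (-_bootstrap(node), abs(below - above), min(clade), node, clade)
                )
        if not candidates:
            raise RuntimeError(
                f"component with {n_total} leaves admits no cut with both sides "
                f">= {min_component}"
            )
        candidates.sort(key=lambda t: t[:3])
        _, _, _, node, clade = candidates[0]

        all_leaves = {lf.taxon.label for lf in component.leaf_node_iter()}
        part_a = dendropy.Tree(component)  # clone, then reduce to one side of the cut
        part_a.retain_taxa_with_labels(sorted(clade))
        part_b = dendropy.Tree(component)
        part_b.retain_taxa_with_labels(sorted(all_leaves - clade))
        return recurse(part_a) + recurse(part_b)

    return recurse(dendropy.Tree(tree))


# ---------------------------------------------------------------------------
# GC3 shifts


def gc3_shifts(
    tree: dendropy.Tree | str,
    gc3: Mapping[str, float],
) -> pd.DataFrame:
    """Per-branch GC3 shift: GC3(child node) - GC3(parent node).

    ``gc3`` maps node keys (leaf taxon labels and internal node labels) to
    GC3 fractions.  Branches with a missing value at either endpoint are
    skipped with a warning.  Returns columns ``child, parent, shift``.
    """
    if isinstance(tree, str):
        tree = read_tree(tree)

    def key(node: dendropy.Node) -> str | None:
        if node.is_leaf():
            return node.taxon.label
        return str(node.label) if node.label is not None else None

    rows, skipped = [], 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        ck, pk = key(node), key(node.parent_node)
        if ck is None or pk is None or ck not in gc3 or pk not in gc3:
            skipped += 1
            continue
        rows.append({"child": ck, "parent": pk, "shift": gc3[ck] - gc3[pk]})
    if skipped:
        logger.warning("gc3_shifts: skipped %d branch(es) with missing GC3", skipped)
    return pd.DataFrame(rows, columns=["child", "parent", "shift"])
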