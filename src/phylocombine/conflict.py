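"""Bipartition-based gene-tree conflict against a reference topology.

Each internal reference edge defines a split; a gene tree is concordant
with it if the split (restricted to shared taxa) occurs in the gene tree,
in conflict if some gene-tree split is incompatible with it, and
uninformative otherwise (insufficient overlap or lack of resolution).
"Strong" support or conflict requires the witnessing split to carry
support at or above the threshold (default 95 percent).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tree import Tree, TreeError
from .tree_compare import bipartition_set

__all__ = [
    "EdgeClassification",
    "classify_edge",
    "conflict_table",
    "topology_conflict_edges",
    "reference_splits",
]


@dataclass
class EdgeClassification:
    status: str  # concordant | conflict | uninformative
    strong: bool = False
    witness: frozenset[str] | None = None


def _compatible(a_in: frozenset, a_out: frozenset, b_in: frozenset, b_out: frozenset) -> bool:
    """Two splits on the same leaf set are compatible iff one of the four
    side intersections is empty."""
    return (
        not (a_in & b_in)
        or not (a_in & b_out)
        or not (a_out & b_in)
        or not (a_out & b_out)
    )


def reference_splits(tree: Tree) -> list[tuple[frozenset[str], frozenset[str]]]:
    """(in-side, out-side) for every internal edge, preorder order."""
    leaves = tree.leaf_set()
    out = []
    for node in tree.preorder():
        if node.parent is None or node.is_tip:
            continue
        clade = frozenset(n.label for n in Tree(node).tips())
        if len(clade) < 2 or len(clade) > len(leaves) - 2:
            continue
        out.append((clade, leaves - clade))
    return out


def classify_edge(
    ref_split: tuple[frozenset[str], frozenset[str]],
    gene_tree: Tree,
    support_threshold: float = 95.0,
) -> EdgeClassification:
    """Classify a gene tree against one reference split.

    The split is restricted to the gene tree's taxa; if either restricted
    side has fewer than two taxa the gene is uninformative for this edge.
    Conflicts are witnessed by the most-supported incompatible gene split.
    """
    side_in, side_out = ref_split
    if not side_in or not side_out:
        raise TreeError("empty reference split side")
    gene_taxa = gene_tree.leaf_set()
    rin = frozenset(side_in & gene_taxa)
    rout = frozenset(side_out & gene_taxa)
    if len(rin) < 2 or len(rout) < 2:
        return EdgeClassification("uninformative")
    shared = rin | rout
    pruned = gene_tree if shared == gene_taxa else gene_tree.prune_to_taxa(shared)
    if len(shared) < 4:
        return EdgeClassification("uninformative")
    bset = bipartition_set(pruned)
    ref = min(bset.leaves)
    canonical = rin if ref not in rin else rout
    if canonical in bset.splits:
        sup = bset.supports.get(canonical)
        return EdgeClassification(
            "concordant", strong=(sup is not None and sup >= support_threshold)
        )
    incompatible = []
    for split in bset.splits:
        other = bset.leaves - split
        if not _compatible(rin, rout, split, other):
            incompatible.append(split)
    if not incompatible:
        return EdgeClassification("uninformative")
    witness = max(
        incompatible,
        key=lambda s: (
            bset.supports.get(s) if bset.supports.get(s) is not None else -1.0,
            tuple(sorted(s)),
        ),
    )
    sup = bset.supports.get(witness)
    return EdgeClassification(
        "conflict",
        strong=(sup is not None and sup >= support_threshold),
        witness=witness,
    )


def conflict_table(
    reference_tree: Tree,
    gene_trees,
    support_threshold: float = 95.0,
) -> pd.DataFrame:
    """Per-reference-edge concordance/conflict tallies over gene trees.

    One row per internal reference edge (preorder), with concordant,
    strong-concordant, conflict, strong-conflict and uninformative
    counts; the three status counts sum to the number of gene trees.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    rows = []
    for eid, split in enumerate(reference_splits(reference_tree)):
        counts = dict(
            n_concordant=0, n_concordant_strong=0,
            n_conflict=0, n_conflict_strong=0, n_uninformative=0,
        )
        for gt in gene_trees:
            c = classify_edge(split, gt, support_threshold)
            if c.status == "concordant":
                counts["n_concordant"] += 1
                counts["n_concordant_strong"] += int(c.strong)
            elif c.status == "conflict":
                counts["n_conflict"] += 1
                counts["n_conflict_strong"] += int(c.strong)
            else:
                counts["n_uninformative"] += 1
        rows.append(
            {"edge_id": eid, "clade": ",".join(sorted(split[0])), **counts}
        )
    return pd.DataFrame(rows)


def topology_conflict_edges(
    tree_a: Tree, tree_b: Tree, support_threshold: float = 95.0
) -> list[frozenset[str]]:
    """A-edges in strong conflict with B.

    An edge of ``tree_a`` is returned iff some split of ``tree_b`` with
    support >= threshold is incompatible with it after pruning both trees
    to their shared taxa.
    """
    shared = tree_a.leaf_set() & tree_b.leaf_set()
    if len(shared) < 4:
        raise TreeError("need >= 4 shared taxa")
    a = tree_a if shared == tree_a.leaf_set() else tree_a.prune_to_taxa(shared)
    b = tree_b if shared == tree_b.leaf_set() else tree_b.prune_to_taxa(shared)
    bset = bipartition_set(b)
    strong = [
        (s, bset.leaves - s)
        for s in bset.splits
        if (bset.supports.get(s) is not None and bset.supports[s] >= support_threshold)
    ]
    out = []
    for a_in, a_out in reference_splits(a):
        if any(not _compatible(a_in, a_out, s, o) for s, o in strong):
            out.append(a_in)
    return out
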