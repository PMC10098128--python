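"""Midpoint rooting, root-to-tip variance, and taxon-subset trimming.

Root-to-tip variance on a midpoint-rooted gene tree is the clock-likeness
metric: zero for a perfectly ultrametric gene, growing with rate
heterogeneity across lineages.  Sample variance (n-1 denominator) is used
throughout.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import Node, Tree, TreeError

__all__ = ["RootToTipReport", "midpoint_root", "root_to_tip_variance", "prune_to_taxa"]


@dataclass
class RootToTipReport:
    distances: dict[str, float]
    variance: float
    n_tips: int


def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest tip-to-tip path.

    Ties on the diameter break on the lexicographically smallest tip
    pair; the two endpoints of the chosen path are equidistant from the
    returned root.
    """
    if tree.n_tips < 2:
        raise TreeError("midpoint rooting needs >= 2 tips")
    work = tree.copy()
    tips = sorted(work.tips(), key=lambda n: n.label)
    best = None  # (distance, (label_a, label_b))
    dist_cache = {}
    for tip in tips:
        d = work.tip_distances_from(tip)
        dist_cache[tip.label] = d
        for other, dd in d.items():
            if other == tip.label:
                continue
            pair = tuple(sorted((tip.label, other)))
            cand = (dd, pair)
            if best is None or dd > best[0] + 1e-12 or (
                abs(dd - best[0]) <= 1e-12 and pair < best[1]
            ):
                best = cand
    diameter, (a_label, b_label) = best
    if diameter <= 0:
        raise TreeError("degenerate rooting: all branch lengths zero")
    # walk from a toward b, accumulating length until diameter/2
    a = next(t for t in work.tips() if t.label == a_label)
    path = _path_between(work, a_label, b_label)
    half = diameter / 2.0
    acc = 0.0
    for node_from, node_to, length in path:
        if acc + length >= half - 1e-15:
            offset = half - acc  # distance from node_from along this edge
            return _root_on_edge(work, node_from, node_to, offset)
        acc += length
    raise TreeError("midpoint not found on diameter path")  # pragma: no cover


def _path_between(tree: Tree, a_label: str, b_label: str):
    """Edges (node_from, node_to, length) along the path a -> b."""
    parent_of = {}
    start = next(t for t in tree.tips() if t.label == a_label)
    stack = [start]
    seen = {id(start)}
    target = None
    while stack:
        node = stack.pop()
        if node.is_tip and node.label == b_label:
            target = node
            break
        neighbors = list(node.children)
        if node.parent is not None:
            neighbors.append(node.parent)
        for nb in neighbors:
            if id(nb) in seen:
                continue
            seen.add(id(nb))
            length = node.length if nb is node.parent else nb.length
            parent_of[id(nb)] = (node, length)
            stack.append(nb)
    assert target is not None
    rev = []
    node = target
    while id(node) in parent_of:
        prev, length = parent_of[id(node)]
        rev.append((prev, node, length if length is not None else 0.0))
        node = prev
    return list(reversed(rev))


def _root_on_edge(tree: Tree, node_from: Node, node_to: Node, offset: float) -> Tree:
    """Re-root the tree ``offset`` along the edge from ``node_from`` toward
    ``node_to`` (tree-direction agnostic)."""
    # identify child end of the edge in the current parent structure
    if node_to.parent is node_from:
        child, dist_from_child = node_to, (node_to.length or 0.0) - offset
    elif node_from.parent is node_to:
        child, dist_from_child = node_from, offset
    else:  # pragma: no cover - path edges are always parent/child pairs
        raise TreeError("not an edge")
    edge_len = child.length or 0.0
    dist_from_child = min(max(dist_from_child, 0.0), edge_len)
    new_root = Node()
    old_parent = child.parent
    old_parent.remove_child(child)
    new_root.add_child(child)
    child.length = dist_from_child
    # reverse the path from old_parent up to the old root
    carry_len = edge_len - dist_from_child
    carry_sup = child.support
    node = old_parent
    prev = new_root
    while node is not None:
        up = node.parent
        if up is not None:
            up.remove_child(node)
        prev.add_child(node)
        next_len = node.length
        next_sup = node.support
        node.length = carry_len
        node.support = carry_sup
        carry_len, carry_sup = next_len, next_sup
        prev = node
        node = up
    out = Tree(new_root, rooted=True)
    out.suppress_unifurcations()
    out.rooted = True
    return out


def root_to_tip_variance(rooted_tree: Tree) -> RootToTipReport:
    """Root-to-tip path lengths and their sample variance (n-1)."""
    tips = rooted_tree.tips()
    if len(tips) < 2:
        raise TreeError("need >= 2 tips")
    distances = {}
    for tip in tips:
        d = 0.0
        node = tip
        while node.parent is not None:
            if node.length is None:
                raise TreeError("missing branch length")
            d += node.length
            node = node.parent
        distances[tip.label] = d
    values = np.array(list(distances.values()))
    return RootToTipReport(distances, float(np.var(values, ddof=1)), len(tips))


def prune_to_taxa(tree: Tree, taxa) -> Tree:
    """Induced subtree on ``taxa`` (wrapper over Tree.prune_to_taxa)."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise TreeError("need >= 3 taxa to keep a tree")
    return tree.prune_to_taxa(taxa)
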