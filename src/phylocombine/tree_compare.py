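"""Bipartitions, Robinson-Foulds distances, tree networks, tree length.

RF distances are unweighted: the size of the symmetric difference of the
two trees' non-trivial split sets, optionally after collapsing every edge
whose support falls below a threshold (missing supports collapse too).
Trees on unequal leaf sets are pruned to the shared taxa first.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .tree import Node, Tree, TreeError

__all__ = [
    "BipartitionSet",
    "bipartition_set",
    "collapse_by_support",
    "rf_distance",
    "rf_matrix",
    "build_tree_network",
    "fr_layout",
    "tree_length",
]


@dataclass
class BipartitionSet:
    """Non-trivial splits of one tree, canonically stored as the side not
    containing the lexicographically smallest taxon."""

    leaves: frozenset[str]
    splits: frozenset[frozenset[str]]
    supports: dict[frozenset[str], float | None]


def _node_clades(tree: Tree):
    """Yield (clade tip set, support) for every non-root internal node."""
    clades: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            clades[id(node)] = frozenset([node.label])
        else:
            clades[id(node)] = frozenset().union(
                *(clades[id(c)] for c in node.children)
            )
            if node.parent is not None:
                yield clades[id(node)], node.support


def bipartition_set(tree: Tree) -> BipartitionSet:
    """Canonical non-trivial splits (with supports where present)."""
    leaves = tree.leaf_set()
    if len(leaves) < 4:
        raise TreeError("bipartitions need >= 4 tips")
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    supports: dict[frozenset[str], float | None] = {}
    for clade, support in _node_clades(tree):
        if len(clade) < 2 or len(clade) > len(leaves) - 2:
            continue
        side = clade if ref not in clade else leaves - clade
        splits.add(side)
        prev = supports.get(side)
        supports[side] = max(
            (s for s in (prev, support) if s is not None), default=None
        )
    return BipartitionSet(leaves, frozenset(splits), supports)


def collapse_by_support(tree: Tree, threshold: float) -> Tree:
    """Contract internal edges with support < threshold (or missing).

    At threshold 0 the tree is unchanged; above 100 every internal edge
    collapses, leaving a star.
    """
    if not (0.0 <= threshold):
        raise ValueError("threshold must be >= 0")
    out = tree.copy()
    if threshold == 0.0:
        return out
    changed = True
    while changed:
        changed = False
        for node in out.internal_edges():
            support = node.support if node.support is not None else 0.0
            if support < threshold:
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx : idx + 1] = node.children
                for c in node.children:
                    c.parent = parent
                changed = True
                break
    return out


def rf_distance(
    t1: Tree, t2: Tree, support_threshold: float | None = None
) -> int:
    """Unweighted Robinson-Foulds distance.

    Trees are pruned to their shared leaf set (>= 4 taxa required); with a
    ``support_threshold`` both trees are support-collapsed first.
    """
    shared = t1.leaf_set() & t2.leaf_set()
    if len(shared) < 4:
        raise TreeError("need >= 4 shared tips for RF distance")
    a, b = t1, t2
    if shared != t1.leaf_set():
        a = t1.prune_to_taxa(shared)
    if shared != t2.leaf_set():
        b = t2.prune_to_taxa(shared)
    if support_threshold is not None:
        a = collapse_by_support(a, support_threshold)
        b = collapse_by_support(b, support_threshold)
    sa = bipartition_set(a).splits
    sb = bipartition_set(b).splits
    return len(sa ^ sb)


def rf_matrix(trees, support_threshold: float | None = None) -> np.ndarray:
    """All-by-all symmetric RF matrix (zero diagonal)."""
    n = len(trees)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = rf_distance(
                trees[i], trees[j], support_threshold
            )
    return out


def build_tree_network(
    labeled_trees, support_threshold: float | None = None
) -> nx.Graph:
    """Inverse-RF network over distinct topologies.

    Trees at RF 0 from each other are merged into a single node carrying
    all member labels; edges between distinct topologies are weighted
    1/RF.  Node attributes: ``members`` (labels list); edge attributes:
    ``rf`` and ``weight``.
    """
    labels = [lbl for lbl, _ in labeled_trees]
    trees = [t for _, t in labeled_trees]
    if len(trees) < 2:
        raise ValueError("need at least two trees")
    mat = rf_matrix(trees, support_threshold)
    # merge RF-0 groups (connected components of the RF == 0 graph)
    zero = nx.Graph()
    zero.add_nodes_from(range(len(trees)))
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            if mat[i, j] == 0:
                zero.add_edge(i, j)
    groups = [sorted(c) for c in nx.connected_components(zero)]
    groups.sort()
    g = nx.Graph()
    for gi, members in enumerate(groups):
        g.add_node(gi, members=[labels[m] for m in members])
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            rf = int(mat[groups[gi][0], groups[gj][0]])
            if rf > 0:
                g.add_edge(gi, gj, rf=rf, weight=1.0 / rf)
    return g


def fr_layout(
    network: nx.Graph,
    iterations: int = 200,
    seed: int = 0,
    ideal_distance: float = 1.0,
) -> dict:
    """Fruchterman-Reingold force-directed layout (deterministic per seed).

    Attractive force along edges w * d^2 / k, repulsive force k^2 / d
    between all pairs, displacement capped by a linearly cooling
    temperature.  A two-node network with edge weight w equilibrates at
    distance k * w^(-1/3).  Coordinates are not rescaled afterwards; a
    single node sits at the origin.
    """
    nodes = list(network.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("network has no nodes")
    if n == 1:
        return {nodes[0]: np.zeros(2)}
    k = ideal_distance
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-k, k, size=(n, 2))
    index = {v: i for i, v in enumerate(nodes)}
    t0 = k * n ** 0.5
    for it in range(iterations):
        disp = np.zeros_like(pos)
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=2)
        np.fill_diagonal(dist, 1.0)
        rep = (k * k / dist**2)[:, :, None] * delta / dist[:, :, None]
        np.fill_diagonal(rep[:, :, 0], 0.0)
        np.fill_diagonal(rep[:, :, 1], 0.0)
        disp += rep.sum(axis=1)
        for u, v, data in network.edges(data=True):
            i, j = index[u], index[v]
            d = pos[i] - pos[j]
            dn = max(np.linalg.norm(d), 1e-9)
            f = data.get("weight", 1.0) * dn * dn / k
            disp[i] -= f * d / dn
            disp[j] += f * d / dn
        t = t0 * (1.0 - it / iterations) * 0.1 + 1e-4
        norms = np.maximum(np.linalg.norm(disp, axis=1), 1e-12)
        step = np.minimum(norms, t)
        pos += disp / norms[:, None] * step[:, None]
    pos -= pos.mean(axis=0)
    return {v: pos[index[v]].copy() for v in nodes}


def tree_length(tree: Tree) -> float:
    """Sum of all branch lengths in the tree."""
    total = 0.0
    for node in tree.edges():
        if node.length is None:
            raise TreeError(f"missing branch length above {node.label or 'internal node'}")
        total += node.length
    return total
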