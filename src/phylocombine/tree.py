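"""Phylogenetic tree container with branch lengths and percent supports.

Unrooted trees are stored with an arbitrary (typically trifurcating) base
node; rooted trees have a bifurcating root.  Branch lengths are in
substitutions per site and live on the edge above each non-root node.
Percent support values (0-100) sit on internal edges; a Newick file whose
supports are all <= 1 is auto-detected as fractional and rescaled.

Newick parsing is delegated to dendropy; writing is native so that output
is deterministic (10 significant digits).
"""
from __future__ import annotations

import warnings
from typing import Iterator

import dendropy

__all__ = ["Node", "Tree", "parse_newick", "write_newick", "TreeError"]


class TreeError(ValueError):
    """Structural problem with a tree or a tree operation."""


class Node:
    __slots__ = ("children", "parent", "length", "label", "support")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        support: float | None = None,
    ):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label
        self.length = length
        self.support = support

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} len={self.length} sup={self.support}>"


class Tree:
    """Tree rooted at ``root``; ``rooted`` distinguishes a true root from
    an arbitrary basal trifurcation of an unrooted tree."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # ---------------------------------------------------------- traversal
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        labels = [n.label for n in self.tips()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("tree contains an empty tip label")
        return labels  # type: ignore[return-value]

    def leaf_set(self) -> frozenset[str]:
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        return frozenset(labels)

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def internal_edges(self) -> list[Node]:
        """Nodes whose parent edge is internal (non-root, non-tip)."""
        return [
            n
            for n in self.preorder()
            if n.parent is not None and not n.is_tip
        ]

    def edges(self) -> list[Node]:
        """All nodes carrying an edge above them (everything but the root)."""
        return [n for n in self.preorder() if n.parent is not None]

    # ------------------------------------------------------------ surgery
    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length, node.support)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return Tree(clone(self.root), self.rooted)

    def suppress_unifurcations(self) -> None:
        """Remove degree-2 nodes, summing lengths; keep max support."""
        changed = True
        while changed:
            changed = False
            for node in list(self.preorder()):
                if node.parent is not None and len(node.children) == 1:
                    child = node.children[0]
                    parent = node.parent
                    if child.length is not None or node.length is not None:
                        child.length = (child.length or 0.0) + (node.length or 0.0)
                    sups = [s for s in (child.support, node.support) if s is not None]
                    child.support = max(sups) if sups else None
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                    changed = True
            # a unifurcating root: replace root by its child
            if len(self.root.children) == 1 and not self.root.is_tip:
                child = self.root.children[0]
                child.parent = None
                child.length = None
                child.support = None
                self.root = child
                changed = True

    def unroot(self) -> "Tree":
        """Collapse a bifurcating root into a basal trifurcation (in place)."""
        if len(self.root.children) == 2:
            a, b = self.root.children
            keep, merge = (a, b) if not a.is_tip else (b, a)
            if keep.is_tip:
                # two-tip tree stays as is
                self.rooted = False
                return self
            self.root.children.remove(keep)
            for child in keep.children:
                child.parent = self.root
                self.root.children.append(child)
            merge.length = (merge.length or 0.0) + (keep.length or 0.0)
            sups = [s for s in (merge.support, keep.support) if s is not None]
            merge.support = max(sups) if sups else None
        self.rooted = False
        return self

    def prune_to_taxa(self, taxa) -> "Tree":
        """Induced subtree on ``taxa`` (degree-2 nodes suppressed)."""
        wanted = set(taxa)
        have = set(self.tip_labels())
        unknown = wanted - have
        if unknown:
            raise TreeError(f"unknown taxa: {sorted(unknown)}")
        tree = self.copy()
        for tip in list(tree.tips()):
            if tip.label not in wanted:
                node = tip
                while node.parent is not None and not node.children:
                    parent = node.parent
                    parent.remove_child(node)
                    node = parent
        tree.suppress_unifurcations()
        return tree

    # ---------------------------------------------------------- distances
    def tip_distances_from(self, start: Node) -> dict[str, float]:
        """Path lengths from ``start`` to every tip (undirected)."""
        dist: dict[int, float] = {id(start): 0.0}
        out: dict[str, float] = {}
        stack = [start]
        seen = {id(start)}
        while stack:
            node = stack.pop()
            d = dist[id(node)]
            if node.is_tip and node is not start:
                out[node.label] = d  # type: ignore[index]
            neighbors = list(node.children)
            if node.parent is not None:
                neighbors.append(node.parent)
            for nb in neighbors:
                if id(nb) in seen:
                    continue
                seen.add(id(nb))
                edge = node.length if nb is node.parent else nb.length
                if edge is None:
                    raise TreeError("missing branch length on path")
                dist[id(nb)] = d + edge
                stack.append(nb)
        if start.is_tip:
            out[start.label] = 0.0  # type: ignore[index]
        return out

    # ------------------------------------------------------------- output
    def newick(self, **kw) -> str:
        return write_newick(self, **kw)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree {self.n_tips} tips rooted={self.rooted}>"


# ------------------------------------------------------------------- I/O
def _fmt(x: float) -> str:
    s = f"{x:.10g}"
    return s


def write_newick(
    tree: Tree, lengths: bool = True, supports: bool = True
) -> str:
    def rec(node: Node) -> str:
        if node.is_tip:
            s = node.label or ""
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if supports and node.support is not None and node.parent is not None:
                s += _fmt(node.support)
        if lengths and node.length is not None and node.parent is not None:
            s += ":" + _fmt(node.length)
        return s

    return rec(tree.root) + ";"


def parse_newick(text: str, rooted: bool | None = None) -> Tree:
    """Parse one Newick statement.

    Numeric internal-node labels are interpreted as percent supports on the
    subtending edge.  If every support is <= 1 they are taken to be
    fractional and rescaled to percent (with a warning).
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("Newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if label is None or label == "":
                raise TreeError("empty tip label")
            node = Node(label=label)
        else:
            node = Node()
            raw = dnode.label
            if raw is not None and raw != "":
                try:
                    node.support = float(raw)
                except ValueError:
                    node.label = raw
        node.length = dnode.edge.length
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    root.support = None
    tree = Tree(root)
    sups = [n.support for n in tree.preorder() if n.support is not None]
    if sups and all(s <= 1.0 for s in sups):
        warnings.warn(
            "all support values <= 1; interpreting as fractional and "
            "rescaling to percent",
            stacklevel=2,
        )
        for n in tree.preorder():
            if n.support is not None:
                n.support *= 100.0
    for s in sups:
        if not (0.0 <= s <= 100.0) and s > 1.0:
            if s > 100.0:
                raise TreeError(f"support {s} outside [0, 100]")
    if rooted is None:
        rooted = len(root.children) == 2 and tree.n_tips > 2
    tree.rooted = rooted
    return tree
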