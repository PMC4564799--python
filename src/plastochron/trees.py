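"""Phylogenetic tree container used across the package.

Trees are stored rooted; an unrooted tree is represented by a root of
degree >= 3 (the usual basal multifurcation).  Branch lengths are in
substitutions per site unless a module documents otherwise (chronograms
carry node ages in Myr instead, see :mod:`plastochron.dating`).
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional


class Node:
    __slots__ = ("label", "length", "support", "age", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
        age: Optional[float] = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.age = age
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length}, age={self.age})"


class Tree:
    """A rooted (or basal-multifurcating unrooted) phylogenetic tree."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        from .io import read_newick

        return read_newick(text)

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length, node.support, node.age)
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return Tree(_copy(self.root))

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find_tip(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(f"taxon not in tree: {label!r}")

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        nodes = [n for n in self.postorder() if not n.is_leaf]
        if not include_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_newick(self, lengths: bool = True, supports: bool = False,
                  precision: int = 12) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if supports and node.support is not None:
                    s += f"{node.support:g}"
                elif node.label:
                    s += node.label
            if lengths and node.length is not None:
                s += ":" + format(node.length, f".{precision}g")
            return s

        return fmt(self.root) + ";"

    def __str__(self) -> str:
        return self.to_newick()

    # ------------------------------------------------------------------
    # topology identity
    # ------------------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions as normalized tip-label sets.

        Each internal edge splits the taxa in two; the side *not*
        containing the lexicographically smallest taxon represents the
        split, so the set is rooting-invariant.
        """
        all_tips = frozenset(self.tip_labels())
        anchor = min(all_tips)
        splits: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                clade = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = clade
                if node is self.root:
                    continue
                side = clade if anchor not in clade else all_tips - clade
                if 1 < len(side) < len(all_tips) - 1:
                    splits.add(side)
        return splits

    def topology_key(self) -> frozenset[frozenset[str]]:
        return frozenset(self.bipartitions())

    def same_topology(self, other: "Tree") -> bool:
        return (set(self.tip_labels()) == set(other.tip_labels())
                and self.topology_key() == other.topology_key())

    def clade_node(self, taxa) -> Node:
        """MRCA of ``taxa``; raises if the clade is not present exactly."""
        want = frozenset(taxa)
        below: dict[int, frozenset[str]] = {}
        best = None
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
            if want <= below[id(node)] and best is None:
                best = node
        if best is None:
            missing = want - frozenset(self.tip_labels())
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        return best

    # ------------------------------------------------------------------
    # manipulation
    # ------------------------------------------------------------------
    def suppress_unifurcations(self) -> None:
        """Splice out internal nodes of out-degree 1, merging lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if not node.is_leaf and len(node.children) == 1:
                    child = node.children[0]
                    if node.parent is None:
                        child.parent = None
                        if child.length is not None and node.length:
                            child.length += node.length
                        self.root = child
                    else:
                        parent = node.parent
                        idx = parent.children.index(node)
                        parent.children[idx] = child
                        child.parent = parent
                        if node.length is not None:
                            child.length = (child.length or 0.0) + node.length
                    changed = True
                    break

    def reroot_on_edge(self, child: Node, fraction: float = 0.5) -> "Tree":
        """Return a new tree rooted on the edge above ``child``.

        The edge is split ``fraction`` of the way from ``child`` towards
        its current parent.  The original tree is not modified.
        """
        if child.parent is None:
            raise ValueError("cannot root on the edge above the root")
        tree = self.copy()
        # locate the matching node in the copy by path from root
        path = []
        n = child
        while n.parent is not None:
            path.append(n.parent.children.index(n))
            n = n.parent
        node = tree.root
        for idx in reversed(path):
            node = node.children[idx]

        old_parent = node.parent
        edge_len = node.length if node.length is not None else None
        new_root = Node()
        # detach node from old_parent
        old_parent.children.remove(node)
        node.parent = None
        # hang node below new root
        new_root.add_child(node)
        if edge_len is not None:
            node.length = edge_len * fraction
        # flip parent pointers from old_parent up to the old root
        carry_len = None if edge_len is None else edge_len * (1.0 - fraction)
        prev = new_root
        current: Optional[Node] = old_parent
        while current is not None:
            nxt = current.parent
            nxt_len = current.length
            if nxt is not None:
                nxt.children.remove(current)
            current.parent = None
            prev.add_child(current)
            current.length = carry_len
            carry_len = nxt_len
            prev = current
            current = nxt
        out = Tree(new_root)
        out.suppress_unifurcations()
        return out

    def unroot(self) -> "Tree":
        """Collapse a bifurcating root into a basal trifurcation."""
        tree = self.copy()
        root = tree.root
        if len(root.children) != 2:
            return tree
        a, b = root.children
        keep, fold = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:
            return tree  # two-taxon tree cannot be unrooted further
        root.remove_child(keep)
        merged = None
        if fold.length is not None or keep.length is not None:
            merged = (fold.length or 0.0) + (keep.length or 0.0)
        fold.length = merged
        for child in list(keep.children):
            keep.remove_child(child)
            root.add_child(child)
        # fold stays on the root with the merged length; keep's children
        # are appended, giving the basal trifurcation
        return tree

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)


# ----------------------------------------------------------------------
# enumeration (oracle support for small problems)
# ----------------------------------------------------------------------

def enumerate_unrooted_topologies(taxa: list[str]) -> Iterator[Tree]:
    """Yield every unrooted binary topology on ``taxa`` (3, 15, 105, ...).

    Stepwise-addition enumeration: taxon k+1 is attached to every edge of
    every (k)-taxon tree.  Intended for small n (<= 8) oracle use.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")

    def build(order: tuple[int, ...]) -> Tree:
        root = Node()
        for lab in taxa[:3]:
            root.add_child(Node(lab))
        tree = Tree(root)
        for k, edge_choice in enumerate(order):
            edges = [n for n in tree.postorder() if n is not tree.root]
            target = edges[edge_choice]
            parent = target.parent
            idx = parent.children.index(target)
            mid = Node()
            parent.children[idx] = mid
            mid.parent = parent
            target.parent = None
            mid.add_child(target)
            mid.add_child(Node(taxa[3 + k]))
        return tree

    n_extra = len(taxa) - 3
    edge_counts = [3 + 2 * k for k in range(n_extra)]
    for order in itertools.product(*(range(c) for c in edge_counts)):
        yield build(order)
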