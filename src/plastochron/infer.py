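"""Tree inference: neighbour joining, maximum parsimony, ML search,
bootstrap supports, consensus and out-group rooting.

Parsimony uses the Fitch set-operation pass (unordered characters,
equal weights, gaps as missing) with random-addition starts and
tree-bisection-reconnection (TBR) hill climbing accepting strict
improvements only.  All tie-breaking is deterministic (lexicographic by
taxon label or by canonical edge order) so identical seeds give
identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment
from .models import SubstitutionModel, distance_matrix, \
    optimize_branch_lengths, _compress
from .trees import Node, Tree


# ----------------------------------------------------------------------
# neighbour joining
# ----------------------------------------------------------------------

def neighbor_joining(dm: pd.DataFrame) -> Tree:
    """Saitou-Nei agglomeration on the Q criterion.

    Deterministic: ties in Q are broken by the lexicographically
    smallest (cluster, cluster) label pair.  Negative branch-length
    estimates are clamped to zero.  Returns an unrooted tree (basal
    trifurcation).
    """
    labels = list(dm.index)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    if list(dm.columns) != labels:
        raise ValueError("distance matrix rows/columns disagree")
    D = dm.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(~np.isfinite(D)) or np.any(D < 0):
        raise ValueError("distances must be finite and non-negative")

    nodes = [Node(lab) for lab in labels]
    sort_key = list(labels)          # lexicographic cluster identity

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((sort_key[i], sort_key[j]))), i, j)
            for i, j in cand if i < j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        parent = Node()
        a, b = nodes[i], nodes[j]
        a.length = max(vi, 0.0)
        b.length = max(vj, 0.0)
        parent.add_child(a)
        parent.add_child(b)
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = _shrink(D, d_new, keep)
        nodes = [parent] + [nodes[k] for k in keep]
        sort_key = [min(sort_key[i], sort_key[j])] + [sort_key[k] for k in keep]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    root = Node()
    for nd in (a, b, c):
        root.add_child(nd)
    return Tree(root)


def _shrink(D, d_new, keep):
    sub = D[np.ix_(keep, keep)]
    row = d_new[keep]
    out = np.empty((len(keep) + 1, len(keep) + 1))
    out[0, 0] = 0.0
    out[0, 1:] = row
    out[1:, 0] = row
    out[1:, 1:] = sub
    return out


def nj_tree(alignment: Alignment, model: Optional[SubstitutionModel] = None
            ) -> Tree:
    """NJ on ML distances; GTR+G by default (the standard plastome choice)."""
    model = model or SubstitutionModel.from_spec("GTR+G4")
    return neighbor_joining(distance_matrix(alignment, model))


# ----------------------------------------------------------------------
# Fitch parsimony on an adjacency representation
# ----------------------------------------------------------------------

_CODE2MASK = np.array([1, 2, 4, 8, 15, 15], dtype=np.uint8)


class _UTree:
    """Unrooted tree as an adjacency map; tips carry alignment rows."""

    __slots__ = ("adj", "tip_row", "next_id")

    def __init__(self):
        self.adj: dict[int, list[int]] = {}
        self.tip_row: dict[int, int] = {}
        self.next_id = 0

    def new_node(self, row: Optional[int] = None) -> int:
        nid = self.next_id
        self.next_id += 1
        self.adj[nid] = []
        if row is not None:
            self.tip_row[nid] = row
        return nid

    def connect(self, u: int, v: int) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)

    def disconnect(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    def copy(self) -> "_UTree":
        t = _UTree.__new__(_UTree)
        t.adj = {k: list(v) for k, v in self.adj.items()}
        t.tip_row = dict(self.tip_row)
        t.next_id = self.next_id
        return t

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, nb in sorted(self.adj.items())
                for v in nb if u < v]

    def insert_on_edge(self, u: int, v: int) -> int:
        mid = self.new_node()
        self.disconnect(u, v)
        self.connect(u, mid)
        self.connect(mid, v)
        return mid

    def suppress_degree2(self, node: int) -> None:
        a, b = self.adj[node]
        self.disconnect(node, a)
        self.disconnect(node, b)
        del self.adj[node]
        self.connect(a, b)

    # -- conversion -------------------------------------------------------
    @classmethod
    def from_tree(cls, tree: Tree, taxa: Sequence[str]) -> "_UTree":
        row_of = {t: i for i, t in enumerate(taxa)}
        ut = cls()
        tree = tree.unroot() if len(tree.root.children) == 2 else tree

        def build(node) -> int:
            nid = ut.new_node(row_of[node.label] if node.is_leaf else None)
            for child in node.children:
                ut.connect(nid, build(child))
            return nid

        build(tree.root)
        return ut

    def to_tree(self, taxa: Sequence[str]) -> Tree:
        def build(node: int, parent: Optional[int]) -> Node:
            if node in self.tip_row:
                out = Node(taxa[self.tip_row[node]])
            else:
                out = Node()
            for nb in self.adj[node]:
                if nb != parent:
                    out.add_child(build(nb, node))
            return out

        # root at the internal neighbour of the lowest-id tip
        tip = min(self.tip_row)
        root_id = self.adj[tip][0]
        root = build(root_id, None)
        return Tree(root)


def _fitch_score(ut: _UTree, masks: np.ndarray, weights: np.ndarray) -> int:
    """Weighted Fitch length over compressed patterns.

    ``masks``: (n_rows, n_patterns) uint8 state bitmasks per taxon.
    """
    tip = min(ut.tip_row)
    start = ut.adj[tip][0]
    total = 0.0
    out_mask: dict[int, np.ndarray] = {}
    # iterative postorder from `start`, excluding the edge to `tip`
    stack = [(start, tip, False)]
    while stack:
        node, parent, expanded = stack.pop()
        if node in ut.tip_row:
            out_mask[node] = masks[ut.tip_row[node]]
            continue
        if not expanded:
            stack.append((node, parent, True))
            for nb in ut.adj[node]:
                if nb != parent:
                    stack.append((nb, node, False))
            continue
        children = [nb for nb in ut.adj[node] if nb != parent]
        acc = out_mask[children[0]]
        for ch in children[1:]:
            inter = acc & out_mask[ch]
            empty = inter == 0
            total += weights[empty].sum()
            acc = np.where(empty, acc | out_mask[ch], inter)
        out_mask[node] = acc
    inter = out_mask[start] & masks[ut.tip_row[tip]]
    total += weights[inter == 0].sum()
    return int(round(total))


def fitch_length(tree: Tree, alignment: Alignment) -> int:
    """Minimum number of state changes on ``tree`` (Fitch, gaps missing)."""
    if set(tree.tip_labels()) != set(alignment.taxa):
        raise ValueError("tree and alignment taxa differ")
    patterns, weights = _compress(alignment.codes)
    masks = _CODE2MASK[patterns]
    ut = _UTree.from_tree(tree, alignment.taxa)
    return _fitch_score(ut, masks, weights)


# ----------------------------------------------------------------------
# parsimony heuristic search
# ----------------------------------------------------------------------

@dataclass
class SearchOptions:
    n_addition_replicates: int = 10
    swap: str = "TBR"                 # TBR | NNI | none
    keep_all_optimal: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_addition_replicates < 1:
            raise ValueError("need >= 1 addition replicate")
        if self.swap not in ("TBR", "NNI", "none"):
            raise ValueError(f"unknown swap {self.swap!r}")


def _stepwise_addition(masks, weights, order: Sequence[int]) -> _UTree:
    ut = _UTree()
    tips = [ut.new_node(r) for r in order[:3]]
    center = ut.new_node()
    for t in tips:
        ut.connect(center, t)
    for row in order[3:]:
        best = None
        for u, v in ut.edges():
            cand = ut.copy()
            mid = cand.insert_on_edge(u, v)
            cand.connect(mid, cand.new_node(row))
            score = _fitch_score(cand, masks, weights)
            if best is None or score < best[0]:
                best = (score, cand)
        ut = best[1]
    return ut


def _bisections(ut: _UTree):
    """Yield TBR candidates: neighbours of ``ut`` under bisect-reconnect."""
    for u, v in ut.edges():
        base = ut.copy()
        base.disconnect(u, v)
        comp_u = _component(base, u)
        comp_v = set(base.adj) - comp_u
        cleaned = base.copy()
        attach_points = []
        for anchor, comp in ((u, comp_u), (v, comp_v)):
            if len(comp) == 1:
                attach_points.append([("node", anchor)])
            else:
                cleaned.suppress_degree2(anchor)
                comp2 = comp - {anchor}
                pts = [("edge", (a, b)) for a, b in cleaned.edges()
                       if a in comp2 and b in comp2]
                attach_points.append(pts)
        for pa in attach_points[0]:
            for pb in attach_points[1]:
                cand = cleaned.copy()
                ends = []
                for kind, where in (pa, pb):
                    if kind == "node":
                        ends.append(where)
                    else:
                        ends.append(cand.insert_on_edge(*where))
                cand.connect(ends[0], ends[1])
                yield cand


def _component(ut: _UTree, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in ut.adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def _nni_candidates(ut: _UTree):
    for u, v in ut.edges():
        if u in ut.tip_row or v in ut.tip_row:
            continue
        u_nb = [x for x in ut.adj[u] if x != v]
        v_nb = [x for x in ut.adj[v] if x != u]
        for swap_v in (v_nb[0], v_nb[1]):
            cand = ut.copy()
            cand.disconnect(u, u_nb[0])
            cand.disconnect(v, swap_v)
            cand.connect(u, swap_v)
            cand.connect(v, u_nb[0])
            yield cand


def _hill_climb(ut: _UTree, masks, weights, swap: str) -> tuple[_UTree, int]:
    score = _fitch_score(ut, masks, weights)
    if swap == "none":
        return ut, score
    gen = _bisections if swap == "TBR" else _nni_candidates
    improved = True
    while improved:
        improved = False
        best_cand, best_score = None, score
        for cand in gen(ut):
            s = _fitch_score(cand, masks, weights)
            if s < best_score:
                best_cand, best_score = cand, s
        if best_cand is not None:
            ut, score = best_cand, best_score
            improved = True
    return ut, score


def parsimony_search(alignment: Alignment,
                     options: Optional[SearchOptions] = None
                     ) -> tuple[list[Tree], int]:
    """Random-addition + branch-swapping search for most parsimonious trees.

    Returns (trees, score).  With ``keep_all_optimal`` every distinct
    optimal topology found across replicates is retained (the MulTrees
    behaviour); otherwise only the first.
    """
    options = options or SearchOptions()
    if alignment.n_taxa < 4:
        raise ValueError("parsimony search needs >= 4 taxa")
    patterns, weights = _compress(alignment.codes)
    masks = _CODE2MASK[patterns]
    rng = np.random.default_rng(options.seed)
    best_score = None
    found: dict[frozenset, Tree] = {}
    for _ in range(options.n_addition_replicates):
        order = rng.permutation(alignment.n_taxa)
        ut = _stepwise_addition(masks, weights, list(order))
        ut, score = _hill_climb(ut, masks, weights, options.swap)
        if best_score is None or score < best_score:
            best_score = score
            found.clear()
        if score == best_score:
            tree = ut.to_tree(alignment.taxa)
            key = tree.topology_key()
            if key not in found:
                found[key] = tree
    trees = list(found.values())
    if not options.keep_all_optimal:
        trees = trees[:1]
    return trees, int(best_score)


# ----------------------------------------------------------------------
# ML topology search (NNI over a start tree)
# ----------------------------------------------------------------------

def nni_ml_search(alignment: Alignment, model: SubstitutionModel,
                  start_tree: Tree, screen_sweeps: int = 1,
                  tol: float = 1e-3) -> tuple[Tree, float]:
    """Hill-climbing NNI search maximizing the pruning log-likelihood.

    Each sweep re-optimizes candidate branch lengths coarsely
    (``screen_sweeps`` coordinate passes) and accepts the best strictly
    improving neighbour; stops when a sweep yields none, then fully
    re-optimizes the final tree.  The returned lnL never falls below
    that of the optimized start tree.
    """
    taxa = alignment.taxa
    ut = _UTree.from_tree(start_tree, taxa)
    current_tree, current = optimize_branch_lengths(
        ut.to_tree(taxa), alignment, model)
    improved = True
    while improved:
        improved = False
        best = None
        for cand in _nni_candidates(ut):
            t = cand.to_tree(taxa)
            t, lnl = optimize_branch_lengths(t, alignment, model,
                                             max_sweeps=screen_sweeps)
            if lnl > current + tol and (best is None or lnl > best[1]):
                best = (cand, lnl, t)
        if best is not None:
            ut = best[0]
            current_tree, current = optimize_branch_lengths(
                best[2], alignment, model)
            improved = True
    return current_tree, current


# ----------------------------------------------------------------------
# bootstrap, consensus, rooting
# ----------------------------------------------------------------------

def _infer_once(alignment: Alignment, method: str,
                model: Optional[SubstitutionModel], seed: int) -> Tree:
    if method == "nj":
        return nj_tree(alignment, model)
    if method == "parsimony":
        trees, _ = parsimony_search(
            alignment, SearchOptions(n_addition_replicates=1, seed=seed))
        return trees[0]
    if method == "ml":
        m = model or SubstitutionModel.from_spec("GTR+G4+I")
        start = nj_tree(alignment, SubstitutionModel.from_spec("JC"))
        tree, _ = nni_ml_search(alignment, m, start)
        return tree
    raise ValueError(f"unknown method {method!r}")


def bootstrap(alignment: Alignment, method: str = "parsimony",
              n_replicates: int = 100, seed: int = 0,
              model: Optional[SubstitutionModel] = None,
              point_tree: Optional[Tree] = None) -> tuple[Tree, pd.DataFrame]:
    """Non-parametric bootstrap supports on the point-estimate tree.

    Columns are resampled with replacement; each pseudo-replicate is
    re-analysed with ``method`` (parsimony uses a single addition
    replicate per pseudo-replicate); supports are the percentage of
    replicates whose tree contains each bipartition of the point tree.
    """
    if n_replicates < 1:
        raise ValueError("need >= 1 bootstrap replicate")
    rng = np.random.default_rng(seed)
    if point_tree is None:
        point_tree = _infer_once(alignment, method, model, seed)
    splits = point_tree.topology_key()
    hits = {s: 0 for s in splits}
    ncol = alignment.column_count
    for rep in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        sub = alignment.take_columns(cols)
        rep_tree = _infer_once(sub, method, model, seed=int(rng.integers(2**31)))
        rep_splits = rep_tree.topology_key()
        for s in splits:
            if s in rep_splits:
                hits[s] += 1
    supported = point_tree.copy()
    all_tips = frozenset(alignment.taxa)
    anchor = min(all_tips)
    rows = []
    below: dict[int, frozenset] = {}
    for node in supported.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
            continue
        clade = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = clade
        if node is supported.root:
            continue
        side = clade if anchor not in clade else all_tips - clade
        if side in hits:
            node.support = 100.0 * hits[side] / n_replicates
            rows.append({"bipartition": "|".join(sorted(side)),
                         "support": node.support})
    return supported, pd.DataFrame(rows)


def majority_consensus(trees: Sequence[Tree], threshold: float = 0.5) -> Tree:
    """Majority-rule consensus; bipartition frequencies become supports."""
    if not trees:
        raise ValueError("no trees given")
    taxa = set(trees[0].tip_labels())
    for t in trees[1:]:
        if set(t.tip_labels()) != taxa:
            raise ValueError("consensus requires identical taxon sets")
    all_tips = frozenset(taxa)
    anchor = min(all_tips)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.topology_key():
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    kept = {s: c / n for s, c in counts.items() if c / n > threshold}
    # nest clades (all splits taken on the side away from the anchor);
    # splits above the majority threshold are mutually compatible
    clades = sorted(kept, key=lambda s: (-len(s), sorted(s)))
    root = Node()
    node_for: dict[frozenset, Node] = {all_tips: root}
    for clade in clades:
        node = Node(support=100.0 * kept[clade])
        parent = min((c for c in node_for if clade < c), key=len)
        node_for[parent].add_child(node)
        node_for[clade] = node
    for lab in sorted(taxa):
        parent = min((c for c in node_for if lab in c), key=len)
        node_for[parent].add_child(Node(lab))
    return Tree(root)


def root_with_outgroup(tree: Tree, outgroup_taxon: str) -> Tree:
    """Root on the out-group's pendant edge (split at its midpoint)."""
    tip = tree.find_tip(outgroup_taxon)
    return tree.reroot_on_edge(tip, fraction=0.5)
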