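"""Unrooted phylogenetic trees, bipartitions, and topology diagnostics.

Trees are held in a lightweight rooted data structure with unrooted
semantics: the "root" is just an internal reference node, and every
topology question is asked in terms of the leaf bipartitions the edges
induce.  Newick parsing is delegated to dendropy; the pruning likelihood
engine consumes the flattened form of these trees.

Besides the Robinson-Foulds (RF) bipartition distance, this module
implements a lower bound on the number of *incorrect* bipartitions
carried by the worse of two phylogenies inferred from the same data: if
two binary trees on n taxa are at RF distance d, the union of their
bipartition sets has (2n-3) + d/2 members, so at least d/2 of them are
absent from the (2n-3)-bipartition true tree, and the worse tree must
contain at least half of those — d/4 in total.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "PhyloTree",
    "Node",
    "NewickError",
    "LeafSetMismatchError",
    "parse_newick",
    "bipartitions",
    "rf_distance",
    "normalized_rf",
    "incorrect_bipartition_bound",
    "count_incorrect_in_union",
    "filter_branches",
    "split_alignment",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class LeafSetMismatchError(ValueError):
    """Trees being compared do not share the same leaf names."""


@dataclass
class Node:
    name: str | None = None
    length: float | None = None  # branch above this node; None at the root
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class PhyloTree:
    """Unrooted tree over named leaves, with optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        self._collapse_degree_two_root()
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None for n in names):
            raise NewickError("every leaf must be named")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise NewickError(f"duplicate leaf names: {', '.join(dupes)}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def _collapse_degree_two_root(self) -> None:
        # a rooted Newick string has a degree-2 root; merge its two edges
        # so that the structure is genuinely unrooted (root degree >= 3,
        # or a trivial 2-leaf/1-leaf tree)
        root = self.root
        while len(root.children) == 2 and not all(c.is_leaf for c in root.children):
            keep = next(c for c in root.children if not c.is_leaf)
            other = next(c for c in root.children if c is not keep)
            extra = other.length
            if keep.length is not None and extra is not None:
                other.length = keep.length + extra
            elif keep.length is not None:
                other.length = keep.length
            keep.parent = None
            keep.add(other)
            root = keep
        root.length = None
        root.parent = None
        self.root = root

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            c = Node(name=node.name, length=node.length)
            for ch in node.children:
                c.add(clone(ch))
            return c

        return PhyloTree(clone(self.root))

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[Node]:
        """Child nodes of every edge (all nodes except the root)."""
        return [n for n in self.postorder() if n.parent is not None]

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.edges())

    # -- serialization -------------------------------------------------

    def newick(self, lengths: bool = True, digits: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = _quote(node.name)
            else:
                label = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths and node.length is not None:
                label += f":{node.length:.{digits}g}"
            return label

        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return f"<PhyloTree {self.n_leaves} leaves>"

    # -- topology ------------------------------------------------------

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        return bipartitions(self, include_trivial=include_trivial)


def _quote(name: str) -> str:
    if any(c in name for c in "()[]{}:;,= \t'\""):
        return "'" + name.replace("'", "''") + "'"
    return name


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick tree (dendropy does the lexical work)."""
    text = text.strip()
    if not text.endswith(";"):
        text += ";"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse Newick string: {exc}") from None

    def convert(dnode) -> Node:
        node = Node(
            name=dnode.taxon.label if dnode.taxon is not None else None,
            length=dnode.edge.length,
        )
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def read_newick_file(path) -> list[PhyloTree]:
    """Read one tree per non-empty line (multi-Newick file)."""
    trees = []
    for line in open(path):
        line = line.strip()
        if line:
            trees.append(parse_newick(line))
    return trees


# ---------------------------------------------------------------------------
# Bipartitions and tree distances


def _canonical(split_side: Iterable[str], all_leaves: frozenset[str]) -> frozenset[str]:
    """Canonical key of a bipartition: the side NOT containing the
    lexicographically smallest leaf."""
    side = frozenset(split_side)
    if min(all_leaves) in side:
        side = all_leaves - side
    return side


def bipartitions(tree: PhyloTree, include_trivial: bool = False) -> set[frozenset[str]]:
    """The leaf bipartitions induced by the edges of ``tree``.

    With ``include_trivial`` the count equals the number of edges
    (2n-3 for an unrooted binary tree); without it only internal splits
    (both sides of size >= 2) are returned.
    """
    all_leaves = frozenset(tree.leaf_names())
    if len(all_leaves) < 2:
        raise ValueError("need at least two leaves")
    below: dict[int, frozenset[str]] = {}
    splits: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is None:
            continue
        side = below[id(node)]
        if len(side) == 0 or len(side) == len(all_leaves):
            continue
        trivial = min(len(side), len(all_leaves) - len(side)) == 1
        if trivial and not include_trivial:
            continue
        splits.add(_canonical(side, all_leaves))
    return splits


def _check_same_leaves(a: PhyloTree, b: PhyloTree) -> frozenset[str]:
    la, lb = frozenset(a.leaf_names()), frozenset(b.leaf_names())
    if la != lb:
        only_a = sorted(la - lb)
        only_b = sorted(lb - la)
        raise LeafSetMismatchError(
            f"leaf sets differ; only in first: {only_a}; only in second: {only_b}"
        )
    return la


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    """Robinson-Foulds distance: bipartitions unique to either tree.

    Counted over nontrivial splits; trivial (single-leaf) splits are
    always shared, so including them would change nothing.
    """
    _check_same_leaves(a, b)
    return len(a.bipartitions() ^ b.bipartitions())


def normalized_rf(a: PhyloTree, b: PhyloTree) -> float:
    """RF distance divided by the 2n-3 bipartitions of a binary tree."""
    leaves = _check_same_leaves(a, b)
    n = len(leaves)
    if n < 3:
        raise ValueError("normalized RF needs at least three leaves")
    return rf_distance(a, b) / (2 * n - 3)


def incorrect_bipartition_bound(rf: int) -> tuple[float, int]:
    """Lower bound on incorrect bipartitions in the worse of two trees.

    For two binary trees at RF distance ``rf`` inferred from the same
    alignment, the worse-likelihood tree carries at least ``rf / 4``
    bipartitions absent from the (unknown) true tree.  Returns the raw
    bound and its integer ceiling.
    """
    if rf < 0:
        raise ValueError("RF distance cannot be negative")
    if rf % 2:
        raise ValueError(f"RF distance must be even (symmetric difference), got {rf}")
    bound = rf / 4.0
    return bound, math.ceil(bound)


def count_incorrect_in_union(a: PhyloTree, b: PhyloTree, truth: PhyloTree) -> int:
    """Nontrivial bipartitions of ``a`` or ``b`` that the true tree lacks."""
    _check_same_leaves(a, b)
    _check_same_leaves(a, truth)
    union = a.bipartitions() | b.bipartitions()
    return len(union - truth.bipartitions())


# ---------------------------------------------------------------------------
# Branch filtering and tree-guided alignment splitting


def _suppress_unary(node: Node) -> None:
    """Collapse any degree-2 (single-child) internal nodes below ``node``."""
    for child in list(node.children):
        _suppress_unary(child)
    if len(node.children) == 1 and node.parent is not None:
        child = node.children[0]
        if child.length is not None and node.length is not None:
            child.length += node.length
        elif node.length is not None:
            child.length = node.length
        parent = node.parent
        idx = parent.children.index(node)
        parent.children[idx] = child
        child.parent = parent


def _as_tree(node: Node) -> PhyloTree | None:
    """Detach ``node`` and normalize it into a standalone tree, or None
    if it has no leaves left."""
    node.parent = None
    node.length = None
    while len(node.children) == 1:
        node = node.children[0]
        node.parent = None
        node.length = None
    if node.is_leaf and node.name is None:
        return None
    for child in list(node.children):
        _suppress_unary(child)
    return PhyloTree(node)


def filter_branches(
    tree: PhyloTree, min_len: float = 0.0, max_len: float = 2.0
) -> list[PhyloTree]:
    """Remove noise branches, cutting the tree into a forest.

    Branches with length <= ``min_len`` are removed: internal ones are
    collapsed into polytomies, terminal ones drop their leaf.  Branches
    with length >= ``max_len`` are cut, each cut separating the tree into
    independent subtrees.  Returns the resulting forest (singleton list if
    nothing was cut); retained branches keep their lengths unchanged.
    """
    work = tree.copy()
    for node in work.postorder():
        if node.parent is not None and node.length is None:
            raise ValueError("filter_branches requires branch lengths on every edge")

    roots: list[Node] = [work.root]
    # pass 1: cut long branches (detach subtree, leave a unary scar to clean later)
    def cut_long(node: Node) -> None:
        for child in list(node.children):
            cut_long(child)
        if node.parent is not None and node.length is not None and node.length >= max_len:
            node.parent.children.remove(node)
            node.parent = None
            roots.append(node)

    cut_long(work.root)

    # pass 2: within each piece, collapse short internal branches and drop
    # leaves attached by short terminal branches
    def collapse_short(node: Node) -> None:
        for child in list(node.children):
            collapse_short(child)
        if node.parent is None or node.length is None or node.length > min_len:
            return
        parent = node.parent
        if node.is_leaf:
            parent.children.remove(node)
        else:
            idx = parent.children.index(node)
            parent.children[idx : idx + 1] = node.children
            for c in node.children:
                c.parent = parent

    forest = []
    for root in roots:
        collapse_short(root)
        piece = _as_tree(root)
        if piece is not None and piece.n_leaves >= 1:
            forest.append(piece)
    return forest


def _cut_edge(tree: PhyloTree, child: Node) -> tuple[PhyloTree, PhyloTree]:
    """Split ``tree`` at the edge above ``child`` into two trees."""
    parent = child.parent
    parent.children.remove(child)
    child.parent = None
    part_a = _as_tree(child)
    node = tree.root
    part_b = _as_tree(node)
    return part_a, part_b


def split_tree(tree: PhyloTree, max_size: int) -> list[PhyloTree]:
    """Recursively cut at the most balanced edge until all parts have at
    most ``max_size`` leaves.  Ties break on the lexicographically
    smallest canonical bipartition key, so the result is deterministic.
    """
    if max_size < 4:
        raise ValueError("max_size must be at least 4")
    if tree.n_leaves <= max_size:
        return [tree]
    work = tree.copy()
    all_leaves = frozenset(work.leaf_names())
    below: dict[int, frozenset[str]] = {}
    candidates = []  # (imbalance, sort key, node)
    for node in work.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is None:
            continue
        side = below[id(node)]
        k = len(side)
        if k == 0 or k == len(all_leaves):
            continue
        imbalance = abs(len(all_leaves) - 2 * k)
        key = tuple(sorted(_canonical(side, all_leaves)))
        candidates.append((imbalance, key, node))
    if not candidates:
        raise ValueError("tree has no internal structure to split")
    _, _, best = min(candidates, key=lambda c: (c[0], c[1]))
    part_a, part_b = _cut_edge(work, best)
    return split_tree(part_a, max_size) + split_tree(part_b, max_size)


def split_alignment(alignment, guide: PhyloTree, max_size: int = 128):
    """Split an alignment into tractable pieces guided by a tree.

    The guide tree is recursively cut at its most balanced edge until
    every part has at most ``max_size`` leaves; each part keeps all
    alignment columns for its taxa.  Returns ``[(sub_alignment, subtree),
    ...]``; the parts' taxon sets partition the guide's leaves.
    """
    if max_size < 4:
        raise ValueError("max_size must be at least 4")
    names = set(alignment.names)
    missing = [l for l in guide.leaf_names() if l not in names]
    if missing:
        raise ValueError(f"guide-tree leaves missing from alignment: {missing[:5]}")
    parts = split_tree(guide, max_size)
    return [(alignment.subset(p.leaf_names()), p) for p in parts]
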