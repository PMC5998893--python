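"""Unrooted phylogenetic trees with polytomies, support values, and oracles.

This module provides the tree model used throughout the package: a rooted
*representation* of an unrooted tree (the root is an arbitrary internal node
of degree >= 3 after canonicalization).  Internal edges may carry a support
value (percent) and a length.  On top of the model it implements newick I/O
(parsing is delegated to dendropy), low-support branch contraction, the
partition view of internal nodes, and deliberately brute-force quartet and
Robinson-Foulds oracles that serve as ground truth for the optimized engine.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "TaxonSet",
    "Node",
    "Tree",
    "GeneTreeCollection",
    "NewickParseError",
    "parse_newick",
    "parse_newick_collection",
    "write_newick",
    "contract_low_support",
    "node_partitions",
    "bipartition_clusters",
    "induced_quartet",
    "shared_quartets",
    "resolved_quartet_count",
    "fn_rate",
    "restrict",
    "tree_from_clusters",
]


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed."""


class TaxonSet:
    """An ordered, immutable set of species labels with stable indices.

    Indices are 0..n-1 in the order given and are used as bit positions for
    cluster bitmasks elsewhere in the package.
    """

    __slots__ = ("labels", "index", "n", "full_mask")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(labels)
        if not labels:
            raise ValueError("TaxonSet requires at least one label")
        if len(set(labels)) != len(labels):
            raise ValueError("taxon labels must be unique")
        if any(not lab for lab in labels):
            raise ValueError("taxon labels must be nonempty")
        self.labels = labels
        self.index = {lab: i for i, lab in enumerate(labels)}
        self.n = len(labels)
        self.full_mask = (1 << self.n) - 1

    def mask_of(self, labels: Iterable[str]) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self.index[lab]
        return m

    def labels_of(self, mask: int) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in bits(mask))

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index

    def __repr__(self) -> str:
        return f"TaxonSet(n={self.n})"


def bits(mask: int) -> Iterator[int]:
    """Yield set bit positions of ``mask`` in ascending order."""
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


class Node:
    __slots__ = ("children", "parent", "label", "length", "support")

    def __init__(self, label: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label
        self.length = length
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Tree:
    """Rooted representation of an unrooted tree; leaves carry taxon labels."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator[Node]:
        return (v for v in self.postorder() if v.is_leaf)

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(v.label for v in self.leaves())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def has_support(self) -> bool:
        return any(v.support is not None
                   for v in self.postorder() if not v.is_leaf)

    # -- structure ---------------------------------------------------------
    def copy(self) -> "Tree":
        def rec(v: Node) -> Node:
            w = Node(v.label, v.length, v.support)
            for c in v.children:
                w.add(rec(c))
            return w
        return Tree(rec(self.root))

    def is_binary(self) -> bool:
        """True iff every internal node of the *unrooted* tree has degree 3."""
        n = self.n_leaves
        if n <= 3:
            return all(len(v.children) in (0, 2) or v is self.root
                       for v in self.postorder())
        for v in self.postorder():
            if v.is_leaf:
                continue
            deg = len(v.children) + (0 if v is self.root else 1)
            if deg != 3:
                return False
        return True

    def canonicalize(self) -> "Tree":
        """Suppress degree-2 nodes and unroot (in place); return self."""
        _suppress_unary(self)
        _unroot(self)
        return self

    def __repr__(self) -> str:
        return f"Tree({write_newick(self)!r})"


def _suppress_unary(tree: Tree) -> None:
    # remove internal nodes with a single child, merging edge attributes
    changed = True
    while changed:
        changed = False
        for v in list(tree.postorder()):
            if v.is_leaf or len(v.children) != 1:
                continue
            child = v.children[0]
            if v.parent is None:
                child.parent = None
                child.length = None
                child.support = None
                tree.root = child
            else:
                p = v.parent
                i = p.children.index(v)
                p.children[i] = child
                child.parent = p
                if v.length is not None or child.length is not None:
                    child.length = (v.length or 0.0) + (child.length or 0.0)
                if child.support is None:
                    child.support = v.support
            changed = True


def _unroot(tree: Tree) -> None:
    root = tree.root
    if len(root.children) != 2:
        return
    a, b = root.children
    if a.is_leaf and b.is_leaf:
        return  # 2-taxon tree; nothing to suppress
    keep, other = (a, b) if not a.is_leaf else (b, a)
    # merge the two root edges into one edge below `keep`
    if keep.length is not None or other.length is not None:
        other.length = (keep.length or 0.0) + (other.length or 0.0)
    if other.support is None:
        other.support = keep.support
    keep.parent = None
    keep.length = None
    keep.support = None
    keep.children.append(other)
    other.parent = keep
    tree.root = keep


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a single newick statement into a canonicalized :class:`Tree`.

    Internal node labels that parse as numbers in [0, 100] are stored as
    branch support; if every support value is <= 1 they are interpreted as
    fractions and rescaled to percent.  Rooted inputs are silently unrooted.
    """
    text = text.strip()
    if not text:
        raise NewickParseError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    if dtree.seed_node is None or not dtree.leaf_nodes():
        raise NewickParseError("newick string encodes an empty tree")

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise NewickParseError("leaf without a label")
            node = Node(label=dnode.taxon.label, length=dnode.edge.length)
        else:
            support = None
            if dnode.label is not None:
                try:
                    val = float(dnode.label)
                except ValueError:
                    val = None
                if val is not None and 0.0 <= val <= 100.0:
                    support = val
            node = Node(length=dnode.edge.length, support=support)
            for dc in dnode.child_nodes():
                node.add(convert(dc))
        return node

    tree = Tree(convert(dtree.seed_node))
    labels = [v.label for v in tree.leaves()]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate leaf labels: {', '.join(dup)}")
    tree.canonicalize()
    supports = [v.support for v in tree.postorder() if v.support is not None]
    if supports and max(supports) <= 1.0:
        for v in tree.postorder():
            if v.support is not None:
                v.support *= 100.0
    return tree


def parse_newick_collection(text: str) -> list[Tree]:
    """Parse one newick tree per non-empty line."""
    trees = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(parse_newick(line))
        except NewickParseError as exc:
            raise NewickParseError(f"line {lineno}: {exc}") from exc
    if not trees:
        raise NewickParseError("no trees found in input")
    return trees


def write_newick(tree: Tree, with_support: bool = True,
                 with_lengths: bool = True, length_format: str = "g") -> str:
    def fmt(v: Node) -> str:
        if v.is_leaf:
            s = v.label
        else:
            s = "(" + ",".join(fmt(c) for c in v.children) + ")"
            if with_support and v.support is not None:
                s += format(v.support, "g")
        if with_lengths and v.length is not None:
            s += ":" + format(v.length, length_format)
        return s
    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# contraction
# ---------------------------------------------------------------------------

CONTRACTION_DISABLED: float | None = None
"""Sentinel passed as tau to leave the tree unchanged."""


def contract_low_support(tree: Tree, tau: float | None) -> Tree:
    """Collapse every internal edge whose support is <= ``tau`` (percent).

    Edges without a support value are treated as fully supported and never
    collapsed; leaf edges are never collapsed.  ``tau=None`` disables
    contraction and returns an unchanged copy.
    """
    if tau is None:
        return tree.copy()
    if not (0.0 <= tau <= 100.0):
        raise ValueError(f"contraction threshold must be in [0, 100]: {tau}")
    out = tree.copy()
    for v in list(out.postorder()):
        if v.is_leaf or v.parent is None:
            continue
        if v.support is not None and v.support <= tau:
            p = v.parent
            i = p.children.index(v)
            p.children[i:i + 1] = v.children
            for c in v.children:
                c.parent = p
    return out.canonicalize()


# ---------------------------------------------------------------------------
# partitions, bipartitions, quartets
# ---------------------------------------------------------------------------

def _subtree_sets(tree: Tree) -> dict[Node, frozenset[str]]:
    below: dict[Node, frozenset[str]] = {}
    for v in tree.postorder():
        if v.is_leaf:
            below[v] = frozenset((v.label,))
        else:
            below[v] = frozenset().union(*(below[c] for c in v.children))
    return below


def node_partitions(tree: Tree) -> list[tuple[frozenset[str], ...]]:
    """The multi-way split of the tree's leaf set at each internal node.

    A node of unrooted degree m yields m parts: each neighboring subtree's
    leaf set, with the part "above" a non-root node taken relative to the
    tree's own leaf set.  Parts are canonically ordered by smallest label.
    """
    below = _subtree_sets(tree)
    full = below[tree.root]
    out = []
    for v in tree.postorder():
        if v.is_leaf:
            continue
        parts = [below[c] for c in v.children]
        if v is not tree.root:
            parts.append(full - below[v])
        if len(parts) >= 3:
            out.append(tuple(sorted(parts, key=min)))
    return out


def bipartition_clusters(tree: Tree) -> set[frozenset[str]]:
    """Internal bipartitions as canonical clusters (side without the
    lexicographically smallest leaf)."""
    below = _subtree_sets(tree)
    full = below[tree.root]
    anchor = min(full)
    n = len(full)
    out: set[frozenset[str]] = set()
    for v in tree.postorder():
        if v is tree.root or v.is_leaf:
            continue
        c = below[v]
        if 2 <= len(c) <= n - 2:
            out.add(full - c if anchor in c else c)
    return out


def _splitting_clusters(tree: Tree) -> list[frozenset[str]]:
    below = _subtree_sets(tree)
    return [below[v] for v in tree.postorder() if v is not tree.root]


def induced_quartet(tree: Tree, four_taxa: Iterable[str],
                    _clusters: Sequence[frozenset[str]] | None = None
                    ) -> frozenset[frozenset[str]] | None:
    """Restriction of the tree to 4 leaves: the pair split, or None if a star.

    Returned as ``{{a, b}, {c, d}}`` for the topology ab|cd.
    """
    four = frozenset(four_taxa)
    if len(four) != 4:
        raise ValueError("exactly 4 distinct taxa required")
    leaf_set = tree.leaf_labels()
    missing = four - leaf_set
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    clusters = _clusters if _clusters is not None else _splitting_clusters(tree)
    for c in clusters:
        inside = four & c
        if len(inside) == 2:
            return frozenset((inside, four - inside))
    return None


def shared_quartets(t: Tree, g: Tree) -> int:
    """Number of 4-subsets of the common leaf set with the same resolved
    topology in both trees.  Brute force over all 4-subsets: the project-wide
    scoring oracle (O(n^4); not a production path)."""
    common = sorted(t.leaf_labels() & g.leaf_labels())
    ct = _splitting_clusters(t)
    cg = _splitting_clusters(g)
    count = 0
    for four in itertools.combinations(common, 4):
        qt = induced_quartet(t, four, _clusters=ct)
        if qt is None:
            continue
        if qt == induced_quartet(g, four, _clusters=cg):
            count += 1
    return count


def resolved_quartet_count(t: Tree) -> int:
    """Number of 4-subsets on which ``t`` induces a resolved topology."""
    leaves = sorted(t.leaf_labels())
    cl = _splitting_clusters(t)
    return sum(1 for four in itertools.combinations(leaves, 4)
               if induced_quartet(t, four, _clusters=cl) is not None)


def fn_rate(reference: Tree, estimate: Tree) -> float:
    """Fraction of reference internal bipartitions absent from the estimate.

    Equals the normalized Robinson-Foulds distance when both trees are
    binary.  Both trees must be on the same leaf set.
    """
    if reference.leaf_labels() != estimate.leaf_labels():
        raise ValueError("fn_rate requires identical leaf sets")
    ref = bipartition_clusters(reference)
    if not ref:
        return 0.0
    est = bipartition_clusters(estimate)
    return len(ref - est) / len(ref)


# ---------------------------------------------------------------------------
# restriction and construction
# ---------------------------------------------------------------------------

def restrict(tree: Tree, taxa: Iterable[str]) -> Tree:
    """The tree induced on a subset of its leaves (canonicalized copy)."""
    keep = set(taxa)
    out = tree.copy()

    def prune(v: Node) -> Node | None:
        if v.is_leaf:
            return v if v.label in keep else None
        v.children = [w for w in (prune(c) for c in v.children)
                      if w is not None]
        for c in v.children:
            c.parent = v
        return v if v.children else None

    root = prune(out.root)
    if root is None:
        raise ValueError("restriction to an empty leaf set")
    root.parent = None
    out.root = root
    return out.canonicalize()


def tree_from_clusters(leaf_labels: Iterable[str],
                       clusters: Iterable[frozenset[str]]) -> Tree:
    """Build the (possibly multifurcating) tree whose internal bipartitions
    are exactly the given pairwise-compatible clusters over ``leaf_labels``."""
    labels = sorted(set(leaf_labels))
    full = frozenset(labels)
    nontrivial = {frozenset(c) for c in clusters
                  if 2 <= len(c) <= len(labels) - 1 and frozenset(c) != full}
    # nest clusters: parent of each node is the smallest strict superset
    nodes: dict[frozenset[str], Node] = {full: Node()}
    order = sorted(nontrivial, key=len, reverse=True)
    for c in order:
        nodes[c] = Node()
    for c in order:
        parent = full
        for d in order:
            if len(d) <= len(c):
                break
            if c < d and len(d) < len(parent):
                parent = d
        if not (c <= parent):
            raise ValueError("clusters are not pairwise compatible")
        nodes[parent].add(nodes[c])
    for lab in labels:
        parent = full
        for d in order:
            if lab in d and len(d) < len(parent):
                parent = d
        nodes[parent].add(Node(label=lab))
    return Tree(nodes[full]).canonicalize()


# ---------------------------------------------------------------------------
# gene tree collections
# ---------------------------------------------------------------------------

class GeneTreeCollection:
    """A set of k gene trees over a shared taxon set L.

    Each tree may cover only a subset of L; the union of leaf sets must
    equal L.
    """

    def __init__(self, trees: Sequence[Tree],
                 taxon_set: TaxonSet | None = None):
        if not trees:
            raise ValueError("at least one gene tree required")
        self.trees = list(trees)
        union: set[str] = set()
        for t in self.trees:
            union |= t.leaf_labels()
        if taxon_set is None:
            taxon_set = TaxonSet(sorted(union))
        else:
            extra = union - set(taxon_set.labels)
            if extra:
                raise ValueError(f"gene tree taxa outside L: {sorted(extra)}")
        self.taxon_set = taxon_set

    @classmethod
    def from_string(cls, text: str,
                    taxon_set: TaxonSet | None = None) -> "GeneTreeCollection":
        return cls(parse_newick_collection(text), taxon_set)

    @classmethod
    def from_file(cls, path,
                  taxon_set: TaxonSet | None = None) -> "GeneTreeCollection":
        with open(path) as fh:
            return cls.from_string(fh.read(), taxon_set)

    @property
    def k(self) -> int:
        return len(self.trees)

    @property
    def n(self) -> int:
        return self.taxon_set.n

    def leaf_masks(self) -> list[int]:
        ts = self.taxon_set
        return [ts.mask_of(t.leaf_labels()) for t in self.trees]

    def __iter__(self) -> Iterator[Tree]:
        return iter(self.trees)

    def __len__(self) -> int:
        return len(self.trees)
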