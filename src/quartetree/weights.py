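"""Quartet-weight engine: unique partitions, polytree memoization, QI.

The score optimized by the package is the number of quartet topologies a
candidate species tree shares with the input gene trees.  The engine here
computes, for any tripartition query T = (A|B|C) of the taxon set, the
contribution w(T) of T to that score, summed over every internal node of
every gene tree.  Three ideas keep this fast:

* identical internal nodes across gene trees are collapsed into a table of
  unique partitions with multiplicities (E, with total degree D);
* the per-node quartet-intersection count QI(T, M) is evaluated in Theta(d)
  for a node of degree d via precomputed S-sums, instead of the naive
  Theta(d^3) triple sum (kept here as the reference oracle);
* the unique clusters of all gene trees form a polytree (a DAG with one
  chosen child set per cluster), so all |W n A| intersection cardinalities
  are filled in one bottom-up pass with at most D additions.

All weights are carried as *doubled* integers (sums of multiplicity x QI;
QI itself is twice a quartet count), so arithmetic is exact; the reported
w(T) is the doubled value halved.

Clusters are bitmasks over the collection's :class:`~quartetree.treeio.TaxonSet`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .treeio import GeneTreeCollection, TaxonSet, Tree, node_partitions

__all__ = [
    "Partition",
    "PartitionTable",
    "Polytree",
    "IntersectionVectors",
    "intersection_vectors",
    "qi_reference",
    "qi_fast",
    "WeightEngine",
    "build_partition_table",
    "build_polytree",
]


def popcount(mask: int) -> int:
    return mask.bit_count()


def canonical_parts(parts: Iterable[int]) -> tuple[int, ...]:
    """Parts ordered by their smallest member index (parts are disjoint, so
    lowest set bits are distinct and give a total order)."""
    return tuple(sorted(parts, key=lambda m: m & -m))


@dataclass(frozen=True)
class Partition:
    """The multi-way split induced by one internal gene-tree node.

    ``parts`` are >= 3 pairwise-disjoint nonempty clusters whose union is the
    owning tree's leaf set ``lg``.
    """
    parts: tuple[int, ...]
    lg: int

    def __post_init__(self):
        object.__setattr__(self, "parts", canonical_parts(self.parts))

    @property
    def degree(self) -> int:
        return len(self.parts)


class _Record:
    """Unique-partition table entry plus its polytree wiring.

    ``children`` holds the d-1 parts that are proper subtrees in the chosen
    rooting; the remaining part is ``lg`` minus their union.
    """
    __slots__ = ("parts", "lg", "mult", "children")

    def __init__(self, parts: tuple[int, ...], lg: int,
                 children: tuple[int, ...]):
        self.parts = parts
        self.lg = lg
        self.mult = 1
        self.children = children


class PartitionTable:
    """Map from canonical partition to multiplicity over a gene tree set."""

    def __init__(self, taxon_set: TaxonSet):
        self.taxon_set = taxon_set
        self._records: dict[tuple[int, ...], _Record] = {}
        self.total_nodes = 0

    def add(self, parts: Sequence[int], lg: int,
            children: Sequence[int]) -> None:
        key = canonical_parts(parts)
        rec = self._records.get(key)
        if rec is None:
            self._records[key] = _Record(key, lg, tuple(children))
        else:
            rec.mult += 1
        self.total_nodes += 1

    @property
    def records(self):
        return self._records.values()

    def __len__(self) -> int:
        return len(self._records)

    def multiplicity(self, parts: Sequence[int]) -> int:
        rec = self._records.get(canonical_parts(parts))
        return rec.mult if rec is not None else 0

    @property
    def D(self) -> int:
        """Sum of degrees over unique partitions."""
        return sum(len(r.parts) for r in self._records.values())

    def items(self):
        """(Partition, multiplicity) pairs."""
        for rec in self._records.values():
            yield Partition(rec.parts, rec.lg), rec.mult

    def dump(self) -> str:
        """Tab-separated text: one unique partition per line."""
        ts = self.taxon_set
        lines = []
        for rec in sorted(self._records.values(),
                          key=lambda r: (-r.mult, r.parts)):
            parts_txt = " | ".join(
                ",".join(ts.labels_of(p)) for p in rec.parts)
            lines.append(f"{rec.mult}\t{len(rec.parts)}\t{parts_txt}")
        return "\n".join(lines)


def _rooted_node_clusters(tree: Tree, ts: TaxonSet):
    """Clusters of ``tree`` re-rooted at its reference taxon.

    The reference taxon is the lexicographically smallest leaf present, so
    identical subtrees across gene trees map to identical clusters and the
    polytree shares as many vertices as possible.

    Returns ``(cluster, children_clusters)`` for every node on the side away
    from the reference leaf, in post-order; singleton clusters have no
    children.
    """
    ref_label = min(tree.leaf_labels())
    # adjacency over the rooted representation
    ref_leaf = next(v for v in tree.postorder()
                    if v.is_leaf and v.label == ref_label)
    start = ref_leaf.parent
    if start is None:  # single-leaf tree
        return
    out = []

    def neighbors(v):
        if v.parent is not None:
            yield v.parent
        yield from v.children

    # iterative post-order DFS from `start`, not crossing back to ref_leaf
    stack = [(start, ref_leaf, False)]
    cluster: dict[int, int] = {}
    while stack:
        v, came_from, expanded = stack.pop()
        kids = [w for w in neighbors(v) if w is not came_from]
        if expanded or not kids:
            if not kids:  # leaf
                cluster[id(v)] = 1 << ts.index[v.label]
                out.append((cluster[id(v)], ()))
            else:
                ch = tuple(cluster[id(w)] for w in kids)
                m = 0
                for c in ch:
                    m |= c
                cluster[id(v)] = m
                out.append((m, ch))
        else:
            stack.append((v, came_from, True))
            for w in kids:
                stack.append((w, v, False))
    return out


def build_partition_table(G: GeneTreeCollection) -> PartitionTable:
    """Collapse identical internal nodes across gene trees into unique
    partitions with multiplicities."""
    ts = G.taxon_set
    table = PartitionTable(ts)
    for tree in G:
        lg = ts.mask_of(tree.leaf_labels())
        nodes = _rooted_node_clusters(tree, ts) or []
        for cluster_mask, children in nodes:
            if not children:
                continue
            # unrooted degree = #children + 1 (edge toward reference taxon)
            if len(children) < 2:
                continue
            remainder = lg & ~cluster_mask
            parts = list(children)
            if remainder:
                parts.append(remainder)
            if len(parts) >= 3:
                table.add(parts, lg, children)
    return table


class Polytree:
    """DAG of the unique gene-tree clusters with one chosen child set each.

    Vertices are clusters observed in the consistently rooted gene trees;
    for a cluster seen with different resolutions in different trees one
    child set is chosen arbitrarily (first seen).  A bottom-up pass over the
    topological order computes every |W n A| with at most D additions.
    """

    def __init__(self, taxon_set: TaxonSet):
        self.taxon_set = taxon_set
        self.children: dict[int, tuple[int, ...]] = {}
        self._order: list[int] | None = None

    def add_vertex(self, cluster: int, children: Sequence[int]) -> None:
        if cluster not in self.children:
            self.children[cluster] = tuple(children)
            self._order = None
        for c in children:
            if c not in self.children:
                self.children[c] = ()
                self._order = None

    @property
    def n_vertices(self) -> int:
        return len(self.children)

    @property
    def n_edges(self) -> int:
        return sum(len(c) for c in self.children.values())

    @property
    def topological_order(self) -> list[int]:
        if self._order is None:
            # children are strict subsets, so popcount is a topological key
            self._order = sorted(self.children, key=popcount)
        return self._order

    def intersection_sizes(self, a: int, b: int, c: int
                           ) -> dict[int, tuple[int, int, int]]:
        """|W n A|, |W n B|, |W n C| for every vertex W, via the recursive
        children sums (single bottom-up pass)."""
        memo: dict[int, tuple[int, int, int]] = {}
        for w in self.topological_order:
            ch = self.children[w]
            if not ch:
                memo[w] = (popcount(w & a), popcount(w & b), popcount(w & c))
            else:
                ia = ib = ic = 0
                for z in ch:
                    za, zb, zc = memo[z]
                    ia += za
                    ib += zb
                    ic += zc
                memo[w] = (ia, ib, ic)
        return memo


def build_polytree(table: PartitionTable,
                   G: GeneTreeCollection | None = None) -> Polytree:
    """Assemble the polytree from the chosen rootings recorded in the table.

    Every internal cluster appears as the union of some record's children
    (the record of the node that owns it), which supplies its chosen child
    set; clusters only ever seen as children of others are leaves or get
    their child set from their own record.  First-seen resolutions win.
    """
    pt = Polytree(table.taxon_set)
    for rec in table.records:
        m = 0
        for child in rec.children:
            m |= child
        if m not in pt.children:
            pt.children[m] = rec.children
    for rec in table.records:
        for child in rec.children:
            if child not in pt.children:
                pt.children[child] = ()
    pt._order = None
    return pt


# ---------------------------------------------------------------------------
# QI: shared quartet topologies between a tripartition and a partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntersectionVectors:
    """Per-part intersection cardinalities of a triple (A, B, C) with the
    parts of a partition M, plus their sums and cross sums."""
    a: tuple[int, ...]
    b: tuple[int, ...]
    c: tuple[int, ...]
    sa: int
    sb: int
    sc: int
    sab: int
    sac: int
    sbc: int

    @classmethod
    def from_counts(cls, a: Sequence[int], b: Sequence[int],
                    c: Sequence[int]) -> "IntersectionVectors":
        return cls(tuple(a), tuple(b), tuple(c),
                   sum(a), sum(b), sum(c),
                   sum(x * y for x, y in zip(a, b)),
                   sum(x * y for x, y in zip(a, c)),
                   sum(x * y for x, y in zip(b, c)))


def intersection_vectors(triple: tuple[int, int, int],
                         parts: Sequence[int]) -> IntersectionVectors:
    A, B, C = triple
    a = [popcount(A & m) for m in parts]
    b = [popcount(B & m) for m in parts]
    c = [popcount(C & m) for m in parts]
    return IntersectionVectors.from_counts(a, b, c)


def qi_reference(triple: tuple[int, int, int],
                 parts: Sequence[int]) -> int:
    """Cubic-time triple sum over ordered distinct (i, j, k): the reference
    oracle for QI.  Exact integer arithmetic (terms are summed doubled and
    halved at the end)."""
    iv = intersection_vectors(triple, parts)
    d = len(parts)
    total2 = 0
    for i in range(d):
        ai = iv.a[i]
        if not ai:
            continue
        for j in range(d):
            if j == i:
                continue
            bj = iv.b[j]
            if not bj:
                continue
            for k in range(d):
                if k == i or k == j:
                    continue
                ck = iv.c[k]
                if ck:
                    total2 += ai * bj * ck * (ai + bj + ck - 3)
    assert total2 % 2 == 0
    return total2 // 2


def _choose2(x: int) -> int:
    return x * (x - 1) // 2


def qi_fast(iv: IntersectionVectors) -> int:
    """Theta(d) evaluation of QI via the S-sum identity; exactly equal to
    :func:`qi_reference` on every input."""
    total = 0
    a, b, c = iv.a, iv.b, iv.c
    sa, sb, sc = iv.sa, iv.sb, iv.sc
    sab, sac, sbc = iv.sab, iv.sac, iv.sbc
    for i in range(len(a)):
        ai, bi, ci = a[i], b[i], c[i]
        if ai >= 2:
            total += _choose2(ai) * ((sb - bi) * (sc - ci) - sbc + bi * ci)
        if bi >= 2:
            total += _choose2(bi) * ((sa - ai) * (sc - ci) - sac + ai * ci)
        if ci >= 2:
            total += _choose2(ci) * ((sa - ai) * (sb - bi) - sab + ai * bi)
    return total


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

class WeightEngine:
    """Scores tripartition queries against a gene tree collection.

    ``weight2(A, B, C)`` returns the doubled weight (sum over unique
    partitions of multiplicity x QI); ``weight`` halves it.  Triples with
    overlapping or repeated parts are allowed (they arise in upper-bound
    computations).
    """

    def __init__(self, G: GeneTreeCollection):
        self.G = G
        self.taxon_set = G.taxon_set
        self.table = build_partition_table(G)
        self.polytree = build_polytree(self.table)

    @property
    def D(self) -> int:
        return self.table.D

    def weight2(self, A: int, B: int, C: int) -> int:
        memo = self.polytree.intersection_sizes(A, B, C)
        total = 0
        lg_cache: dict[int, tuple[int, int, int]] = {}
        for rec in self.table.records:
            lg = rec.lg
            tot = lg_cache.get(lg)
            if tot is None:
                tot = (popcount(A & lg), popcount(B & lg), popcount(C & lg))
                lg_cache[lg] = tot
            a = []
            b = []
            c = []
            ra, rb, rc = tot
            for z in rec.children:
                za, zb, zc = memo[z]
                a.append(za)
                b.append(zb)
                c.append(zc)
                ra -= za
                rb -= zb
                rc -= zc
            if len(rec.parts) > len(rec.children):
                a.append(ra)
                b.append(rb)
                c.append(rc)
            qi = qi_fast(IntersectionVectors.from_counts(a, b, c))
            if qi:
                total += rec.mult * qi
        return total

    def weight(self, A: int, B: int, C: int) -> float:
        """w(T): half the multiplicity-weighted QI sum (a multiple of 1/2)."""
        return self.weight2(A, B, C) / 2.0

    # -- species tree scoring ---------------------------------------------
    def tree_score2(self, t: Tree) -> int:
        """Doubled quartet score of a binary species tree on L: twice the
        total number of quartet topologies shared with the gene trees."""
        ts = self.taxon_set
        if t.leaf_labels() != set(ts.labels):
            raise ValueError("species tree must cover the full taxon set")
        if not t.is_binary():
            raise ValueError("scoring requires a binary species tree")
        total = 0
        for parts in node_partitions(t):
            masks = [ts.mask_of(p) for p in parts]
            if len(masks) != 3:
                raise ValueError("scoring requires a binary species tree")
            total += self.weight2(*masks)
        return total

    def tree_score(self, t: Tree) -> int:
        """Quartet score: sum over gene trees of shared quartet topologies."""
        s2 = self.tree_score2(t)
        assert s2 % 2 == 0
        return s2 // 2
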