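"""Construction of the constraint cluster set X and the search space Y.

The dynamic program only considers species-tree clades drawn from a
constraint set X of clusters, closed under complement.  X is seeded with
every cluster induced by a gene-tree bipartition (sufficient for statistical
consistency) and then enlarged by consensus-based heuristics whose total
additions are bounded so that |X| = O(nk):

* up to a fixed number of rounds (default 110), a greedy consensus of the
  gene trees is built with randomized tie-breaking and each of its
  polytomies is resolved three ways -- by a UPGMA-like tree over the
  polytomy sides, by a greedy consensus of gene trees subsampled to one
  taxon per side, and (under a quadratic budget sum d_i^2 <= c*n over the
  ascending-degree prefix) by caterpillar trees ordered by similarity;
* polytomies inside the gene trees themselves are resolved against a
  UPGMA guide tree, three random one-taxon-per-side samples each.

The pairwise similarity used everywhere counts, for taxa u and v, the
gene-tree quartets resolved as uv|xy; unresolved quartets contribute
nothing, so polytomies never inflate similarity.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .treeio import (
    GeneTreeCollection,
    TaxonSet,
    Tree,
    bipartition_clusters,
    bits,
    node_partitions,
    restrict,
    tree_from_clusters,
)
from .weights import popcount

__all__ = [
    "SimilarityMatrix",
    "ConstraintSet",
    "SearchSpaceConfig",
    "build_similarity_matrix",
    "upgma_like_tree",
    "greedy_consensus",
    "resolve_consensus_polytomies",
    "gene_polytomy_resolutions",
    "quadratic_budget_prefix",
    "merge_extra_bipartitions",
    "build_constraint_set",
    "enumerate_resolutions",
    "count_tripartitions",
    "KANE_TAO_EXPONENT",
]

#: Theoretical cap on log|Y| / log|X| for complement-closed cluster sets.
KANE_TAO_EXPONENT = 3.0 / math.log(27.0 / 4.0, 3.0)


@dataclass
class SearchSpaceConfig:
    """Knobs bounding the growth of the constraint set.

    rounds:            cap on consensus rounds (keeps |X| = O(nk)).
    poly_budget_c:     constant c of the quadratic caterpillar budget c*n.
    guide_repeats:     random one-per-side samples per gene-tree polytomy.
    early_stop:        a round adding fewer new clusters than this stops
                       the loop.
    seed:              all randomness (tie-breaks, taxon samples).
    """
    rounds: int = 110
    poly_budget_c: float = 25.0
    guide_repeats: int = 3
    early_stop: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.poly_budget_c <= 0:
            raise ValueError("poly_budget_c must be positive")
        if self.guide_repeats < 1:
            raise ValueError("guide_repeats must be >= 1")


class SimilarityMatrix:
    """Symmetric nonnegative quartet-support counts between taxon pairs."""

    def __init__(self, taxon_set: TaxonSet, counts: np.ndarray):
        self.taxon_set = taxon_set
        self.counts = counts

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.counts[i, j])

    def group_linkage(self, a: Iterable[int], b: Iterable[int]) -> float:
        """Mean similarity over all cross pairs of two taxon-index groups."""
        a = list(a)
        b = list(b)
        return float(self.counts[np.ix_(a, b)].sum()) / (len(a) * len(b))


def build_similarity_matrix(G: GeneTreeCollection) -> SimilarityMatrix:
    """Entry (u, v) = number of gene-tree quartets resolved as uv|xy.

    Computed per tree by inclusion-exclusion over edges and internal nodes:
    a resolved quartet's central path has one more edge than interior node,
    so summing separated-pair counts over edges and subtracting the
    same-part/other-part counts over internal nodes counts each resolved
    quartet exactly once.  Unresolved (star) quartets have an empty central
    path and contribute nothing.
    """
    ts = G.taxon_set
    n = ts.n
    S = np.zeros((n, n), dtype=np.int64)
    for tree in G:
        parts_list = node_partitions(tree)
        lg = sorted(tree.leaf_labels())
        lg_idx = np.array([ts.index[x] for x in lg])
        m = len(lg)
        # edge term: every cluster below a non-root node splits L_g
        from .treeio import _subtree_sets  # local helper reuse
        below = _subtree_sets(tree)
        for v in tree.postorder():
            if v is tree.root:
                continue
            side = [ts.index[x] for x in below[v]]
            size = len(side)
            other = m - size
            if size >= 2 and other >= 2:
                rest = [i for i in lg_idx if i not in set(side)]
                S[np.ix_(side, side)] += other * (other - 1) // 2
                S[np.ix_(rest, rest)] += size * (size - 1) // 2
        # node term: pairs within one part vs pairs within another part
        for parts in parts_list:
            sizes = [len(p) for p in parts]
            c2 = [s * (s - 1) // 2 for s in sizes]
            tot_c2 = sum(c2)
            for p, own in zip(parts, c2):
                idx = [ts.index[x] for x in p]
                if len(idx) >= 2:
                    S[np.ix_(idx, idx)] -= tot_c2 - own
    np.fill_diagonal(S, 0)
    return SimilarityMatrix(ts, S)


def upgma_like_tree(S: SimilarityMatrix, items: Sequence[int]
                    ) -> tuple[Tree, list[int]]:
    """Agglomerate disjoint clusters by maximum average similarity.

    ``items`` are bitmasks over the taxon set.  Returns a rooted binary tree
    over the items (leaves labeled by each item's smallest-index taxon, so
    with singleton items this is a proper guide tree over taxa) and the list
    of union masks created at internal nodes, in merge order.
    """
    if len(items) < 2:
        raise ValueError("UPGMA needs at least 2 items")
    ts = S.taxon_set
    from .treeio import Node
    groups = []
    for mask in items:
        idx = list(bits(mask))
        node = Node(label=ts.labels[idx[0]]) if len(idx) == 1 else Node()
        if len(idx) > 1:
            for i in idx:
                node.add(Node(label=ts.labels[i]))
        groups.append({"mask": mask, "idx": idx, "node": node})
    unions: list[int] = []
    while len(groups) > 1:
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                link = S.group_linkage(groups[i]["idx"], groups[j]["idx"])
                key = (-link, groups[i]["mask"] & -groups[i]["mask"],
                       groups[j]["mask"] & -groups[j]["mask"])
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        gi, gj = groups[i], groups[j]
        parent = Node()
        parent.add(gi["node"])
        parent.add(gj["node"])
        merged = {"mask": gi["mask"] | gj["mask"],
                  "idx": gi["idx"] + gj["idx"], "node": parent}
        unions.append(merged["mask"])
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(merged)
    return Tree(groups[0]["node"]), unions


def greedy_consensus(trees: Sequence[Tree], rng: random.Random | int = 0,
                     ) -> Tree:
    """Greedy (extended majority) consensus over a common leaf set.

    Bipartitions are added in decreasing frequency, ties broken at random,
    skipping any bipartition incompatible with those already accepted.
    """
    if isinstance(rng, int):
        rng = random.Random(rng)
    leaf_sets = {t.leaf_labels() for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("greedy consensus requires a common leaf set")
    labels = sorted(next(iter(leaf_sets)))
    full = frozenset(labels)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for c in bipartition_clusters(t):
            counts[c] = counts.get(c, 0) + 1
    ranked = sorted(counts, key=lambda c: (-counts[c], rng.random()))
    accepted: list[frozenset[str]] = []
    for c in ranked:
        ok = True
        for d in accepted:
            if not (c <= d or d <= c or not (c & d) or c | d == full):
                ok = False
                break
        if ok:
            accepted.append(c)
    return tree_from_clusters(labels, accepted)


class ConstraintSet:
    """A complement-closed set of clusters (bitmasks) over the taxon set."""

    def __init__(self, taxon_set: TaxonSet):
        self.taxon_set = taxon_set
        self.full_mask = taxon_set.full_mask
        self._set: set[int] = set()
        self.round_log: list[int] = []
        for i in range(taxon_set.n):
            self.add(1 << i)
        self.add(self.full_mask)

    def add(self, mask: int) -> bool:
        """Insert a cluster and its complement; True if the cluster is new."""
        if mask == 0:
            return False
        new = mask not in self._set
        self._set.add(mask)
        comp = self.full_mask & ~mask
        if comp:
            self._set.add(comp)
        return new

    def __contains__(self, mask: int) -> bool:
        return mask in self._set

    def __len__(self) -> int:
        return len(self._set)

    def __iter__(self):
        return iter(self._set)

    def clusters_by_size(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for m in self._set:
            out.setdefault(popcount(m), []).append(m)
        for v in out.values():
            v.sort(key=lambda m: (m & -m, m))
        return out

    def dump(self) -> str:
        ts = self.taxon_set
        rows = sorted(self._set, key=lambda m: (popcount(m), m))
        return "\n".join(",".join(ts.labels_of(m)) for m in rows)


def _polytomy_partitions(tree: Tree, min_parts: int = 4):
    return [p for p in node_partitions(tree) if len(p) >= min_parts]


def quadratic_budget_prefix(degrees: Sequence[int], c: float, n: int) -> int:
    """Largest prefix length q of the ascending-sorted degrees whose squares
    sum to at most c*n (the eligibility rule for the quadratic caterpillar
    resolution).  The stated rule reads "smallest q with the sum <= c*n",
    but the prefix sum grows with q; the largest such q is the reading that
    bounds, rather than voids, the technique."""
    acc = 0.0
    q = 0
    for d in sorted(degrees):
        if acc + d * d > c * n:
            break
        acc += d * d
        q += 1
    return q


def resolve_consensus_polytomies(consensus: Tree, S: SimilarityMatrix,
                                 G: GeneTreeCollection,
                                 cfg: SearchSpaceConfig, X: ConstraintSet,
                                 rng: random.Random) -> int:
    """Resolve every polytomy of a consensus tree three ways, adding the
    implied clusters to X; the quadratic caterpillar technique is limited to
    the ascending-degree prefix of polytomies fitting the c*n budget."""
    ts = X.taxon_set
    polys = _polytomy_partitions(consensus)
    if not polys:
        return 0
    ranked = sorted(range(len(polys)), key=lambda i: len(polys[i]))
    q = quadratic_budget_prefix([len(p) for p in polys],
                                cfg.poly_budget_c, ts.n)
    eligible = set(ranked[:q])

    added = 0
    for idx, parts in enumerate(polys):
        side_masks = [ts.mask_of(p) for p in parts]
        # technique 1: UPGMA over the polytomy sides
        _, unions = upgma_like_tree(S, side_masks)
        for m in unions[:-1]:  # final union is the whole polytomy
            added += X.add(m)
        # one random taxon per side, shared by techniques 2 and 3
        sampled = [sorted(p)[rng.randrange(len(p))] for p in parts]
        side_of = {s: m for s, m in zip(sampled, side_masks)}
        # technique 2: greedy consensus of gene trees restricted to the sample
        sample_set = set(sampled)
        sub = [restrict(t, sample_set) for t in G
               if sample_set <= t.leaf_labels()]
        if sub:
            cons = greedy_consensus(sub, rng)
            for c in bipartition_clusters(cons):
                m = 0
                for s in c:
                    m |= side_of[s]
                added += X.add(m)
        # technique 3: caterpillars by decreasing similarity to each sample
        if idx in eligible:
            for s in sampled:
                si = ts.index[s]
                others = sorted(
                    (t for t in sampled if t != s),
                    key=lambda t: (-S[si, ts.index[t]], ts.index[t]))
                prefix = side_of[s]
                for t in others[:-1]:
                    prefix |= side_of[t]
                    added += X.add(prefix)
    return added


def gene_polytomy_resolutions(G: GeneTreeCollection, guide: Tree,
                              cfg: SearchSpaceConfig, X: ConstraintSet,
                              rng: random.Random) -> int:
    """Resolve polytomies inside gene trees against a binary guide tree.

    For each polytomy, one taxon is sampled per side; the guide restricted
    to the sample is mapped back by replacing each sampled taxon with its
    whole side.  Repeated ``cfg.guide_repeats`` times with fresh samples.
    """
    ts = X.taxon_set
    added = 0
    for tree in G:
        for parts in _polytomy_partitions(tree):
            side_masks = [ts.mask_of(p) for p in parts]
            for _ in range(cfg.guide_repeats):
                sampled = [sorted(p)[rng.randrange(len(p))] for p in parts]
                side_of = {s: m for s, m in zip(sampled, side_masks)}
                sub = restrict(guide, set(sampled))
                for c in bipartition_clusters(sub):
                    m = 0
                    for s in c:
                        m |= side_of[s]
                    added += X.add(m)
    return added


def build_constraint_set(G: GeneTreeCollection,
                         cfg: SearchSpaceConfig | None = None
                         ) -> ConstraintSet:
    """Assemble the full constraint set X for a gene tree collection."""
    cfg = cfg or SearchSpaceConfig()
    ts = G.taxon_set
    if ts.n < 4:
        raise ValueError("constraint set construction needs >= 4 taxa")
    rng = random.Random(cfg.seed)
    X = ConstraintSet(ts)
    # base set: every cluster of every gene-tree bipartition (+ complements)
    from .treeio import _subtree_sets
    any_polytomy = False
    for tree in G:
        below = _subtree_sets(tree)
        for v in tree.postorder():
            if v is tree.root:
                continue
            X.add(ts.mask_of(below[v]))
        if _polytomy_partitions(tree):
            any_polytomy = True

    S = build_similarity_matrix(G)
    if any_polytomy:
        guide, _ = upgma_like_tree(S, [1 << i for i in range(ts.n)])
        gene_polytomy_resolutions(G, guide, cfg, X, rng)

    # consensus rounds use gene trees covering the full taxon set
    complete = [t for t in G if t.leaf_labels() == set(ts.labels)]
    if complete:
        for _ in range(cfg.rounds):
            cons = greedy_consensus(complete, rng)
            added = resolve_consensus_polytomies(cons, S, G, cfg, X, rng)
            X.round_log.append(added)
            if added < cfg.early_stop:
                break
    _ensure_resolvable(X)
    return X


def merge_extra_bipartitions(X: ConstraintSet, trees: Iterable[Tree]) -> int:
    """Merge the bipartition clusters of user-supplied trees into X
    (with complements), then re-complete; returns the number added."""
    ts = X.taxon_set
    added = 0
    for t in trees:
        extra = t.leaf_labels() - set(ts.labels)
        if extra:
            raise ValueError(f"extra-bipartition taxa outside L: "
                             f"{sorted(extra)}")
        for c in bipartition_clusters(t):
            added += X.add(ts.mask_of(c))
    _ensure_resolvable(X)
    return added


def _has_resolution(a: int, X: ConstraintSet,
                    by_size: dict[int, list[int]]) -> bool:
    size = popcount(a)
    for s in range(1, size // 2 + 1):
        for ap in by_size.get(s, ()):
            if not (ap & ~a) and (a & ~ap) in X:
                return True
    return False


def _ensure_resolvable(X: ConstraintSet) -> int:
    """Complete X so every cluster of size >= 2 has a resolution within X.

    Clusters harvested from gene trees with missing taxa (or their
    complements) need not decompose into smaller members of X; for each
    such cluster the smallest-member split is inserted, iterating to a
    fixpoint.  This adds at most one chain per offending cluster and keeps
    the dynamic program total (it errors on unresolvable clusters).
    """
    added = 0
    changed = True
    while changed:
        changed = False
        by_size = X.clusters_by_size()
        for size in sorted(by_size):
            if size < 2:
                continue
            for a in by_size[size]:
                if not _has_resolution(a, X, by_size):
                    rest = a ^ (a & -a)
                    if X.add(rest):
                        added += 1
                    changed = True
    return added


def enumerate_resolutions(A: int, X: ConstraintSet,
                          _by_size: dict[int, list[int]] | None = None
                          ) -> list[tuple[int, int]]:
    """All unordered pairs (A', A - A') with both halves in X.

    Deterministic order: by smallest-member index of the smaller half.
    """
    if A not in X:
        raise ValueError("cluster A must be a member of X")
    size = popcount(A)
    if size < 2:
        raise ValueError("cluster A must have at least 2 taxa")
    by_size = _by_size if _by_size is not None else X.clusters_by_size()
    lowbit = A & -A
    out: list[tuple[int, int]] = []
    for s in range(1, size // 2 + 1):
        for ap in by_size.get(s, ()):
            if ap & ~A:
                continue
            comp = A & ~ap
            if comp in X:
                if 2 * s == size and not (ap & lowbit):
                    continue  # equal halves: keep the one holding A's anchor
                out.append((ap, comp))
    def _key(pr):
        small = pr[0] if (popcount(pr[0]), pr[0]) <= (popcount(pr[1]), pr[1]) \
            else pr[1]
        return ((small & -small).bit_length(), small)
    out.sort(key=_key)
    return out


def count_tripartitions(X: ConstraintSet) -> int:
    """|Y|: total resolutions over all clusters of X (always within the
    theoretical |X|^1.726 cap)."""
    by_size = X.clusters_by_size()
    total = 0
    for m in X:
        if popcount(m) >= 2:
            total += len(enumerate_resolutions(m, X, _by_size=by_size))
    return total
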