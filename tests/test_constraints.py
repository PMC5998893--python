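"""Similarity matrix, consensus/UPGMA machinery, and constraint set X."""

import itertools
import math
import random

import numpy as np
import pytest

from quartetree.constraints import (
    KANE_TAO_EXPONENT,
    ConstraintSet,
    SearchSpaceConfig,
    build_constraint_set,
    build_similarity_matrix,
    count_tripartitions,
    enumerate_resolutions,
    gene_polytomy_resolutions,
    greedy_consensus,
    quadratic_budget_prefix,
    resolve_consensus_polytomies,
    upgma_like_tree,
)
from quartetree.treeio import (
    GeneTreeCollection,
    TaxonSet,
    bipartition_clusters,
    induced_quartet,
    parse_newick,
)
from quartetree.weights import popcount
from conftest import random_collection


def brute_similarity(G):
    """O(n^4) per-tree oracle: count resolved quartets uv|xy per pair."""
    ts = G.taxon_set
    S = np.zeros((ts.n, ts.n), dtype=int)
    for t in G:
        leaves = sorted(t.leaf_labels())
        for four in itertools.combinations(leaves, 4):
            q = induced_quartet(t, four)
            if q is None:
                continue
            for pair in q:
                u, v = sorted(pair)
                S[ts.index[u], ts.index[v]] += 1
                S[ts.index[v], ts.index[u]] += 1
    return S


class TestSimilarity:
    def test_star_contributes_nothing(self):
        G = GeneTreeCollection([parse_newick("(a,b,c,d,e);")])
        assert build_similarity_matrix(G).counts.sum() == 0

    def test_single_quartet_tree(self):
        G = GeneTreeCollection([parse_newick("((a,b),(c,d));")])
        S = build_similarity_matrix(G)
        ts = G.taxon_set
        assert S[ts.index["a"], ts.index["b"]] == 1
        assert S[ts.index["a"], ts.index["c"]] == 0

    def test_duplication_doubles_entries(self, rng):
        G1 = random_collection([f"x{i}" for i in range(6)], 3, rng,
                               multifurcating=True)
        G2 = GeneTreeCollection(list(G1) + [t.copy() for t in G1])
        assert (build_similarity_matrix(G2).counts
                == 2 * build_similarity_matrix(G1).counts).all()

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(6):
            G = random_collection([f"x{i}" for i in range(7)],
                                  rng.randrange(2, 5), rng,
                                  multifurcating=True, incomplete=True)
            S = build_similarity_matrix(G)
            assert (S.counts == brute_similarity(G)).all()
            assert (S.counts == S.counts.T).all()
            assert (np.diag(S.counts) == 0).all()


class TestUpgma:
    def test_most_similar_pair_merges_first(self):
        ts = TaxonSet(["a", "b", "c"])
        counts = np.array([[0, 9, 1], [9, 0, 1], [1, 1, 0]])
        from quartetree.constraints import SimilarityMatrix
        tree, unions = upgma_like_tree(SimilarityMatrix(ts, counts),
                                       [1, 2, 4])
        assert unions[0] == 0b011  # {a, b} first
        assert bipartition_clusters(tree) == set()  # 3-taxon tree

    def test_unequal_group_linkage_is_mean_over_cross_pairs(self):
        ts = TaxonSet(list("abcde"))
        counts = np.zeros((5, 5), int)
        # group {a,b} vs {c,d,e}: mean of 6 cross pairs
        for (i, j, v) in [(0, 2, 6), (0, 3, 0), (0, 4, 0),
                          (1, 2, 0), (1, 3, 0), (1, 4, 6)]:
            counts[i, j] = counts[j, i] = v
        from quartetree.constraints import SimilarityMatrix
        S = SimilarityMatrix(ts, counts)
        assert S.group_linkage([0, 1], [2, 3, 4]) == pytest.approx(2.0)

    def test_all_equal_similarity_is_deterministic(self):
        ts = TaxonSet(list("abcd"))
        from quartetree.constraints import SimilarityMatrix
        S = SimilarityMatrix(ts, np.ones((4, 4), int))
        r1 = upgma_like_tree(S, [1, 2, 4, 8])
        r2 = upgma_like_tree(S, [1, 2, 4, 8])
        assert r1[1] == r2[1]


class TestGreedyConsensus:
    def test_identical_trees_return_that_tree(self):
        t = parse_newick("((a,b),(c,(d,e)));")
        cons = greedy_consensus([t.copy() for _ in range(3)], 0)
        assert bipartition_clusters(cons) == bipartition_clusters(t)

    def test_majority_bipartition_beats_minority(self):
        trees = [parse_newick("((a,b),c,d,e);"),
                 parse_newick("((a,b),c,d,e);"),
                 parse_newick("((a,c),b,d,e);")]
        cons = greedy_consensus(trees, 0)
        bips = bipartition_clusters(cons)
        assert frozenset("cde") in bips or frozenset("ab") in bips
        assert len(bips) == 1

    def test_total_conflict_keeps_one_side_of_the_tie(self):
        trees = [parse_newick("((a,b),(c,d));"),
                 parse_newick("((a,c),(b,d));")]
        cons = greedy_consensus(trees, 0)
        assert len(bipartition_clusters(cons)) <= 1


class TestBudget:
    @pytest.mark.parametrize("degrees,n,c,expected_q", [
        ([3, 4, 10], 10, 25, 3),   # prefix sums 9, 25, 125 <= 250
        ([5, 20], 10, 25, 1),      # 25 <= 250 but 425 > 250
        ([], 10, 25, 0),
        ([16], 10, 25, 0),         # 256 > 250 immediately
    ])
    def test_prefix_arithmetic(self, degrees, n, c, expected_q):
        assert quadratic_budget_prefix(degrees, c, n) == expected_q


class TestConstraintSet:
    def test_closure_after_every_insertion(self, rng):
        ts = TaxonSet([f"x{i}" for i in range(8)])
        X = ConstraintSet(ts)
        for _ in range(50):
            X.add(rng.randrange(1, ts.full_mask))
            for m in X:
                comp = ts.full_mask & ~m
                assert comp == 0 or comp in X

    def test_contains_singletons_and_l(self):
        ts = TaxonSet(list("abcd"))
        X = ConstraintSet(ts)
        assert all((1 << i) in X for i in range(4))
        assert ts.full_mask in X
        assert 0 not in X


class TestBuildConstraintSet:
    def test_four_taxon_identical_trees_exact_listing(self):
        G = GeneTreeCollection([parse_newick("((a,b),(c,d));")] * 5)
        X = build_constraint_set(G, SearchSpaceConfig(seed=0))
        assert len(X) == 11
        assert len(X.round_log) == 1  # early stop after the first round

    def test_contains_every_gene_bipartition_cluster(self, rng):
        labels = [f"x{i}" for i in range(8)]
        G = random_collection(labels, 6, rng)
        X = build_constraint_set(G, SearchSpaceConfig(seed=1))
        ts = G.taxon_set
        for t in G:
            for c in bipartition_clusters(t):
                assert ts.mask_of(c) in X

    def test_all_star_collection_still_resolvable(self):
        G = GeneTreeCollection([parse_newick("(a,b,c,d,e,f);")] * 4)
        X = build_constraint_set(G, SearchSpaceConfig(seed=0))
        # enough clusters to assemble at least one binary tree on L
        from quartetree.dp import dp_solve
        from quartetree.weights import WeightEngine
        res = dp_solve(X, WeightEngine(G))
        assert res.tree.leaf_labels() == set("abcdef")
        assert res.tree.is_binary()
        assert res.score2 == 0

    def test_deterministic_given_seed(self, rng):
        labels = [f"x{i}" for i in range(7)]
        G = random_collection(labels, 5, rng, multifurcating=True)
        X1 = build_constraint_set(G, SearchSpaceConfig(seed=7))
        X2 = build_constraint_set(G, SearchSpaceConfig(seed=7))
        assert set(X1) == set(X2)

    def test_per_round_additions_linear_in_n(self, rng):
        # generous constant: T1+T2 add O(d) each, caterpillars <= c*n
        for trial in range(3):
            labels = [f"x{i}" for i in range(12)]
            G = random_collection(labels, 8, rng, multifurcating=True)
            cfg = SearchSpaceConfig(seed=trial)
            X = build_constraint_set(G, cfg)
            bound = (cfg.poly_budget_c + 5) * len(labels)
            assert all(a <= bound for a in X.round_log)

    def test_extra_bipartitions_merged(self):
        from quartetree.constraints import merge_extra_bipartitions
        G = GeneTreeCollection([parse_newick("((a,b),(c,d));")] * 2)
        X = build_constraint_set(G, SearchSpaceConfig(seed=0))
        extra = parse_newick("((a,c),(b,d));")
        added = merge_extra_bipartitions(X, [extra])
        ts = G.taxon_set
        assert added >= 1 and ts.mask_of("ac") in X and ts.mask_of("bd") in X

    def test_too_few_taxa_rejected(self):
        G = GeneTreeCollection([parse_newick("(a,b,c);")])
        with pytest.raises(ValueError):
            build_constraint_set(G)


class TestGenePolytomyResolutions:
    def test_binary_collection_adds_nothing(self, rng):
        labels = [f"x{i}" for i in range(6)]
        G = random_collection(labels, 4, rng)
        X = ConstraintSet(G.taxon_set)
        S = build_similarity_matrix(G)
        guide, _ = upgma_like_tree(S, [1 << i for i in range(6)])
        added = gene_polytomy_resolutions(G, guide, SearchSpaceConfig(),
                                          X, random.Random(0))
        assert added == 0

    def test_degree_four_side_substitution(self):
        # gene tree polytomy with sides {a},{b},{c},{d,e}
        G = GeneTreeCollection([parse_newick("(a,b,c,(d,e));"),
                                parse_newick("((a,b),c,(d,e));")])
        ts = G.taxon_set
        X = ConstraintSet(ts)
        S = build_similarity_matrix(G)
        guide, _ = upgma_like_tree(S, [1 << i for i in range(ts.n)])
        added = gene_polytomy_resolutions(G, guide, SearchSpaceConfig(seed=0),
                                          X, random.Random(0))
        assert added >= 1
        # every added cluster is a union of polytomy sides
        sides = [ts.mask_of(s) for s in ("a", "b", "c", "de")]
        for m in X:
            if popcount(m) in (1, ts.n - 1, ts.n):
                continue  # singletons, their complements, and L: seed set
            comp = ts.full_mask & ~m
            assert _is_union_of(m, sides) or _is_union_of(comp, sides)


def _is_union_of(mask, sides):
    cover = 0
    for s in sides:
        if mask & s:
            if mask & s != s:
                return False
            cover |= s
    return cover == mask


class TestResolutionsAndY:
    def _eleven_cluster_x(self):
        G = GeneTreeCollection([parse_newick("((a,b),(c,d));")] * 2)
        return G, build_constraint_set(G, SearchSpaceConfig(seed=0))

    def test_resolutions_of_l(self):
        G, X = self._eleven_cluster_x()
        assert len(enumerate_resolutions(G.taxon_set.full_mask, X)) == 5

    def test_two_taxon_cluster_single_resolution(self):
        G, X = self._eleven_cluster_x()
        cd = G.taxon_set.mask_of("cd")
        assert enumerate_resolutions(cd, X) == [
            (G.taxon_set.mask_of("c"), G.taxon_set.mask_of("d"))]

    def test_singleton_rejected(self):
        G, X = self._eleven_cluster_x()
        with pytest.raises(ValueError):
            enumerate_resolutions(1, X)

    def test_nonmember_rejected(self):
        ts = TaxonSet(list("abcde"))
        X = ConstraintSet(ts)
        with pytest.raises(ValueError):
            enumerate_resolutions(ts.mask_of("ab"), X)

    def test_y_count_eleven_cluster_example(self):
        _, X = self._eleven_cluster_x()
        assert count_tripartitions(X) == 11

    def test_y_of_minimal_x_matches_enumeration_oracle(self):
        ts = TaxonSet(list("abcd"))
        X = ConstraintSet(ts)  # singletons + complements + L only
        oracle = 0
        members = set(X)
        for a in members:
            if popcount(a) < 2:
                continue
            seen = set()
            for ap in members:
                comp = a & ~ap
                if ap and not (ap & ~a) and comp in members and comp:
                    seen.add(frozenset((ap, comp)))
            oracle += len(seen)
        assert count_tripartitions(X) == oracle

    def test_kane_tao_bound_on_random_inputs(self, rng):
        for trial in range(4):
            labels = [f"x{i}" for i in range(9)]
            G = random_collection(labels, 6, rng, multifurcating=True)
            X = build_constraint_set(G, SearchSpaceConfig(seed=trial))
            y = count_tripartitions(X)
            assert math.log(y) / math.log(len(X)) <= KANE_TAO_EXPONENT
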