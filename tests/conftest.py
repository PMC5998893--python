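"""Shared fixtures: random tree generators used as test inputs everywhere."""

import random

import pytest

from quartetree.treeio import GeneTreeCollection, Node, Tree, contract_low_support


def random_binary_tree(labels, rng: random.Random) -> Tree:
    """Uniform-ish random unrooted binary tree by random pair joining."""
    nodes = [Node(label=lab) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        p = Node()
        p.add(nodes[i])
        p.add(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(p)
    root = Node()
    for x in nodes:
        root.add(x)
    return Tree(root).canonicalize()


def random_multifurcating_tree(labels, rng: random.Random,
                               collapse_prob: float = 0.4) -> Tree:
    """Random binary tree with each internal edge independently collapsed."""
    t = random_binary_tree(labels, rng)
    for v in list(t.postorder()):
        if not v.is_leaf and v.parent is not None:
            v.support = 0.0 if rng.random() < collapse_prob else 100.0
    return contract_low_support(t, 0.0)


def random_collection(all_labels, k: int, rng: random.Random,
                      multifurcating: bool = False,
                      incomplete: bool = False) -> GeneTreeCollection:
    """k random gene trees; optionally with polytomies and missing taxa.

    Every taxon is guaranteed to appear in at least one tree.
    """
    trees = []
    labels = list(all_labels)
    for i in range(k):
        sub = list(labels)
        if incomplete and len(labels) > 4 and rng.random() < 0.5 and i > 0:
            drop = rng.sample(labels, rng.randrange(1, len(labels) - 3))
            sub = [x for x in labels if x not in drop]
        maker = random_multifurcating_tree if (multifurcating
                                               and rng.random() < 0.7) \
            else random_binary_tree
        trees.append(maker(sub, rng))
    return GeneTreeCollection(trees)


@pytest.fixture
def rng():
    return random.Random(20260926)
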