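"""Coalescent test-data generation: Yule species trees, MSCM gene trees.

The generator emulates, at desk scale, the homogeneous birth-only design
used to benchmark quartet summary methods: species trees are drawn from a
pure-birth (Yule) process conditioned on the tip count, the total height is
redrawn from a log-normal distribution (in generations), and gene trees are
simulated under the multispecies coalescent with one haploid lineage per
species and a constant haploid effective population size Ne on every branch
(coalescent time unit = Ne generations).  Gene-tree simulation is delegated
to msprime; the Yule/height machinery and all fixture presets are local.

A support-annotated "noisy" preset perturbs true gene trees by random NNI
moves and assigns pseudo-support inversely related to the perturbation, so
branch-contraction code paths can be exercised without sequence simulation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import msprime
import numpy as np

from .treeio import (
    GeneTreeCollection,
    Node,
    Tree,
    bipartition_clusters,
    fn_rate,
    write_newick,
)

__all__ = [
    "SimulationConfig",
    "SpeciesTreeModel",
    "sample_species_tree",
    "low_ils_model",
    "sample_gene_tree_msc",
    "sample_gene_trees",
    "discordance_summary",
    "perturb_with_support",
    "make_fixture_collection",
    "PRESETS",
]


@dataclass
class SimulationConfig:
    """Study conditions for the homogeneous birth-only design.

    Defaults: 101 species, per-generation birth rate 1e-7, fixed haploid
    Ne of 400K, total tree height (generations) log-normal with mean 2.5M
    (``height_sigma_log`` is the spread of the underlying normal on the log
    scale), 1000 gene trees.
    """
    n: int = 101
    birth_rate: float = 1e-7
    ne: float = 400_000.0
    height_mean: float = 2.5e6
    height_sigma_log: float = 0.25
    k: int = 1000
    seed: int = 0
    # support-noise knobs for contraction fixtures
    nni_moves: int = 2
    support_true: tuple[float, float] = (60.0, 100.0)
    support_false: tuple[float, float] = (0.0, 40.0)

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 species")
        if self.k < 1:
            raise ValueError("need at least 1 gene tree")
        if self.birth_rate <= 0 or self.ne <= 0 or self.height_mean <= 0:
            raise ValueError("rates and sizes must be positive")


class SpeciesTreeModel:
    """Rooted ultrametric species tree; branch lengths in generations."""

    def __init__(self, tree: Tree, ne: float):
        self.tree = tree  # rooted: root has 2 children (not unrooted!)
        self.ne = ne

    @property
    def height(self) -> float:
        """Root-to-tip path length in generations (ultrametric)."""
        h = 0.0
        v = self.tree.root
        while v.children:
            v = v.children[0]
            h += v.length
        return h

    @property
    def labels(self) -> list[str]:
        return sorted(self.tree.leaf_labels())

    def newick(self) -> str:
        # full precision so ultrametricity survives the round trip
        return write_newick(self.tree, with_support=False,
                            length_format=".17g")

    def unrooted_topology(self) -> Tree:
        """The species tree as an unrooted topology (for comparisons)."""
        return self.tree.copy().canonicalize()

    def check_ultrametric(self, rtol: float = 1e-8) -> bool:
        depths = []

        def rec(v: Node, d: float):
            if v.is_leaf:
                depths.append(d)
            for c in v.children:
                rec(c, d + c.length)
        rec(self.tree.root, 0.0)
        return max(depths) - min(depths) <= rtol * max(depths, default=1.0)


def _leaf_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{str(i).zfill(width)}" for i in range(1, n + 1)]


def sample_species_tree(cfg: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> SpeciesTreeModel:
    """Pure-birth (Yule) species tree conditioned on the tip count and on a
    total height freshly drawn from the log-normal (mean
    ``cfg.height_mean`` generations).

    Conditioned on n tips and height T, the root split sits at time 0 and
    the remaining n-2 split times are i.i.d. on (0, T) with density
    proportional to lambda*exp(lambda*t) (more splits toward the present);
    at each split a uniformly chosen extant lineage divides.  This matches
    the birth-only simulators used for coalescent benchmarking datasets.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    lam = cfg.birth_rate
    height = float(rng.lognormal(
        np.log(cfg.height_mean) - cfg.height_sigma_log ** 2 / 2.0,
        cfg.height_sigma_log))
    # topology by forward random splitting; creation order = time order
    root = Node()
    active: list[Node] = [root]
    order: list[Node] = []
    while len(active) < n:
        v = active.pop(rng.integers(len(active)))
        order.append(v)
        for _ in range(2):
            active.append(v.add(Node()))
    # split times: root at 0; inverse-CDF draws of the truncated
    # exponential-growth density, sorted ascending
    if n > 2:
        u = rng.uniform(size=n - 2)
        draws = np.sort(np.log1p(u * np.expm1(lam * height)) / lam)
    else:
        draws = np.array([])
    split_time = {id(order[0]): 0.0}
    for v, t in zip(order[1:], draws):
        split_time[id(v)] = float(t)
    tree = Tree(root)
    leaves = [v for v in tree.postorder() if v.is_leaf]
    for name, leaf in zip(_leaf_names(n), leaves):
        leaf.label = name
    for v in tree.postorder():
        if v.parent is None:
            v.length = None
            continue
        t_parent = split_time[id(v.parent)]
        t_self = split_time.get(id(v), height)
        v.length = t_self - t_parent
    return SpeciesTreeModel(tree, cfg.ne)


def low_ils_model(n: int = 8, ne: float = 400_000.0,
                  internal_cu: float = 2.5, seed: int = 0
                  ) -> SpeciesTreeModel:
    """A Yule topology with every internal branch stretched to
    ``internal_cu`` coalescent units (Ne generations): a low-ILS regime in
    which gene trees overwhelmingly match the species tree."""
    cfg = SimulationConfig(n=n, ne=ne, seed=seed)
    model = sample_species_tree(cfg)
    step = internal_cu * ne

    # assign ages by internal-node level so internal edges are all `step`
    def level(v: Node) -> int:
        if v.is_leaf:
            return 0
        return 1 + max(level(c) for c in v.children)

    ages: dict[int, float] = {}

    def assign(v: Node):
        ages[id(v)] = level(v) * step
        for c in v.children:
            assign(c)
    assign(model.tree.root)
    for v in model.tree.postorder():
        if v.parent is not None:
            v.length = ages[id(v.parent)] - ages[id(v)]
    return model


def _demography(model: SpeciesTreeModel) -> msprime.Demography:
    return msprime.Demography.from_species_tree(
        model.newick(), initial_size=model.ne)


def _tree_from_tskit(tsk_tree, label_of_sample: dict[int, str],
                     unroot: bool) -> Tree:
    def conv(u: int) -> Node:
        ch = tsk_tree.children(u)
        if not ch:
            return Node(label=label_of_sample[u])
        node = Node()
        for c in ch:
            node.add(conv(c))
        return node
    tree = Tree(conv(tsk_tree.root))
    return tree.canonicalize() if unroot else tree


def sample_gene_trees(model: SpeciesTreeModel, k: int, seed: int,
                      unroot: bool = True) -> list[Tree]:
    """``k`` gene trees under the multispecies coalescent on the model.

    One haploid lineage per species; within a branch, each lineage pair
    coalesces at rate 1/Ne per generation; lineages failing to coalesce
    enter the parent branch, and coalescence continues above the root.
    With ``unroot=False`` the rooted coalescent genealogy shape is kept
    (needed e.g. to read off which pair coalesces first in triplets).
    """
    demog = _demography(model)
    samples = {p.name: 1 for p in demog.populations if p.name in model.labels}
    reps = msprime.sim_ancestry(
        samples=samples, demography=demog, ploidy=1,
        random_seed=(seed % (2 ** 31 - 1)) + 1, num_replicates=k)
    out = []
    for ts in reps:
        label_of = {u: demog.populations[ts.node(u).population].name
                    for u in ts.samples()}
        out.append(_tree_from_tskit(ts.first(), label_of, unroot))
    return out


def sample_gene_tree_msc(model: SpeciesTreeModel, seed: int) -> Tree:
    """A single MSCM gene tree (binary, on the species labels)."""
    return sample_gene_trees(model, 1, seed)[0]


def first_cherry(rooted: Tree) -> frozenset[str] | None:
    """The lowest cherry (two-leaf pair) of a rooted tree, by minimal
    subtree; for a 3-taxon genealogy this is the first-coalescing pair."""
    for v in rooted.postorder():
        if not v.is_leaf and len(v.children) == 2 \
                and all(c.is_leaf for c in v.children):
            return frozenset(c.label for c in v.children)
    return None


def triplet_model(tau: float, ne: float = 100_000.0) -> SpeciesTreeModel:
    """A 3-species model ((a,b),c) whose internal branch is ``tau``
    coalescent units: the rooted gene-tree topology matches the species
    topology with probability 1 - (2/3) e^(-tau)."""
    root = Node()
    inner = root.add(Node(length=tau * ne))
    inner.add(Node(label="a", length=2.0 * ne))
    inner.add(Node(label="b", length=2.0 * ne))
    root.add(Node(label="c", length=(2.0 + tau) * ne))
    return SpeciesTreeModel(Tree(root), ne)


def triplet_match_fraction(tau: float, n_draws: int, seed: int,
                           ne: float = 100_000.0) -> float:
    """Fraction of MSCM gene trees matching the species triplet ((a,b),c)."""
    model = triplet_model(tau, ne)
    genes = sample_gene_trees(model, n_draws, seed, unroot=False)
    target = frozenset(("a", "b"))
    return float(np.mean([first_cherry(g) == target for g in genes]))


def discordance_summary(model: SpeciesTreeModel,
                        gene_trees: list[Tree]) -> float:
    """Mean normalized RF between the (unrooted) true species tree and the
    gene trees."""
    ref = model.unrooted_topology()
    return float(np.mean([fn_rate(ref, g) for g in gene_trees]))


# ---------------------------------------------------------------------------
# contraction fixtures
# ---------------------------------------------------------------------------

def _random_nni(tree: Tree, rng: np.random.Generator) -> None:
    """One nearest-neighbor interchange on a random internal edge (in place)."""
    edges = [v for v in tree.postorder()
             if not v.is_leaf and v.parent is not None]
    if not edges:
        return
    v = edges[rng.integers(len(edges))]
    p = v.parent
    siblings = [c for c in p.children if c is not v]
    if not siblings or not v.children:
        return
    s = siblings[rng.integers(len(siblings))]
    c = v.children[rng.integers(len(v.children))]
    # swap subtree c (below v) with sibling s (beside v)
    p.children[p.children.index(s)] = c
    v.children[v.children.index(c)] = s
    c.parent, s.parent = p, v


def perturb_with_support(tree: Tree, cfg: SimulationConfig,
                         rng: np.random.Generator) -> Tree:
    """NNI-perturbed copy with pseudo-support: edges preserved from the
    original draw high support, edges created by the perturbation draw low
    support -- support is inversely related to the perturbation."""
    original = bipartition_clusters(tree)
    out = tree.copy()
    for _ in range(cfg.nni_moves):
        _random_nni(out, rng)
    below = {}
    for v in out.postorder():
        below[v] = (frozenset([v.label]) if v.is_leaf
                    else frozenset().union(*(below[c] for c in v.children)))
    full = below[out.root]
    anchor = min(full)
    for v in out.postorder():
        if v.is_leaf or v.parent is None:
            continue
        c = below[v]
        canon = full - c if anchor in c else c
        lo, hi = (cfg.support_true if canon in original
                  else cfg.support_false)
        v.support = float(np.round(rng.uniform(lo, hi), 1))
    return out


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESETS = {
    "tiny": SimulationConfig(n=6, k=30, seed=0),
    "homogeneous101": SimulationConfig(n=101, k=200, seed=0),
    "contraction_demo": SimulationConfig(n=8, k=40, seed=0, nni_moves=2),
}


def make_fixture_collection(preset: str, seed: int, out_dir) -> dict:
    """Write a reproducible newick gene-tree fixture plus manifest.

    Returns a manifest dict with file paths; identical seeds give
    byte-identical files.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    base = PRESETS[preset]
    cfg = SimulationConfig(**{**asdict(base), "seed": seed})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    model = sample_species_tree(cfg, rng)
    gene_seed = int(rng.integers(1, 2 ** 31 - 1))
    genes = sample_gene_trees(model, cfg.k, gene_seed)
    discordance = round(discordance_summary(model, genes), 4)
    files = {}
    sp_path = out_dir / f"{preset}.species.nwk"
    sp_path.write_text(model.newick() + "\n")
    files["species_tree"] = str(sp_path)
    if preset == "contraction_demo":
        genes = [perturb_with_support(g, cfg, rng) for g in genes]
    gt_path = out_dir / f"{preset}.genetrees.nwk"
    gt_path.write_text(
        "".join(write_newick(g, with_lengths=False) + "\n" for g in genes))
    files["gene_trees"] = str(gt_path)
    manifest = {
        "preset": preset,
        "seed": seed,
        "config": asdict(cfg),
        "files": files,
        "mean_discordance": discordance,
    }
    man_path = out_dir / f"{preset}.manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["manifest"] = str(man_path)
    return manifest


def collection_from_preset(preset: str, seed: int) -> GeneTreeCollection:
    """In-memory version of :func:`make_fixture_collection`."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    base = PRESETS[preset]
    cfg = SimulationConfig(**{**asdict(base), "seed": seed})
    rng = np.random.default_rng(seed)
    model = sample_species_tree(cfg, rng)
    gene_seed = int(rng.integers(1, 2 ** 31 - 1))
    genes = sample_gene_trees(model, cfg.k, gene_seed)
    if preset == "contraction_demo":
        genes = [perturb_with_support(g, cfg, rng) for g in genes]
    return GeneTreeCollection(genes)
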