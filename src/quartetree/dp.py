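"""Constrained dynamic program maximizing the shared-quartet score.

V(A) is the best score achievable by any rooted resolution of cluster A
using only clusters from the constraint set X:

    V(A) = max over (A'|A-A'|L-A) of  V(A') + V(A-A') + w(A'|A-A'|L-A)

with V = 0 for singletons.  Three interchangeable search modes return the
same V(L) and a tree attaining it:

* ``none``      -- plain memoized recursion;
* ``ubound``    -- resolutions of each cluster are visited in decreasing
  order of the A*-style bound U(A, A') and pruned once the bound cannot
  beat the best resolution found, where U(A) = w(A|A|L)/2 - w(A|A|A)/3
  dominates V(A) and needs no recursion;
* ``two_stage_alpha`` -- a first pass computes V_alpha (accepting a new
  resolution only when it beats the incumbent by a factor alpha >= 1),
  which sandwiches V_alpha <= V <= alpha * V_alpha and yields the tighter
  bound U_alpha = min(U, alpha*V_alpha) used to prune the exact second pass.

Scores are carried as doubled integers and bounds in twelfths (U is not an
integer in doubled units), with alpha an exact Fraction, so every pruning
comparison is exact and pruning can never change V(L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

from .constraints import (
    ConstraintSet,
    SearchSpaceConfig,
    build_constraint_set,
    count_tripartitions,
    enumerate_resolutions,
)
from .treeio import GeneTreeCollection, Node, Tree
from .weights import WeightEngine, popcount

__all__ = [
    "DPConfig",
    "InferenceResult",
    "ConstraintSetIncompleteError",
    "upper_bound",
    "greedy_alpha",
    "dp_solve",
    "two_stage_solve",
    "exact_solve",
    "normalized_score",
    "infer_species_tree",
]

TRIM_MODES = ("none", "ubound", "two_stage_alpha")


@dataclass
class DPConfig:
    """Search-mode configuration for the dynamic program."""
    trim: str = "ubound"
    alpha: Fraction | None = None   # override the U(L)/g(L) heuristic
    exact_cap: int = 12             # refusal threshold for exact mode
    seed: int = 0

    def __post_init__(self):
        if self.trim not in TRIM_MODES:
            raise ValueError(f"trim mode must be one of {TRIM_MODES}")
        if self.alpha is not None and self.alpha < 1:
            raise ValueError("alpha must be >= 1")


@dataclass
class InferenceResult:
    """Species tree plus its exact score and search diagnostics."""
    tree: Tree
    score2: int                     # doubled V(L), exact integer
    normalized: float               # V(L)/U(L), in [0, 1]
    diagnostics: dict = field(default_factory=dict)

    @property
    def score(self) -> float:
        """Raw quartet score V(L): total quartets shared with gene trees."""
        return self.score2 / 2.0


class ConstraintSetIncompleteError(RuntimeError):
    def __init__(self, cluster_labels: Sequence[str]):
        self.cluster = tuple(cluster_labels)
        super().__init__(
            "constraint set incomplete: no resolution for cluster "
            "{" + ",".join(cluster_labels) + "}")


class _DP:
    """Shared machinery for all trim modes (exact integer arithmetic)."""

    def __init__(self, engine: WeightEngine,
                 resolver: Callable[[int], list[tuple[int, int]]],
                 cfg: DPConfig):
        self.engine = engine
        self.resolver = resolver
        self.cfg = cfg
        self.L = engine.taxon_set.full_mask
        self._w2: dict[tuple[int, int, int], int] = {}
        self._u12: dict[int, int] = {}
        self.v2: dict[int, int] = {}
        self.valpha2: dict[int, int] = {}
        self.choice: dict[int, tuple[int, int]] = {}
        self.pruned = 0
        self.pruned_alpha = 0

    # -- weights and bounds ------------------------------------------------
    def w2(self, a: int, b: int, c: int) -> int:
        if c == 0:
            return 0
        key = (a, b, c)
        val = self._w2.get(key)
        if val is None:
            val = self.engine.weight2(a, b, c)
            self._w2[key] = val
        return val

    def u12(self, a: int) -> int:
        """12 * U(A) = 3*w2(A|A|L) - 2*w2(A|A|A)."""
        val = self._u12.get(a)
        if val is None:
            if popcount(a) <= 1:
                val = 0
            else:
                val = 3 * self.w2(a, a, self.L) - 2 * self.w2(a, a, a)
            self._u12[a] = val
        return val

    def u12_pair(self, a: int, a1: int, a2: int) -> int:
        return self.u12(a1) + self.u12(a2) + 6 * self.w2(a1, a2, self.L & ~a)

    def resolutions(self, a: int) -> list[tuple[int, int]]:
        res = self.resolver(a)
        if not res:
            ts = self.engine.taxon_set
            raise ConstraintSetIncompleteError(ts.labels_of(a))
        return res

    # -- plain / U-bound dynamic program -----------------------------------
    def solve_v(self, a: int, use_ubound: bool,
                alpha: Fraction | None = None) -> int:
        """Exact V2(A); with ``use_ubound`` resolutions are visited in
        decreasing U(A, A') and pruned; with ``alpha`` set, the stage-one
        memo additionally supplies U_alpha bounds."""
        memo = self.v2
        if a in memo:
            return memo[a]
        if popcount(a) == 1:
            memo[a] = 0
            return 0
        res = self.resolutions(a)
        if use_ubound:
            scored = [(self.u12_pair(a, a1, a2), i, a1, a2)
                      for i, (a1, a2) in enumerate(res)]
            scored.sort(key=lambda t: (-t[0], t[1]))
        else:
            scored = [(None, i, a1, a2) for i, (a1, a2) in enumerate(res)]
        best = None
        best_choice = None
        for pos, (u12p, _, a1, a2) in enumerate(scored):
            if best is not None and u12p is not None:
                if u12p <= 6 * best:
                    self.pruned += len(scored) - pos
                    break
                if alpha is not None:
                    ua12 = (self._ualpha_part(a1, alpha)
                            + self._ualpha_part(a2, alpha)
                            + 6 * self.w2(a1, a2, self.L & ~a))
                    if 6 * best > ua12:
                        self.pruned += 1
                        continue
            v = (self.solve_v(a1, use_ubound, alpha)
                 + self.solve_v(a2, use_ubound, alpha)
                 + self.w2(a1, a2, self.L & ~a))
            if best is None or v > best:
                best = v
                best_choice = (a1, a2)
        memo[a] = best
        self.choice[a] = best_choice
        return best

    def _ualpha_part(self, c: int, alpha: Fraction):
        """min(12*U(C), 12*alpha*V_alpha(C)); exact Fraction when needed."""
        u = self.u12(c)
        va2 = self.valpha2.get(c)
        if va2 is None:
            return u
        return min(u, 6 * alpha * va2)

    # -- stage one of alpha-trimming ---------------------------------------
    def solve_valpha(self, a: int, alpha: Fraction) -> int:
        memo = self.valpha2
        if a in memo:
            return memo[a]
        if popcount(a) == 1:
            memo[a] = 0
            return 0
        res = self.resolutions(a)
        scored = [(self.u12_pair(a, a1, a2), i, a1, a2)
                  for i, (a1, a2) in enumerate(res)]
        scored.sort(key=lambda t: (-t[0], t[1]))
        best = 0  # V_alpha^0 = 0
        for pos, (u12p, _, a1, a2) in enumerate(scored):
            # alpha * best >= U(A, A_j) guarantees no alpha-improvement
            if 6 * alpha * best >= u12p:
                self.pruned_alpha += len(scored) - pos
                break
            va = (self.solve_valpha(a1, alpha)
                  + self.solve_valpha(a2, alpha)
                  + self.w2(a1, a2, self.L & ~a))
            if va > alpha * best:
                best = va
        memo[a] = best
        return best

    # -- greedy alpha heuristic --------------------------------------------
    def greedy_g2(self, a: int) -> int:
        """One root-to-leaves descent following the argmax of U(A, A_j)."""
        if popcount(a) == 1:
            return 0
        res = self.resolutions(a)
        best = max(
            ((self.u12_pair(a, a1, a2), -i, a1, a2)
             for i, (a1, a2) in enumerate(res)))
        _, _, a1, a2 = best
        return (self.greedy_g2(a1) + self.greedy_g2(a2)
                + self.w2(a1, a2, self.L & ~a))

    def backtrack_tree(self) -> Tree:
        ts = self.engine.taxon_set

        def build(mask: int) -> Node:
            if popcount(mask) == 1:
                return Node(label=ts.labels[mask.bit_length() - 1])
            a1, a2 = self.choice[mask]
            node = Node()
            node.add(build(a1))
            node.add(build(a2))
            return node

        return Tree(build(self.L)).canonicalize()


def _resolver_from_x(X: ConstraintSet):
    by_size = X.clusters_by_size()
    cache: dict[int, list[tuple[int, int]]] = {}

    def resolver(a: int) -> list[tuple[int, int]]:
        res = cache.get(a)
        if res is None:
            res = enumerate_resolutions(a, X, _by_size=by_size)
            cache[a] = res
        return res

    return resolver


def _submask_resolver(full: int):
    def resolver(a: int) -> list[tuple[int, int]]:
        lb = a & -a
        rest = a ^ lb
        out = []
        sub = rest
        while True:
            a1 = lb | sub
            a2 = a ^ a1
            if a2:
                out.append((a1, a2))
            if sub == 0:
                break
            sub = (sub - 1) & rest
        return out

    return resolver


def upper_bound(A: int, engine: WeightEngine) -> float:
    """U(A) = w(A|A|L)/2 - w(A|A|A)/3 >= V(A), computed without recursion."""
    if popcount(A) <= 1:
        return 0.0
    L = engine.taxon_set.full_mask
    return (3 * engine.weight2(A, A, L) - 2 * engine.weight2(A, A, A)) / 12.0


def greedy_alpha(X: ConstraintSet, engine: WeightEngine,
                 cfg: DPConfig | None = None) -> Fraction:
    """alpha = U(L) / g(L) where g follows the greedy argmax-of-U descent;
    falls back to 1 when g(L) = 0 (e.g. all-star gene trees)."""
    dp = _DP(engine, _resolver_from_x(X), cfg or DPConfig())
    g2 = dp.greedy_g2(engine.taxon_set.full_mask)
    if g2 == 0:
        return Fraction(1)
    alpha = Fraction(dp.u12(engine.taxon_set.full_mask), 6 * g2)
    return max(alpha, Fraction(1))


def _finish(dp: _DP, X_size, Y_size, engine: WeightEngine,
            extras: dict | None = None) -> InferenceResult:
    L = engine.taxon_set.full_mask
    score2 = dp.v2[L]
    u12_l = dp.u12(L)
    normalized = (6 * score2 / u12_l) if u12_l else 0.0
    diag = {
        "X_size": X_size,
        "Y_size": Y_size,
        "pruned": dp.pruned,
        "pruned_alpha": dp.pruned_alpha,
        "score2": score2,
        "U_L": u12_l / 12.0,
    }
    if extras:
        diag.update(extras)
    return InferenceResult(tree=dp.backtrack_tree(), score2=score2,
                           normalized=normalized, diagnostics=diag)


def dp_solve(X: ConstraintSet, engine: WeightEngine,
             cfg: DPConfig | None = None,
             count_y: bool = True) -> InferenceResult:
    """Maximize the quartet score over binary trees with clusters in X."""
    cfg = cfg or DPConfig()
    if cfg.trim == "two_stage_alpha":
        return two_stage_solve(X, engine, cfg, count_y=count_y)
    dp = _DP(engine, _resolver_from_x(X), cfg)
    dp.solve_v(engine.taxon_set.full_mask, use_ubound=(cfg.trim == "ubound"))
    y = count_tripartitions(X) if count_y else None
    res = _finish(dp, len(X), y, engine)
    res.diagnostics["trim"] = cfg.trim
    res.dp_state = dp  # exposed for invariant checks
    return res


def two_stage_solve(X: ConstraintSet, engine: WeightEngine,
                    cfg: DPConfig | None = None,
                    count_y: bool = True) -> InferenceResult:
    """Alpha-trimmed search: stage one computes V_alpha, stage two the
    exact V using the tightened U_alpha bounds.  V(L) is identical to the
    other modes."""
    cfg = cfg or DPConfig(trim="two_stage_alpha")
    dp = _DP(engine, _resolver_from_x(X), cfg)
    L = engine.taxon_set.full_mask
    alpha = cfg.alpha
    if alpha is None:
        g2 = dp.greedy_g2(L)
        alpha = (Fraction(1) if g2 == 0
                 else max(Fraction(dp.u12(L), 6 * g2), Fraction(1)))
    dp.solve_valpha(L, alpha)
    dp.solve_v(L, use_ubound=True, alpha=alpha)
    y = count_tripartitions(X) if count_y else None
    res = _finish(dp, len(X), y, engine, extras={"alpha": float(alpha)})
    res.diagnostics["trim"] = "two_stage_alpha"
    res.dp_state = dp
    res.alpha = alpha
    return res


def exact_solve(G: GeneTreeCollection,
                cfg: DPConfig | None = None) -> InferenceResult:
    """Optimum over ALL binary trees on L (X = power set); refuses above
    the configured taxon cap (the space grows as ~3^n tripartitions)."""
    cfg = cfg or DPConfig()
    engine = WeightEngine(G)
    n = engine.taxon_set.n
    if n > cfg.exact_cap:
        raise ValueError(
            f"exact mode refused: {n} taxa exceeds the cap of "
            f"{cfg.exact_cap} (the unconstrained space is ~3^n)")
    dp = _DP(engine, _submask_resolver(engine.taxon_set.full_mask), cfg)
    L = engine.taxon_set.full_mask
    if cfg.trim == "two_stage_alpha":
        g2 = dp.greedy_g2(L)
        alpha = cfg.alpha or (Fraction(1) if g2 == 0
                              else max(Fraction(dp.u12(L), 6 * g2),
                                       Fraction(1)))
        dp.solve_valpha(L, alpha)
        dp.solve_v(L, use_ubound=True, alpha=alpha)
    else:
        dp.solve_v(L, use_ubound=(cfg.trim == "ubound"))
    res = _finish(dp, 2 ** n, None, engine, extras={"mode": "exact"})
    res.dp_state = dp
    return res


def normalized_score(result: InferenceResult,
                     engine: WeightEngine) -> float:
    """V(L)/U(L) in [0, 1]; 0 by convention when U(L) = 0."""
    u = upper_bound(engine.taxon_set.full_mask, engine)
    return (result.score / u) if u else 0.0


def infer_species_tree(G: GeneTreeCollection,
                       space_cfg: SearchSpaceConfig | None = None,
                       dp_cfg: DPConfig | None = None,
                       count_y: bool = True,
                       extra_trees: Sequence[Tree] = ()) -> InferenceResult:
    """End-to-end inference: build X (optionally merging bipartitions from
    user-supplied trees), build the weight engine, run the DP."""
    X = build_constraint_set(G, space_cfg)
    if extra_trees:
        from .constraints import merge_extra_bipartitions
        merge_extra_bipartitions(X, extra_trees)
    engine = WeightEngine(G)
    res = dp_solve(X, engine, dp_cfg, count_y=count_y)
    res.diagnostics["rounds_used"] = len(X.round_log)
    return res
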