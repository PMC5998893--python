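# Methods

This note documents the model, the algorithmic identities, the numerical
conventions, and the design choices behind `quartetree`, in the spirit of
the methods documentation of simulation and inference packages in this
field.

## Problem and model

Input is a set *G* of *k* unrooted gene trees over subsets of a species set
*L* (|L| = n); trees may contain polytomies (unresolved nodes) and missing
taxa, and optionally carry percent support on internal branches. The target
is the unrooted binary species tree maximizing the number of induced quartet
topologies shared with *G*. Under the multispecies coalescent the most
probable unrooted quartet gene tree matches the species tree quartet, which
is what makes the optimum a consistent estimator; no branch lengths or
rooting of the inputs are used.

## Scoring engine

Every internal node of a gene tree *g* induces a partition of the tree's
own leaf set L_g (one part per neighboring subtree; for trees missing taxa
the remainder part is taken relative to L_g, never renormalized). Identical
partitions across trees are collapsed into a table E of unique partitions
with multiplicities; D denotes the summed degree over unique partitions.
The contribution of a candidate tripartition T = (A|B|C) is

    w(T) = 1/2 * sum over (M, c) in E of c * QI(T, M)

where QI(T, M) is twice the number of quartet topologies shared between
one tree containing only node T and one containing only node M. QI admits
two evaluations, kept deliberately in parallel:

* a cubic reference sum over ordered part triples (the oracle used in
  tests), and
* a Θ(d) evaluation from the per-part intersection cardinalities
  a_i = |A ∩ M_i| (similarly b, c) and their sums S_a, S_ab, ...:

      QI = Σ_i C(a_i,2)·((S_b−b_i)(S_c−c_i) − S_bc + b_i c_i)  + (two
      symmetric terms)

The equality of the two is asserted exhaustively for small taxon sets and
on randomized high-degree instances, including triples with repeated or
overlapping parts (which the bounds below rely on).

Intersection cardinalities are not computed per query by popcounts:
the unique clusters of all gene trees form a *polytree* — each gene tree is
rooted at the lexicographically smallest taxon it contains, so identical
subtrees map to identical clusters; each cluster keeps one (first-seen)
child set. One bottom-up pass over the polytree fills every |W ∩ A| with at
most D additions via |W ∩ A| = Σ_{Z ∈ children(W)} |Z ∩ A|. The direct
popcount is retained as the test oracle for this pass.

## Dynamic program

V(A), the best score of any resolution of cluster A using clusters from
the constraint set X, follows the recursion in the README; the output tree
is reconstructed from backtracking links and serialized unrooted. The
top-level split contributes w = 0 (its third part is empty), so score
audits should not expect a root term. Three search modes return identical
V(L):

* **none** — plain memoized recursion in canonical resolution order.
* **ubound** — resolutions of A are visited in decreasing
  U(A,A′) = U(A′) + U(A−A′) + w(A′|A−A′|L−A), where
  U(A) = w(A|A|L)/2 − w(A|A|A)/3 ≥ V(A) needs no recursion; once the best
  found resolution reaches the bound of the next candidate, the remainder
  of the (sorted) list is pruned wholesale.
* **two_stage_alpha** — stage one computes V_α by the same recursion but
  accepts a new resolution only when it beats the incumbent by a factor
  α ≥ 1, pruning when α·(incumbent) ≥ U(A,A_j); this sandwiches
  V_α ≤ V ≤ α·V_α. Stage two computes exact V using the tightened bound
  U_α(A,A_j) = min(U(A_j), αV_α(A_j)) + min(U(A−A_j), αV_α(A−A_j)) + w(...)
  (falling back to U for clusters stage one never memoized). α defaults to
  U(L)/g(L), where g is one greedy root-to-leaves descent always following
  the argmax of U(A,A_j); α = 1 whenever g(L) = 0, and α = 1 reproduces the
  plain program exactly.

Numerical conventions: quartet scores are carried as doubled integers
(sums of multiplicity × QI), U-bounds in twelfths (12U = 3·w2(A|A|L) −
2·w2(A|A|A) is integral), and α as an exact rational — every pruning
comparison is exact, so trimming can only remove work, never change V(L).
Ties among equal-scoring resolutions go to the first candidate in the
deterministic visiting order. Exact mode replaces X by the power set
(submask enumeration) and refuses above a 12-taxon cap, since the
unconstrained space grows as ~3^n.

## Constraint set X

X always contains all singletons, complements, L, and every cluster of
every gene-tree bipartition — the last being the ingredient that preserves
statistical consistency. Enlargement then proceeds:

1. If any gene tree has a polytomy, a UPGMA guide tree is built over all
   taxa from the similarity matrix, and each gene-tree polytomy is resolved
   three times (independent random samples of one taxon per side): the
   guide restricted to the sample is mapped back by replacing each sampled
   taxon with its entire side, and the resulting clusters join X.
2. Up to 110 rounds (config cap): a greedy consensus of the gene trees is
   built with randomized tie-breaking, and each consensus polytomy is
   resolved by (a) a UPGMA-like tree over the polytomy sides, (b) a greedy
   consensus of gene trees restricted to a one-taxon-per-side sample, and
   (c) caterpillar trees ordered by decreasing similarity to each sampled
   taxon. Technique (c) is quadratic in the degree, so it applies only to
   the ascending-degree prefix d_1…d_q with Σd_i² ≤ c·n (c = 25 by
   default); the stated rule reads "smallest q", but the prefix sum grows
   with q, so the largest such q is implemented (the reading that bounds,
   rather than voids, the technique). A round adding fewer than 10 new
   clusters stops the loop.
3. A completion pass: clusters harvested from incomplete gene trees (or
   their complements) may not decompose into members of X; for each such
   cluster the smallest-member split is inserted, to a fixpoint, so the
   dynamic program is total (it raises a descriptive error on any
   unresolvable cluster it does reach).

The similarity between taxa u and v is the number of gene-tree quartets
resolved as uv|xy — unresolved quartets contribute nothing, so polytomies
never inflate similarity. It is computed per tree in one inclusion-
exclusion sweep (each resolved quartet's central path has one more edge
than interior node) and checked against an O(n⁴) brute-force oracle.
Consensus rounds use only gene trees covering all of L; incomplete trees
still contribute their bipartitions and polytomy resolutions (distance-
based completion of partial trees is out of scope). With these caps each
round adds O(n) clusters and |X| stays O(nk); the tripartition space obeys
|Y| ≤ |X|^(3/log₃(27/4)) ≈ |X|^1.726 for any complement-closed X, which
the acceptance script verifies empirically on simulated grids (observed
exponents ≈ 1.2–1.3).

## Branch contraction

`contract_low_support` collapses every internal edge with support ≤ τ
(inclusive comparison, matching the threshold grids used in contraction
studies); leaf edges never collapse; edges lacking a support value are
treated as fully supported, since contraction targets measured uncertainty
only. Supports parse from internal node labels; if every value is ≤ 1 they
are read as fractions and scaled to percent. τ = None disables contraction.

## Fixture generator

The generator emulates a homogeneous birth-only benchmark design at
configurable scale. Defaults are the study conditions: n = 101 species,
per-generation birth rate 1e-7, fixed haploid Ne = 400,000, total height
drawn log-normal with mean 2.5e6 generations, k = 1000 gene trees.

* **Species trees** are pure-birth trees conditioned on the tip count and
  on the drawn height: the root split sits at time 0 and the remaining
  n−2 split times are i.i.d. with density ∝ λe^(λt) on (0, T), each split
  dividing a uniformly chosen extant lineage. (A free Yule run rescaled to
  the drawn height was evaluated and rejected: it concentrates length near
  the root and yields materially higher gene-tree discordance than the
  conditioned process this design emulates.) The log-normal is
  parameterized by the mean of the distribution itself; its log-scale
  spread defaults to 0.25 and is a config knob. At the default conditions
  the mean true-tree/gene-tree normalized RF comes out ≈ 0.41–0.46 with a
  per-replicate spread of roughly 0.3–0.6.
* **Gene trees** are simulated with msprime (one haploid lineage per
  species, ploidy 1, populations of size Ne, divergence times from the
  species tree), so the coalescent time unit is Ne generations — users
  comparing against diploid-convention simulators should halve/double
  accordingly.
* **Support-annotated noisy collections** perturb true gene trees by
  random NNI moves and draw pseudo-support high (60–100) on branches the
  perturbation preserved and low (0–40) on branches it created, so
  contraction thresholds are exercisable without sequence simulation.
  These fixtures emulate topology noise only: real bootstrap supports
  correlate with branch length and alignment signal in ways this does not
  model, so passing contraction tests demonstrates plumbing and threshold
  semantics, not accuracy on real data.
* The 3-taxon calibration oracle is the closed form
  P(match) = 1 − (2/3)e^(−τ) for an internal branch of τ coalescent units;
  a low-ILS preset stretches every internal branch of a sampled topology
  to a fixed coalescent length (2.5 units by default) for consistency
  smoke tests.

All randomness flows from explicit seeds; fixture files are byte-identical
across runs with the same seed.

## Problem sizes used in the shipped checks

The test battery runs the QI identity exhaustively for ≤ 6 taxa and on
1000 random instances with degree ≤ 30; the score/oracle identity on 200
random instances with n ≤ 10; exact-mode optimality against full topology
enumeration for n = 6 and 7; trim-mode equivalence on 50 random instances;
consistency on 20 seeds of an 8-taxon low-ILS model with 300 gene trees
(20/20 recoveries observed); and fixture calibration with 20,000 coalescent
draws per τ and 10 replicates of 200 gene trees at n = 101. The acceptance
script uses 20 collections over n ∈ {20, 50} × k ∈ {20, 100}. These sizes
were chosen so the full battery completes in minutes on one CPU while each
property is exercised well past its small-case edge conditions.

## Known limitations

* Single allele per species; no mapping of multiple individuals.
* No branch lengths or support annotation on the output species tree; the
  output is a topology with its exact quartet score.
* Non-binary species trees are not scored.
* The greedy consensus treats only complete gene trees; heavily incomplete
  collections lean on the completion pass, whose added clusters are
  structural (smallest-member chains) rather than similarity-guided.
* The normalized score V(L)/U(L) is a convention of this package (share of
  the attainable resolved-quartet agreement realized); it is not a
  posterior or a support value.
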