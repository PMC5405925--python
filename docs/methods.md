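# Methods

## Scope and model

`mpclad` implements unweighted and implied-weighted maximum parsimony for
unordered discrete morphological characters (up to four states), the
workflow used in cladistic studies of small fossil datasets: heuristic and
exact tree search, strict consensus with zero-length-branch collapsing,
ensemble consistency/retention indices, Bremer support from suboptimal
trees, and ACCTRAN character mapping rooted on a designated outgroup.

Characters are independent and unordered: any state may change into any
other at unit cost.  Unknown (`?`) and inapplicable (`–`) cells both
contribute the character's full state set during optimization, so they can
never force a step — the behaviour of the major parsimony programs for the
gap symbol.  Hierarchical inapplicability (an organ-shape character that
cannot be scored when the organ is absent) is therefore respected at the
*coding* level only: the matrix model records a `controlling` character
per dependent character, and the simulator enforces the dependency, but
scoring treats `–` exactly like `?`.

## Optimization machinery

Two scoring routes coexist deliberately:

* a packed **Fitch** engine for binary trees used inside searches: state
  sets live one 4-bit nibble per character in a single Python integer, so
  one Fitch join for all characters is a handful of word-wide bit
  operations, and per-character step counters fit the same layout (a
  character can need at most n − 1 < 16 steps);
* a per-character **Sankoff** dynamic programme (unit costs) for all
  public scoring, which is exact on multifurcating trees (consensus
  mapping) and reduces to Fitch counts on binary ones.

The two routes cross-check each other in the tests, and both are checked
against a brute-force enumeration of all internal-node assignments on
small instances and against an external parsimony implementation
(phangorn, via Rscript).

Per-character bounds use the standard identities: minimum steps
m = (observed states − 1); maximum steps g = (scoreable taxa) − (count of
the most frequent state), which equals the star-tree score and the maximum
over all binary trees (asserted exhaustively at n = 7 in the tests).
Ensemble CI = Σm/L and RI = (Σg − L)/(Σg − Σm) are reported both over all
characters and over parsimony-informative ones, at full precision and
rounded half-up to two decimals.  The implied-weighting objective is
F = Σ h/(h + k), h = s − m, minimised; as k → ∞ its ranking converges to
the length ranking (property-tested), and at the true tree of
homoplasy-free data F = 0.

## Tree search

The heuristic follows the classic traditional-search recipe: per
replicate, a random addition sequence builds a greedy stepwise starting
tree, then branch swapping (TBR by default; SPR and NNI available)
accepts the *first* improving rearrangement in a seeded-shuffled order —
reproducible yet unbiased — and, at the local optimum, explores the
plateau of equal-score trees breadth-first, holding up to
`hold_per_replicate` trees.  TBR rescoring is incremental: bisecting at an
edge and computing Fitch root sets for every reattachment point in both
halves makes each reconnection a single join.  Defaults (100 replicates,
hold 100, buffer 100 000 trees, suboptimal margin 20 steps) mirror common
practice for matrices of this size.

Suboptimal trees encountered during swapping are buffered (topology key
and length only) up to `max_trees`, with a bounded per-sweep quota; Bremer
support of a clade is the shortest buffered tree lacking the clade minus
the best length.  Buffered Bremer values are upper bounds that tighten as
the pool grows (property-tested); clades never contradicted within the
pool are reported as `> margin`.  An exact mode enumerates all trees for
tiny matrices (n ≤ 9) and validates the pooled values.

Branch-and-bound adds taxa one at a time — most mutually distant taxa
first, which makes the bound bite early — pruning a partial tree when its
length plus the number of states absent from the current taxon subset
exceeds the best known score; it returns *all* optimal binary trees and is
guarded at 16 taxa.  For implied weighting the bound exploits monotonicity
of the fit in added steps.  Heuristic and exact routes are asserted equal
on every test matrix.

## Collapsing, consensus, identity

Trees are stored and compared unrooted; identity is equality of
non-trivial bipartition sets, and rooting on the outgroup is a display and
clade-query operation only (length is rooting-invariant).  After a search,
zero-length branches collapse under a selectable rule: **min** (default —
collapse when some most-parsimonious reconstruction puts zero changes on
the branch) or **max** (collapse only when every reconstruction does).
Distinctness of MPTs is assessed after collapsing.  One caveat found and
documented while testing: contracting *several* min-zero branches
simultaneously can increase a tree's length, because no single
reconstruction need realise zero on all of them at once; the max rule
provably preserves length (every reconstruction avoids all max-zero
branches).  Ensemble indices are therefore computed on the pre-collapse
binary optima.  Strict consensus keeps exactly the bipartitions shared by
all inputs (asserted as an exact set identity, and cross-checked against
dendropy's consensus).

## ACCTRAN mapping

Character changes are mapped onto a tree rooted through a virtual node on
the outgroup's branch.  Per character, a Sankoff down-pass supplies cost
vectors; the virtual root takes a minimum-cost state, ties broken toward
the outgroup's observed state (plesiomorphic polarity, so a basal change is
drawn on the ingroup stem rather than as an outgroup autapomorphy); a
preorder pass then assigns each node a single minimum-cost state, ties
broken toward a state *different* from the parent — the accelerated
transformation, which places changes as close to the root as possible and
prefers reversals over parallelisms.  A change is flagged *unique* when
its character changes exactly once on the whole tree, otherwise
homoplasious; changes hanging from polytomies are flagged as potentially
ambiguous in placement.  Conservation (mapped changes per character equal
that character's minimum steps on the tree) is asserted on every mapping.

## Synthetic data and what passing tests show

The generator plants evolution on a known tree.  Each character receives
arity − 1 baseline changes, each introducing a brand-new state (so m is
known by construction); homoplasy is E explicit re-introductions of
existing states, each verified by rescoring to add exactly one step; thus
on the generating tree L = Σm + E and CI = Σm/(Σm + E) *exactly*.  Planted
clades get dedicated characters whose defining change sits on the clade
stem, and no other character may place an event on a planted stem.
Missing cells are injected at a stochastically rounded global count but
only where they change neither a character's step count nor its observed
state set, keeping the bookkeeping exact; the outgroup row and planted
columns are protected.  Inapplicable cells are derived from the true
simulated controller states before homoplasy planting, and dependent
characters are re-placed if the mask distorts their step count.  A
rate-based Mk-style mode exists for realism checks and carries no
bookkeeping.

The bundled 14 × 39 example (`mpclad.datasets`, fixed seed) applies the
template of a fossil-aphid matrix: 34 binary and five multistate
characters (Σm = 45), canadaphidid and bajsaphidid clades planted with the
synapomorphy characters listed there, E = 30 (generating-tree CI exactly
0.60), 15% missing cells, and two controller→dependent links.  On it the
optimum is 74 steps — one step *shorter* than the generating tree: thirty
random extra changes can conspire to support alternative groupings, which
is exactly the regime the implied-weights stability check is for.  The
three-taxon canadaphidid clade (nine planted characters) survives with
Bremer support 7; the two-character bajsaphidid pair dissolves into the
consensus polytomy.  ACCTRAN may map additional *homoplasious* changes
onto a planted stem (ambiguous placements migrate rootward), so under
homoplasy the planted set is asserted as a subset of the mapped set;
equality holds, and is asserted, on the homoplasy-free variant.

What the simulations do not emulate: correlated character evolution,
hierarchically structured (phylogenetically coherent) homoplasy,
taxon-biased missingness, or ordered/continuous characters.  Passing tests
therefore demonstrate correctness of the algorithms under known-truth
conditions, not robustness of parsimony on any particular real dataset.

## Numerical and reproducibility choices

All searches are deterministic given (matrix, config, seed): every draw
comes from one seeded generator, and the CLI makes the seed mandatory.
Implied-weight scores compare with an absolute tolerance of 1e-9 (exact
integer arithmetic everywhere else).  Reported CI/RI round half-up to two
decimals.  Problem sizes in the test suite and the acceptance script —
oracle checks at 4–10 taxa, full protocol at 14 — were chosen so the whole
suite completes in about a minute while every oracle comparison stays
exhaustive.

## Known limitations

No ordered/Sankoff-cost-matrix characters, no ratchet or driven searches
(unnecessary below ~20 taxa), no majority-rule or Adams consensus, no
DELTRAN or full MPR-set enumeration (the unique/homoplasious flag needs
only change counts), and branch-and-bound is capped at 16 taxa.  The TNT
reader handles only the minimal `xread` dialect.
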