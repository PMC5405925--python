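"""Character-level parsimony: steps, homoplasy, ensemble indices, implied
weighting, and ACCTRAN synapomorphy mapping.

All characters are unordered (Fitch) characters.  Scoring uses the Sankoff
dynamic programme with unit costs, which computes the exact minimum number
of changes on *any* tree, including multifurcating ones (consensus trees),
and degenerates to Fitch counts on binary trees.  Missing and inapplicable
cells carry the full state set and never force a step.

Notation follows standard morphological cladistics: for character i,
``s`` = observed steps on a tree, ``m`` = minimum steps over all trees
(number of observed states - 1), ``g`` = maximum steps (star-tree steps),
``h = s - m`` = homoplasy.  Ensemble consistency index CI = sum(m)/L and
retention index RI = (sum(g) - L)/(sum(g) - sum(m)) with L the tree length.
Implied weighting scores a tree by F = sum_i h_i/(h_i + k), minimised, with
concavity constant k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

from . import _engine
from .matrix_io import CharacterMatrix
from .trees import PhyloTree

__all__ = [
    "CharacterScore",
    "MatrixScore",
    "Change",
    "SynapomorphyMap",
    "fitch_steps",
    "tree_length",
    "min_max_steps",
    "character_scores",
    "ensemble_indices",
    "implied_fit",
    "branch_length_ranges",
    "acctran_map",
    "round2",
]

_INF = 1 << 20


def round2(x: float) -> float:
    """Round half-up to 2 decimals (reporting convention for CI/RI)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Sankoff machinery on indexed adjacencies
# ---------------------------------------------------------------------------

def _leaf_costs(matrix: CharacterMatrix, char_index: int) -> list[list[int]]:
    """Per-taxon Sankoff cost vectors for one character (0-based taxon order)."""
    arity = matrix.characters[char_index - 1].arity
    out = []
    for cell in matrix.column(char_index):
        if cell >= 0:
            out.append([0 if s == cell else _INF for s in range(arity)])
        else:
            out.append([0] * arity)  # missing/inapplicable: any state, free
    return out


def _directed_costs(
    adj: dict[int, tuple[int, ...]],
    leaf_costs: list[list[int]],
    arity: int,
    n_taxa: int,
) -> dict[tuple[int, int], list[int]]:
    """``D[(x, y)][s]`` = min changes in the side containing ``x`` when edge
    (x, y) is cut, given ``x`` is assigned state ``s`` (edge itself excluded)."""
    D: dict[tuple[int, int], list[int]] = {}
    for u, v in _engine.edges_of(adj):
        for x, y in ((u, v), (v, u)):
            if (x, y) in D:
                continue
            for a, b in _engine._postorder(adj, x, y):
                kids = [c for c in adj[a] if c != b]
                if a < n_taxa and not kids:
                    D[(a, b)] = list(leaf_costs[a])
                    continue
                vec = list(leaf_costs[a]) if a < n_taxa else [0] * arity
                for c in kids:
                    child = D[(c, a)]
                    best_child = min(child)
                    vec = [
                        vec[s]
                        + min(child[s], best_child + 1)
                        for s in range(arity)
                    ]
                D[(a, b)] = vec
    return D


def _char_min_on_tree(
    adj: dict[int, tuple[int, ...]],
    leaf_costs: list[list[int]],
    arity: int,
    n_taxa: int,
) -> int:
    """Single postorder Sankoff pass (exact on multifurcating trees)."""
    if len(adj) == 2:
        a, b = leaf_costs[0], leaf_costs[1]
        return min(
            a[s] + b[t] + (s != t) for s in range(arity) for t in range(arity)
        )
    leaf = next(u for u in adj if len(adj[u]) == 1)
    root = adj[leaf][0]
    vecs: dict[int, list[int]] = {}
    for a, b in _engine._postorder(adj, root, leaf):
        kids = [c for c in adj[a] if c != b]
        if a < n_taxa and not kids:
            vecs[a] = leaf_costs[a]
            continue
        vec = list(leaf_costs[a]) if a < n_taxa else [0] * arity
        for c in kids:
            child = vecs[c]
            best = min(child)
            vec = [vec[s] + min(child[s], best + 1) for s in range(arity)]
        vecs[a] = vec
    rootv = vecs[root]
    leafv = leaf_costs[leaf]
    best_leaf = min(leafv)
    return min(
        rootv[s] + min(leafv[s], best_leaf + 1) for s in range(arity)
    )


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterScore:
    """Per-character parsimony bookkeeping on one tree."""

    char_index: int
    s: int  # observed steps on the tree
    m: int  # minimum steps over all trees
    g: int  # maximum (star-tree) steps
    fit_k: float | None = None  # concavity used for `fit`, if any

    @property
    def h(self) -> int:
        return self.s - self.m

    @property
    def fit(self) -> float:
        """Implied-weight contribution h/(h+k) (0 when homoplasy-free)."""
        if self.fit_k is None:
            raise ValueError("no concavity constant attached to this score")
        return self.h / (self.h + self.fit_k) if self.h > 0 else 0.0


@dataclass(frozen=True)
class MatrixScore:
    """Whole-matrix summary on a tree (or set of equally long trees)."""

    length: int
    sum_m: int
    sum_g: int
    n_characters: int
    variant: str = "all"  # character-inclusion variant: all | informative
    k: float | None = None
    fit_total: float | None = None

    @property
    def ci(self) -> float:
        if self.length == 0:
            raise ZeroDivisionError("CI undefined at zero length")
        return self.sum_m / self.length

    @property
    def ri(self) -> float:
        denom = self.sum_g - self.sum_m
        if denom == 0:
            raise ZeroDivisionError("RI undefined when sum(g) == sum(m)")
        return (self.sum_g - self.length) / denom

    @property
    def ci2(self) -> float:
        return round2(self.ci)

    @property
    def ri2(self) -> float:
        return round2(self.ri)


def fitch_steps(tree: PhyloTree, matrix: CharacterMatrix, char_index: int) -> int:
    """Minimum number of unordered state changes of one character on a tree.

    Exact for multifurcating trees too (Sankoff with unit costs).  Missing
    and inapplicable leaves never force a step.
    """
    if not 1 <= char_index <= matrix.n_characters:
        raise IndexError(f"character index {char_index} out of range")
    adj = tree.to_indexed_adjacency(matrix.taxa)
    return _char_min_on_tree(
        adj,
        _leaf_costs(matrix, char_index),
        matrix.characters[char_index - 1].arity,
        matrix.n_taxa,
    )


def tree_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Total parsimony length L = sum of per-character minimum changes.

    Invariant under rerooting.  Binary trees take the fast packed-Fitch
    path; multifurcating trees fall back to per-character Sankoff.
    """
    adj = tree.to_indexed_adjacency(matrix.taxa)
    if tree.is_binary():
        return _engine.fitch_length(adj, _engine.PackedMatrix(matrix))
    return sum(
        _char_min_on_tree(
            adj,
            _leaf_costs(matrix, j),
            matrix.characters[j - 1].arity,
            matrix.n_taxa,
        )
        for j in range(1, matrix.n_characters + 1)
    )


def min_max_steps(matrix: CharacterMatrix, char_index: int) -> tuple[int, int]:
    """(m, g): minimum steps over all trees and maximum (star-tree) steps.

    m = (number of distinct observed states) - 1 (floor 0); g = number of
    scoreable taxa minus the count of the most frequent observed state.
    """
    counts = matrix.state_counts(char_index)
    if not counts:
        return 0, 0
    m = len(counts) - 1
    g = sum(counts.values()) - max(counts.values())
    return m, g


def character_scores(
    tree: PhyloTree, matrix: CharacterMatrix, k: float | None = None
) -> list[CharacterScore]:
    """Per-character s/m/g (and implied-weight fit if ``k`` given) on a tree."""
    out = []
    for j in range(1, matrix.n_characters + 1):
        s = fitch_steps(tree, matrix, j)
        m, g = min_max_steps(matrix, j)
        out.append(CharacterScore(j, s, m, g, fit_k=k))
    return out


def ensemble_indices(
    trees: list[PhyloTree] | PhyloTree,
    matrix: CharacterMatrix,
    variant: str = "all",
) -> MatrixScore:
    """Ensemble CI and RI over a set of equally parsimonious trees.

    ``variant="all"`` uses all characters; ``variant="informative"``
    excludes parsimony-uninformative ones (their steps, m and g are removed
    from every sum; per-character steps are taken on the first tree).
    """
    if isinstance(trees, PhyloTree):
        trees = [trees]
    if not trees:
        raise ValueError("no trees given")
    if variant not in ("all", "informative"):
        raise ValueError(f"unknown variant {variant!r}")
    lengths = {tree_length(t, matrix) for t in trees}
    if len(lengths) != 1:
        raise ValueError(f"trees are not equally long: {sorted(lengths)}")
    scores = character_scores(trees[0], matrix)
    if variant == "informative":
        scores = [sc for sc in scores if matrix.is_informative(sc.char_index)]
    L = sum(sc.s for sc in scores)
    sum_m = sum(sc.m for sc in scores)
    sum_g = sum(sc.g for sc in scores)
    return MatrixScore(L, sum_m, sum_g, len(scores), variant)


def implied_fit(tree: PhyloTree, matrix: CharacterMatrix, k: float) -> MatrixScore:
    """Implied-weighting objective F = sum_i h_i/(h_i + k), minimised."""
    if k <= 0:
        raise ValueError("concavity k must be positive")
    scores = character_scores(tree, matrix, k=k)
    return MatrixScore(
        length=sum(sc.s for sc in scores),
        sum_m=sum(sc.m for sc in scores),
        sum_g=sum(sc.g for sc in scores),
        n_characters=len(scores),
        k=k,
        fit_total=sum(sc.fit for sc in scores),
    )


# ---------------------------------------------------------------------------
# Branch length ranges (for zero-length collapsing)
# ---------------------------------------------------------------------------

def branch_length_ranges(
    tree: PhyloTree, matrix: CharacterMatrix
) -> dict[frozenset[str], tuple[int, int]]:
    """Minimum and maximum length of every internal branch over all
    most-parsimonious reconstructions.

    Keys are the tree's non-trivial splits (side not containing the
    reference leaf, as in :meth:`PhyloTree.bipartitions`).  Per character a
    branch carries 0 or 1 change in a given reconstruction; characters
    choose reconstructions independently, so the bounds are per-character
    sums.
    """
    taxa = matrix.taxa
    adj = tree.to_indexed_adjacency(taxa)
    n = matrix.n_taxa
    ref = min(taxa)
    full = frozenset(taxa)

    internal_edges = [
        (u, v) for u, v in _engine.edges_of(adj) if u >= n and v >= n
    ]
    lo = {e: 0 for e in internal_edges}
    hi = {e: 0 for e in internal_edges}
    for j in range(1, matrix.n_characters + 1):
        arity = matrix.characters[j - 1].arity
        D = _directed_costs(adj, _leaf_costs(matrix, j), arity, n)
        for u, v in internal_edges:
            du, dv = D[(u, v)], D[(v, u)]
            overall = min(
                du[s] + dv[t] + (s != t)
                for s in range(arity)
                for t in range(arity)
            )
            same = min(du[s] + dv[s] for s in range(arity))
            diff = min(
                (du[s] + dv[t] + 1 for s in range(arity) for t in range(arity) if s != t),
                default=_INF,
            )
            if same > overall:
                lo[(u, v)] += 1  # every reconstruction changes on this branch
            if diff == overall:
                hi[(u, v)] += 1  # some reconstruction changes on this branch

    # translate edges to label splits
    out: dict[frozenset[str], tuple[int, int]] = {}
    for u, v in internal_edges:
        side = {taxa[i] for i in _leafset_beyond(adj, v, u, n)}
        if ref in side:
            side = set(full) - side
        out[frozenset(side)] = (lo[(u, v)], hi[(u, v)])
    return out


def _leafset_beyond(adj, start: int, blocked: int, n_taxa: int) -> set[int]:
    seen = {blocked, start}
    stack = [start]
    leaves = set()
    while stack:
        x = stack.pop()
        if x < n_taxa:
            leaves.add(x)
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return leaves


# ---------------------------------------------------------------------------
# ACCTRAN optimisation and synapomorphy mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Change:
    """One character-state change on a branch."""

    char_index: int
    from_state: int
    to_state: int
    unique: bool  # the only change of this character on the whole tree
    at_polytomy: bool = False  # parent node is a polytomy (placement ambiguous)


@dataclass
class SynapomorphyMap:
    """Branch -> changes under an ACCTRAN reconstruction.

    Branches are keyed by the descendant leaf set of their child node when
    the tree is rooted on the outgroup; singleton keys are terminal
    branches (autapomorphies).
    """

    outgroup: str
    changes: dict[frozenset[str], list[Change]] = field(default_factory=dict)

    def synapomorphies_of(self, clade: frozenset[str] | set[str]) -> list[Change]:
        return self.changes.get(frozenset(clade), [])

    def characters_of(self, clade: frozenset[str] | set[str]) -> set[int]:
        """Character numbers changing on the stem branch of ``clade``."""
        return {c.char_index for c in self.synapomorphies_of(clade)}

    def total_changes(self, char_index: int) -> int:
        return sum(
            1
            for chs in self.changes.values()
            for c in chs
            if c.char_index == char_index
        )


def acctran_map(
    tree: PhyloTree, matrix: CharacterMatrix, outgroup: str | None = None
) -> SynapomorphyMap:
    """Map character changes onto branches under accelerated transformation.

    The tree is rooted on the outgroup; each character gets a single-state
    assignment at every node realising the minimum number of changes, with
    ambiguities resolved by placing changes as close to the root as
    possible (preferring reversals over parallelisms).  Works on
    multifurcating trees (consensus mapping); changes hanging from a
    polytomy are flagged ``at_polytomy``.  The per-character total number
    of mapped changes equals the character's minimum (conservation).
    """
    og = outgroup or matrix.outgroup
    if og not in tree.leaf_labels:
        raise ValueError(f"outgroup {og!r} is not a leaf of the tree")
    taxa = matrix.taxa
    adj = tree.to_indexed_adjacency(taxa)
    n = matrix.n_taxa
    og_idx = taxa.index(og)
    root = adj[og_idx][0]

    # children orientation away from the root
    order = _engine._postorder(adj, root, og_idx)
    children = {u: tuple(v for v in adj[u] if v != p) for u, p in order}
    children[root] = (og_idx,) + children[root]
    # leaf sets per node (outgroup first: the root's child list includes it)
    leafset: dict[int, frozenset[str]] = {og_idx: frozenset([og])}
    for u, _p in order:
        if u < n:
            leafset[u] = frozenset([taxa[u]])
        else:
            leafset[u] = frozenset().union(*(leafset[c] for c in children[u]))

    ingroup_set = frozenset(taxa) - {og}
    raw: dict[frozenset[str], list[tuple[int, int, int, bool]]] = {}
    counts: dict[int, int] = {}
    for j in range(1, matrix.n_characters + 1):
        arity = matrix.characters[j - 1].arity
        costs = _leaf_costs(matrix, j)
        # downward cost vectors
        down: dict[int, list[int]] = {}
        for u, _p in order:
            vec = list(costs[u]) if u < n else [0] * arity
            for c in children.get(u, ()):
                if c == og_idx:
                    continue
                child = down[c]
                best = min(child)
                vec = [vec[s] + min(child[s], best + 1) for s in range(arity)]
            down[u] = vec
        down[og_idx] = list(costs[og_idx])
        # a virtual root sits on the outgroup's branch; its state prefers
        # the outgroup's own state on ties (plesiomorphic polarity), so the
        # basal-most change is drawn on the ingroup stem, not the outgroup
        ogv = down[og_idx]
        best_og = min(ogv)
        ingv = down[root]  # ingroup-side cost vector (og excluded)
        best_ing = min(ingv)
        vrootv = [
            min(ogv[s], best_og + 1) + min(ingv[s], best_ing + 1)
            for s in range(arity)
        ]
        total = min(vrootv)
        og_states = {s for s in range(arity) if ogv[s] == 0}
        vr_state = min(
            range(arity),
            key=lambda s: (vrootv[s] != total, s not in og_states, s),
        )
        # preorder single-state assignment, ACCTRAN tie-break: prefer a
        # state different from the parent (changes migrate rootward); the
        # outgroup leaf and the ingroup root hang from the virtual root
        VR = -1
        assign: dict[int, int] = {VR: vr_state}
        stack = [(og_idx, VR), (root, VR)]
        changes_j: list[tuple[int, frozenset[str], int, int, bool]] = []
        while stack:
            u, p = stack.pop()
            ps = assign[p]
            vec = down[u]
            cand = min(vec[s] + (s != ps) for s in range(arity))
            state = min(
                range(arity),
                key=lambda s: (vec[s] + (s != ps) != cand, s == ps, s),
            )
            assign[u] = state
            if state != ps:
                key = leafset[u] if u != root else ingroup_set
                poly = p != VR and (
                    len(children.get(p, ())) + (p != root) > 3
                )
                changes_j.append((j, key, ps, state, poly))
            for c in children.get(u, ()):
                if c != og_idx:
                    stack.append((c, u))
        counts[j] = len(changes_j)
        for j_, key, a, b, poly in changes_j:
            raw.setdefault(key, []).append((j_, a, b, poly))

    smap = SynapomorphyMap(outgroup=og)
    for key, lst in raw.items():
        smap.changes[key] = [
            Change(j, a, b, unique=(counts[j] == 1), at_polytomy=poly)
            for j, a, b, poly in sorted(lst)
        ]
    return smap


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def scores_tsv(scores: list[CharacterScore]) -> str:
    """Tab-separated per-character table (character, s, m, g, h, fit)."""
    lines = ["character\ts\tm\tg\th\tfit"]
    for sc in scores:
        fit = f"{sc.fit:.6f}" if sc.fit_k is not None else ""
        lines.append(f"{sc.char_index}\t{sc.s}\t{sc.m}\t{sc.g}\t{sc.h}\t{fit}")
    return "\n".join(lines) + "\n"


def synapomorphy_tsv(smap: SynapomorphyMap) -> str:
    """Per-branch change report keyed by clade leaf sets."""
    lines = ["clade\tcharacter\tfrom\tto\tunique\tat_polytomy"]
    for key in sorted(smap.changes, key=lambda s: (len(s), sorted(s))):
        clade = ",".join(sorted(key))
        for c in smap.changes[key]:
            lines.append(
                f"{clade}\t{c.char_index}\t{c.from_state}\t{c.to_state}"
                f"\t{int(c.unique)}\t{int(c.at_polytomy)}"
            )
    return "\n".join(lines) + "\n"
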