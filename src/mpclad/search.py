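"""Tree search under equal and implied weights, plus Bremer support.

The heuristic follows the classic "traditional search" recipe: per
replicate, a random-addition-sequence starting tree is refined by
branch-swapping (TBR by default; SPR/NNI selectable) accepting the first
improving rearrangement in a seeded-shuffled order, then the plateau of
equal-best trees is explored breadth-first, retaining up to
``hold_per_replicate`` trees.  Suboptimal trees encountered on the way are
buffered (up to ``max_trees``) for Bremer support.  Distinctness of
retained trees is assessed *after* zero-length-branch collapsing.

An exact branch-and-bound search doubles as an oracle for small matrices,
and an exhaustive enumerator backs exact Bremer values on tiny ones.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from . import _engine
from .matrix_io import CharacterMatrix
from .trees import PhyloTree, collapse_zero_length

__all__ = [
    "SearchConfig",
    "SearchResult",
    "CladeSupport",
    "heuristic_search",
    "branch_and_bound",
    "implied_weight_search",
    "bremer_support",
    "exact_bremer",
    "all_binary_trees",
]

_EPS = 1e-9


@dataclass(frozen=True)
class SearchConfig:
    """Settings of a heuristic search (defaults follow common practice for
    small morphological matrices: 100 random-addition replicates, 100 trees
    held per replicate, a 100000-tree buffer, TBR swapping, suboptimal
    retention up to 20 extra steps)."""

    replicates: int = 100
    hold_per_replicate: int = 100
    max_trees: int = 100000
    swapper: str = "tbr"
    weighting: str = "equal"  # "equal" | "implied"
    k: float = 3.0
    suboptimal_margin: int = 20
    seed: int = 0
    collapse_rule: str = "min"

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.hold_per_replicate < 1 or self.max_trees < 1:
            raise ValueError("counts must be positive")
        if self.suboptimal_margin < 0:
            raise ValueError("suboptimal margin must be >= 0")
        if self.swapper not in ("tbr", "spr", "nni"):
            raise ValueError(f"unknown swapper {self.swapper!r}")
        if self.weighting not in ("equal", "implied"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.collapse_rule not in ("min", "max"):
            raise ValueError(f"unknown collapse rule {self.collapse_rule!r}")
        if self.weighting == "implied" and self.k <= 0:
            raise ValueError("concavity k must be positive")


@dataclass
class SearchResult:
    """Outcome of a search: best score, distinct post-collapse optimal
    trees, and (for equal weights) the buffered suboptimal pool used for
    Bremer support, as ``{splits: length}`` over binary pre-collapse trees."""

    best_score: float
    trees: list[PhyloTree]
    config: SearchConfig
    matrix_taxa: list[str]
    pool: dict[tuple, int] = field(default_factory=dict)
    truncated: bool = False
    #: pre-collapse binary optima (ensemble indices are computed on these:
    #: simultaneous MIN-rule collapsing can lengthen a tree)
    binary_trees: list[PhyloTree] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass(frozen=True)
class CladeSupport:
    """Bremer (decay) support of one clade, in steps.  When no pooled tree
    contradicts the clade the value is only a lower bound (``> margin``)."""

    clade: frozenset[str]
    bremer: int
    is_lower_bound: bool = False

    def __str__(self) -> str:
        return f"{'>' if self.is_lower_bound else ''}{self.bremer}"


# ---------------------------------------------------------------------------
# Heuristic search
# ---------------------------------------------------------------------------

def _score_of(raw, pm, weighting, k):
    if weighting == "equal":
        return raw
    return _engine.implied_fit_from_counter(raw, pm, k)


def _key_tuple(adj, n) -> tuple:
    return tuple(sorted(_engine.tree_key(adj, n)))


def heuristic_search(matrix: CharacterMatrix, config: SearchConfig) -> SearchResult:
    """Random-addition + branch-swapping search.

    Deterministic given (matrix, config): every random draw comes from one
    seeded generator.  Returns the distinct post-collapse optimal trees and
    the suboptimal pool (equal weights only).
    """
    if matrix.n_taxa < 4:
        raise ValueError("heuristic search needs at least 4 taxa")
    pm = _engine.PackedMatrix(matrix)
    n = matrix.n_taxa
    rng = random.Random(config.seed)
    counters = config.weighting == "implied"
    margin = config.suboptimal_margin if config.weighting == "equal" else 0

    best: float | None = None
    best_binary: dict[tuple, _engine.Adjacency] = {}
    swept: set[tuple] = set()
    pool: dict[tuple, int] = {}
    truncated = False

    def consider_pool(adj, length: int) -> None:
        nonlocal truncated
        if config.weighting != "equal" or best is None:
            return
        if length <= best + margin:
            if len(pool) >= config.max_trees:
                truncated = True
                return
            pool.setdefault(_key_tuple(adj, n), length)

    for _rep in range(config.replicates):
        order = list(range(n))
        rng.shuffle(order)
        adj = _engine.addition_tree(pm, order, rng)
        raw = (
            _engine.fitch_counter(adj, pm)
            if counters
            else _engine.fitch_length(adj, pm)
        )
        score = _score_of(raw, pm, config.weighting, config.k)

        # hill-climb: first improving rearrangement in shuffled order
        improved = True
        while improved:
            improved = False
            nbrs = _engine.neighbourhood(adj, pm, config.swapper, counters)
            rng.shuffle(nbrs)
            for raw_s, move in nbrs:
                s = _score_of(raw_s, pm, config.weighting, config.k)
                if s < score - _EPS:
                    adj = _engine.apply_move(adj, n, move)
                    score = s
                    improved = True
                    break

        if best is None or score < best - _EPS:
            best = score
            best_binary = {}
            swept = set()
            if config.weighting == "equal":
                pool = {k_: v for k_, v in pool.items() if v <= best + margin}
        if score > best + (margin if config.weighting == "equal" else 0) + _EPS:
            continue

        # plateau exploration from this replicate's tree
        queue = []
        key = _key_tuple(adj, n)
        if config.weighting == "equal":
            pool.setdefault(key, int(score))
        if score <= best + _EPS and key not in best_binary:
            best_binary[key] = adj
            queue.append((key, adj))
        held = 1
        while queue and held < config.hold_per_replicate:
            key, tree = queue.pop(0)
            if key in swept:
                continue
            swept.add(key)
            nbrs = _engine.neighbourhood(tree, pm, config.swapper, counters)
            rng.shuffle(nbrs)
            pool_quota = 50  # bounded per sweep; diversity comes from shuffling
            for raw_s, move in nbrs:
                s = _score_of(raw_s, pm, config.weighting, config.k)
                if s < best - _EPS:
                    # late improvement: restart plateau from the better tree
                    cand = _engine.apply_move(tree, n, move)
                    best = s
                    best_binary = {}
                    swept = set()
                    k2 = _key_tuple(cand, n)
                    best_binary[k2] = cand
                    queue = [(k2, cand)]
                    if config.weighting == "equal":
                        pool = {
                            k_: v for k_, v in pool.items() if v <= best + margin
                        }
                        pool.setdefault(k2, int(s))
                    break
                in_plateau = s <= best + _EPS
                in_margin = config.weighting == "equal" and s <= best + margin
                if not (in_plateau or (in_margin and pool_quota > 0)):
                    continue
                cand = _engine.apply_move(tree, n, move)
                k2 = _key_tuple(cand, n)
                if in_margin:
                    pool_quota -= 1
                    consider_pool(cand, int(s))
                if in_plateau and k2 not in best_binary and held < config.hold_per_replicate:
                    best_binary[k2] = cand
                    held += 1
                    queue.append((k2, cand))

    assert best is not None
    trees = _collapse_distinct(best_binary.values(), matrix, config.collapse_rule)
    return SearchResult(
        best_score=best if counters else int(best),
        trees=trees,
        config=config,
        matrix_taxa=list(matrix.taxa),
        pool=pool,
        truncated=truncated,
        binary_trees=[
            PhyloTree.from_indexed_adjacency(a, matrix.taxa)
            for a in best_binary.values()
        ],
    )


def _collapse_distinct(
    adjs, matrix: CharacterMatrix, rule: str
) -> list[PhyloTree]:
    out: list[PhyloTree] = []
    seen = set()
    for adj in adjs:
        t = PhyloTree.from_indexed_adjacency(adj, matrix.taxa)
        c = collapse_zero_length(t, matrix, rule)
        key = c.bipartitions()
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# Exact search
# ---------------------------------------------------------------------------

def branch_and_bound(
    matrix: CharacterMatrix,
    weighting: str = "equal",
    k: float = 3.0,
    collapse_rule: str = "min",
) -> SearchResult:
    """Provably optimal score and the complete set of distinct
    post-collapse optimal trees (guarded at 16 taxa)."""
    pm = _engine.PackedMatrix(matrix)
    objective = "length" if weighting == "equal" else "fit"
    best, optima = _engine.branch_and_bound(pm, objective=objective, k=k)
    cfg = SearchConfig(weighting=weighting, k=k, collapse_rule=collapse_rule)
    trees = _collapse_distinct(optima, matrix, collapse_rule)
    return SearchResult(
        best_score=best if weighting == "implied" else int(best),
        trees=trees,
        config=cfg,
        matrix_taxa=list(matrix.taxa),
        binary_trees=[
            PhyloTree.from_indexed_adjacency(a, matrix.taxa) for a in optima
        ],
    )


def all_binary_trees(labels: list[str]):
    """Yield every unrooted binary tree on ``labels`` (guarded at 9 leaves:
    135135 trees).  Exhaustive oracle for tiny instances."""
    n = len(labels)
    if n > 9:
        raise ValueError("exhaustive enumeration guarded at 9 leaves")
    if n == 2:
        yield PhyloTree({0: (1,), 1: (0,)}, {0: labels[0], 1: labels[1]})
        return

    def build(adj: dict, depth: int, next_node: int):
        if depth == n:
            yield {u: tuple(vs) for u, vs in adj.items()}
            return
        for u, v in _engine.edges_of(adj):
            yield from build(
                _engine.insert_leaf(adj, depth, (u, v), next_node),
                depth + 1,
                next_node + 1,
            )

    for adj in build(_engine.star_with(0, 1, 2, n), 3, n + 1):
        yield PhyloTree.from_indexed_adjacency(adj, labels)


# ---------------------------------------------------------------------------
# Implied-weights runs
# ---------------------------------------------------------------------------

def implied_weight_search(
    matrix: CharacterMatrix,
    config: SearchConfig,
    k_values: list[float] | None = None,
) -> dict[float, SearchResult]:
    """Independent implied-weights searches, one per concavity value
    (default k = 1..10, integers)."""
    ks = list(k_values) if k_values is not None else [float(i) for i in range(1, 11)]
    out: dict[float, SearchResult] = {}
    for i, k in enumerate(ks):
        cfg = replace(
            config, weighting="implied", k=float(k), seed=config.seed + i
        )
        out[float(k)] = heuristic_search(matrix, cfg)
    return out


# ---------------------------------------------------------------------------
# Bremer support
# ---------------------------------------------------------------------------

def _clade_mask(clade: frozenset[str], taxa: list[str]) -> int:
    full = (1 << len(taxa)) - 1
    m = 0
    for t in clade:
        m |= 1 << taxa.index(t)
    if m & 1:
        m = full & ~m
    return m


def bremer_support(
    matrix: CharacterMatrix,
    clades: list[frozenset[str]],
    result: SearchResult,
) -> list[CladeSupport]:
    """Pool-based Bremer (decay) support.

    For each clade, support = (shortest pooled tree lacking the clade)
    minus the best length.  A clade never contradicted within the pool gets
    its support reported as a lower bound at the suboptimal margin.
    """
    if not result.pool:
        raise ValueError("suboptimal pool is empty; run an equal-weights search")
    taxa = result.matrix_taxa
    best = int(result.best_score)
    margin = result.config.suboptimal_margin
    out = []
    for clade in clades:
        mask = _clade_mask(frozenset(clade), taxa)
        worst = None
        for key, length in result.pool.items():
            if mask not in key:
                if worst is None or length < worst:
                    worst = length
        if worst is None:
            out.append(CladeSupport(frozenset(clade), margin, is_lower_bound=True))
        else:
            out.append(CladeSupport(frozenset(clade), worst - best))
    return out


def exact_bremer(
    matrix: CharacterMatrix,
    clade: frozenset[str],
    outgroup: str | None = None,
) -> int:
    """Exact decay index by exhaustive enumeration (tiny matrices only):
    min length over all trees lacking the clade minus min length overall."""
    from .parsimony import tree_length

    best = None
    best_lacking = None
    for t in all_binary_trees(matrix.taxa):
        L = tree_length(t, matrix)
        if best is None or L < best:
            best = L
        og = outgroup or matrix.outgroup
        present = frozenset(clade) in t.clusters(og)
        if not present and (best_lacking is None or L < best_lacking):
            best_lacking = L
    assert best is not None and best_lacking is not None
    return best_lacking - best
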