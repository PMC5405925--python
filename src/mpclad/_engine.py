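"""Low-level parsimony engine.

Character state sets are packed one 4-bit nibble per character into a single
Python integer (states 0-3 -> bits 0-3 of the nibble; missing/inapplicable
cells carry the full declared state set so they never force a step).  The
Fitch join of two packed sets is a handful of word-wide bit operations
(SWAR), so scoring a whole tree costs ~2n joins regardless of character
count, and a TBR reconnection costs a single join once the two half-tree
root sets are known.

Trees here are *indexed* adjacencies: ``dict[int, tuple[int, ...]]`` with
leaves ``0..n-1`` in matrix taxon order and internal nodes above.  Public,
label-based wrappers live in :mod:`mpclad.parsimony` and
:mod:`mpclad.search`.
"""

from __future__ import annotations

import random

from .matrix_io import CharacterMatrix

Adjacency = dict[int, tuple[int, ...]]

#: A rearrangement descriptor, as produced by :func:`neighbourhood`.
Move = tuple


class PackedMatrix:
    """Leaf state sets of a matrix packed for the SWAR engine."""

    def __init__(self, matrix: CharacterMatrix):
        self.n_taxa = matrix.n_taxa
        self.n_char = matrix.n_characters
        #: bit at position 4*j for every character j
        self.lsb = sum(1 << (4 * j) for j in range(self.n_char))
        self.leaf_sets: list[int] = []
        arities = [c.arity for c in matrix.characters]
        for row in matrix.cells:
            packed = 0
            for j, cell in enumerate(row):
                bits = (1 << cell) if cell >= 0 else (1 << arities[j]) - 1
                packed |= bits << (4 * j)
            self.leaf_sets.append(packed)
        # per-character minimum steps over all trees
        self.min_steps = [
            max(0, len(matrix.observed_states(j + 1)) - 1)
            for j in range(self.n_char)
        ]
        #: per-taxon, per-character observed state (or None), for B&B bounds
        self.states: list[list[int | None]] = [
            [c if c >= 0 else None for c in row] for row in matrix.cells
        ]


def join(a: int, b: int, lsb: int) -> tuple[int, int]:
    """One Fitch node: returns ``(result_set, empty_mask)`` where
    ``empty_mask`` has the nibble-LSB set for every character whose
    intersection was empty (i.e. that incurred one step)."""
    x = a & b
    t = x | (x >> 2)
    t |= t >> 1
    empty = lsb & ~t
    if empty:
        x |= (a | b) & (empty * 15)
    return x, empty


def _postorder(adj: Adjacency, root: int, parent: int) -> list[tuple[int, int]]:
    """Postorder (node, parent) pairs for the subtree at ``root``."""
    out: list[tuple[int, int]] = []
    stack = [(root, parent)]
    while stack:
        u, p = stack.pop()
        out.append((u, p))
        for v in adj[u]:
            if v != p:
                stack.append((v, u))
    out.reverse()
    return out


def fitch_length(
    adj: Adjacency, pm: PackedMatrix, cutoff: int | None = None
) -> int:
    """Total Fitch length of a binary indexed tree.

    With ``cutoff`` the scan aborts once the running total exceeds it (the
    returned value is then only a lower bound > cutoff).
    """
    if len(adj) == 2:
        _, empty = join(pm.leaf_sets[0], pm.leaf_sets[1], pm.lsb)
        return empty.bit_count()
    lsb = pm.lsb
    leaf = next(u for u in adj if u < pm.n_taxa)
    root = adj[leaf][0]
    steps = 0
    sets: dict[int, int] = {}
    for u, p in _postorder(adj, root, leaf):
        if u < pm.n_taxa:
            sets[u] = pm.leaf_sets[u]
            continue
        kids = [v for v in adj[u] if v != p]
        acc = sets[kids[0]]
        for kid in kids[1:]:
            acc, empty = join(acc, sets[kid], lsb)
            steps += empty.bit_count()
        sets[u] = acc
        if cutoff is not None and steps > cutoff:
            return steps
    _, empty = join(sets[root], pm.leaf_sets[leaf], lsb)
    return steps + empty.bit_count()


def fitch_counter(adj: Adjacency, pm: PackedMatrix) -> int:
    """Packed per-character step counts (nibble j = steps of character j;
    at most 15 steps per character, which the n <= 16 guard guarantees)."""
    if len(adj) == 2:
        _, empty = join(pm.leaf_sets[0], pm.leaf_sets[1], pm.lsb)
        return empty
    lsb = pm.lsb
    leaf = next(u for u in adj if u < pm.n_taxa)
    root = adj[leaf][0]
    counter = 0
    sets: dict[int, int] = {}
    for u, p in _postorder(adj, root, leaf):
        if u < pm.n_taxa:
            sets[u] = pm.leaf_sets[u]
            continue
        kids = [v for v in adj[u] if v != p]
        acc = sets[kids[0]]
        for kid in kids[1:]:
            acc, empty = join(acc, sets[kid], lsb)
            counter += empty
        sets[u] = acc
    _, empty = join(sets[root], pm.leaf_sets[leaf], lsb)
    return counter + empty


def nibbles(counter: int, n_char: int) -> list[int]:
    return [(counter >> (4 * j)) & 0xF for j in range(n_char)]


def implied_fit_from_counter(counter: int, pm: PackedMatrix, k: float) -> float:
    """Goloboff fit F = sum_i h_i/(h_i + k), h_i = s_i - m_i; lower is better."""
    if k <= 0:
        raise ValueError("concavity k must be positive")
    f = 0.0
    for j, m in enumerate(pm.min_steps):
        h = ((counter >> (4 * j)) & 0xF) - m
        if h > 0:
            f += h / (h + k)
    return f


# ---------------------------------------------------------------------------
# Tree utilities
# ---------------------------------------------------------------------------

def edges_of(adj: Adjacency) -> list[tuple[int, int]]:
    return [(u, v) for u, vs in adj.items() for v in vs if u < v]


def tree_key(adj: Adjacency, n_taxa: int) -> frozenset[int]:
    """Canonical identity: the set of non-trivial splits as leaf bitmasks of
    the side not containing leaf 0."""
    full = (1 << n_taxa) - 1
    masks = []
    sides: dict[tuple[int, int], int] = {}
    # compute each directed side mask bottom-up
    for u, v in edges_of(adj):
        for x, y in ((u, v), (v, u)):
            if (x, y) in sides:
                continue
            for a, b in _postorder(adj, x, y):
                m = (1 << a) if a < n_taxa else 0
                for c in adj[a]:
                    if c != b:
                        m |= sides[(c, a)]
                sides[(a, b)] = m
    for u, v in edges_of(adj):
        m = sides[(v, u)]
        if m & 1:
            m = full & ~m
        if 2 <= m.bit_count() <= n_taxa - 2:
            masks.append(m)
    return frozenset(masks)


def star_with(a: int, b: int, c: int, centre: int) -> Adjacency:
    return {a: (centre,), b: (centre,), c: (centre,), centre: (a, b, c)}


def insert_leaf(
    adj: Adjacency, leaf: int, edge: tuple[int, int], new_node: int
) -> Adjacency:
    """New adjacency with ``leaf`` attached by subdividing ``edge``."""
    u, v = edge
    out = dict(adj)
    out[u] = tuple(x if x != v else new_node for x in adj[u])
    out[v] = tuple(x if x != u else new_node for x in adj[v])
    out[new_node] = (u, v, leaf)
    out[leaf] = (new_node,)
    return out


def _directed_sets(
    adj: Adjacency, pm: PackedMatrix, counters: bool
) -> dict[tuple[int, int], tuple[int, int]]:
    """``S[(x, y)] = (set, steps)`` of the side containing ``x`` when edge
    (x, y) is cut, Fitch-rooted at ``x``.  ``steps`` is a packed counter
    when ``counters`` is true."""
    lsb = pm.lsb
    S: dict[tuple[int, int], tuple[int, int]] = {}
    for u, v in edges_of(adj):
        for x, y in ((u, v), (v, u)):
            if (x, y) in S:
                continue
            for a, b in _postorder(adj, x, y):
                if a < pm.n_taxa and len(adj[a]) == 1:
                    S[(a, b)] = (pm.leaf_sets[a], 0)
                    continue
                kids = [c for c in adj[a] if c != b]
                if not kids:  # leaf-like endpoint of a 2-node component
                    S[(a, b)] = (pm.leaf_sets[a], 0)
                    continue
                acc, tot = S[(kids[0], a)]
                for c in kids[1:]:
                    s2, t2 = S[(c, a)]
                    acc, empty = join(acc, s2, lsb)
                    tot += t2 + (empty if counters else empty.bit_count())
                S[(a, b)] = (acc, tot)
    return S


# ---------------------------------------------------------------------------
# TBR / SPR / NNI neighbourhoods
# ---------------------------------------------------------------------------

class _Component:
    """One side of a bisected tree, with a virtual-root (set, steps) for
    every reattachment edge."""

    __slots__ = ("single_leaf", "node", "adj", "edges", "mid", "stub")

    def __init__(
        self, full: Adjacency, cut_from: int, cut_to: int, pm: PackedMatrix,
        counters: bool,
    ):
        self.node = cut_from
        self.single_leaf = cut_from < pm.n_taxa
        if self.single_leaf:
            self.adj = {cut_from: ()}
            self.stub = (cut_from, cut_from)
            self.edges = [self.stub]
            self.mid = {self.stub: (pm.leaf_sets[cut_from], 0)}
            return
        # component nodes, with cut_from suppressed
        nodes = set()
        stack = [cut_from]
        seen = {cut_to}
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            nodes.add(x)
            stack.extend(full[x])
        a1, a2 = (x for x in full[cut_from] if x != cut_to)
        comp: Adjacency = {}
        for x in nodes:
            if x == cut_from:
                continue
            nb = []
            for y in full[x]:
                if y == cut_from:
                    nb.append(a2 if x == a1 else a1)
                elif y in nodes:
                    nb.append(y)
            comp[x] = tuple(nb)
        self.adj = comp
        self.stub = (a1, a2) if a1 < a2 else (a2, a1)
        self.edges = edges_of(comp)
        S = _directed_sets(comp, pm, counters)
        lsb = pm.lsb
        self.mid = {}
        for u, v in self.edges:
            s1, t1 = S[(u, v)]
            s2, t2 = S[(v, u)]
            acc, empty = join(s1, s2, lsb)
            self.mid[(u, v)] = (
                acc, t1 + t2 + (empty if counters else empty.bit_count())
            )


def neighbourhood(
    adj: Adjacency,
    pm: PackedMatrix,
    swapper: str = "tbr",
    counters: bool = False,
) -> list[tuple[int, Move]]:
    """Score every rearrangement of a binary tree under the given swapper.

    Returns ``(score, move)`` pairs where ``score`` is the rearranged
    tree's total length (or packed per-character counter when ``counters``)
    and ``move`` feeds :func:`apply_move`.  The identity rearrangement is
    omitted.  TBR bisects at every edge and reconnects any edge pair; SPR
    fixes the pruned side's own attachment point; NNI swaps subtrees across
    internal edges only.
    """
    if swapper not in ("tbr", "spr", "nni"):
        raise ValueError(f"unknown swapper {swapper!r}")
    if swapper == "nni":
        return _nni_neighbourhood(adj, pm, counters)
    lsb = pm.lsb
    out: list[tuple[int, Move]] = []
    for u, v in edges_of(adj):
        c1 = _Component(adj, u, v, pm, counters)
        c2 = _Component(adj, v, u, pm, counters)
        for ea in c1.edges:
            sa, ta = c1.mid[ea]
            a_is_stub = ea == c1.stub
            for eb in c2.edges:
                if a_is_stub and eb == c2.stub:
                    continue  # recreates the original tree
                if swapper == "spr" and not (a_is_stub or eb == c2.stub):
                    continue
                sb, tb = c2.mid[eb]
                _, empty = join(sa, sb, lsb)
                score = ta + tb + (empty if counters else empty.bit_count())
                out.append((score, ("tbr", (u, v), ea, eb)))
    return out


def _nni_neighbourhood(
    adj: Adjacency, pm: PackedMatrix, counters: bool
) -> list[tuple[int, Move]]:
    out: list[tuple[int, Move]] = []
    for u, v in edges_of(adj):
        if u < pm.n_taxa or v < pm.n_taxa:
            continue
        xs = [x for x in adj[u] if x != v]
        ys = [y for y in adj[v] if y != u]
        for ynew in ys:
            cand = _swap_across(adj, u, v, xs[0], ynew)
            score = (
                fitch_counter(cand, pm) if counters else fitch_length(cand, pm)
            )
            out.append((score, ("nni", u, v, xs[0], ynew)))
    return out


def _swap_across(adj: Adjacency, u: int, v: int, x: int, y: int) -> Adjacency:
    out = dict(adj)
    out[u] = tuple(y if z == x else z for z in adj[u])
    out[v] = tuple(x if z == y else z for z in adj[v])
    out[x] = tuple(v if z == u else z for z in adj[x])
    out[y] = tuple(u if z == v else z for z in adj[y])
    return out


def apply_move(adj: Adjacency, n_taxa: int, move: Move) -> Adjacency:
    """Materialise a rearrangement described by :func:`neighbourhood`."""
    if move[0] == "nni":
        _, u, v, x, y = move
        return _swap_across(adj, u, v, x, y)
    _, (u, v), ea, eb = move
    out = {x: list(ys) for x, ys in adj.items()}
    out[u].remove(v)
    out[v].remove(u)
    spares: list[int] = []

    def suppress(x: int) -> bool:
        """Suppress a now-degree-2 internal node; False if x is a leaf."""
        if x < n_taxa:
            return False
        a1, a2 = out[x]
        out[a1] = [a2 if z == x else z for z in out[a1]]
        out[a2] = [a1 if z == x else z for z in out[a2]]
        out[x] = []
        spares.append(x)
        return True

    u_internal = suppress(u)
    v_internal = suppress(v)

    def junction(point: int, edge: tuple[int, int], internal: bool) -> int:
        if not internal:
            return point  # single-leaf component: attach the leaf itself
        mid = spares.pop()
        a, b = edge
        out[a] = [mid if z == b else z for z in out[a]]
        out[b] = [mid if z == a else z for z in out[b]]
        out[mid] = [a, b]
        return mid

    p1 = junction(u, ea, u_internal)
    p2 = junction(v, eb, v_internal)
    out[p1].append(p2)
    out[p2].append(p1)
    return {x: tuple(ys) for x, ys in out.items() if ys}


# ---------------------------------------------------------------------------
# Stepwise addition
# ---------------------------------------------------------------------------

def addition_tree(
    pm: PackedMatrix, order: list[int], rng: random.Random
) -> Adjacency:
    """Greedy stepwise-addition tree: each taxon goes to the edge whose
    insertion adds the fewest steps (ties broken at random)."""
    if len(order) < 3:
        raise ValueError("need at least 3 taxa")
    n = pm.n_taxa
    adj = star_with(order[0], order[1], order[2], n)
    next_node = n + 1
    for leaf in order[3:]:
        best: list[tuple[int, int]] = []
        best_len: int | None = None
        for edge in edges_of(adj):
            cand = insert_leaf(adj, leaf, edge, next_node)
            length = fitch_length(cand, pm)
            if best_len is None or length < best_len:
                best_len = length
                best = [edge]
            elif length == best_len:
                best.append(edge)
        adj = insert_leaf(adj, leaf, best[rng.randrange(len(best))], next_node)
        next_node += 1
    return adj


# ---------------------------------------------------------------------------
# Branch and bound
# ---------------------------------------------------------------------------

def branch_and_bound(
    pm: PackedMatrix,
    upper: float | None = None,
    objective: str = "length",
    k: float = 3.0,
    max_optimal: int = 100000,
) -> tuple[float, list[Adjacency]]:
    """Exact search: provably optimal score and *all* optimal binary trees.

    Taxa are added one at a time (most completely scored first); a partial
    tree is pruned when its length plus the number of states still absent
    from the current taxon subset already exceeds the best known score.
    ``objective`` is ``"length"`` (equal weights) or ``"fit"`` (implied
    weighting with concavity ``k``; the bound uses monotonicity of the fit
    in added steps).  Guarded at n <= 16.
    """
    n = pm.n_taxa
    if n > 16:
        raise ValueError(f"branch-and-bound guarded at 16 taxa (got {n})")
    if objective not in ("length", "fit"):
        raise ValueError(f"unknown objective {objective!r}")
    if n < 4:
        adj: Adjacency = (
            {0: (1,), 1: (0,)} if n == 2 else star_with(0, 1, 2, n)
        )
        return _score_tree(adj, pm, objective, k), [adj]

    order = _addition_order(pm)
    remaining = [[0] * 4 for _ in range(pm.n_char)]
    current = [[0] * 4 for _ in range(pm.n_char)]
    for i in order[3:]:
        for j, s in enumerate(pm.states[i]):
            if s is not None:
                remaining[j][s] += 1
    for i in order[:3]:
        for j, s in enumerate(pm.states[i]):
            if s is not None:
                current[j][s] += 1

    if upper is None:
        start = addition_tree(pm, list(range(n)), random.Random(0))
        upper = _score_tree(start, pm, objective, k)
    best = float(upper)
    optima: list[Adjacency] = []
    seen: set[frozenset[int]] = set()
    eps = 1e-9

    def recurse(adj: Adjacency, depth: int, next_node: int) -> None:
        nonlocal best, optima, seen
        if depth == n:
            score = _score_tree(adj, pm, objective, k)
            if score < best - eps:
                best = score
                optima = []
                seen = set()
            if score <= best + eps and len(optima) < max_optimal:
                key = tree_key(adj, n)
                if key not in seen:
                    seen.add(key)
                    optima.append(adj)
            return
        leaf = order[depth]
        for j, s in enumerate(pm.states[leaf]):
            if s is not None:
                remaining[j][s] -= 1
                current[j][s] += 1
        lbs = [
            sum(1 for s in range(4) if rc[s] > 0 and cc[s] == 0)
            for rc, cc in zip(remaining, current)
        ]
        lb_total = sum(lbs)
        for edge in edges_of(adj):
            cand = insert_leaf(adj, leaf, edge, next_node)
            if objective == "length":
                partial = fitch_length(cand, pm, cutoff=int(best + eps))
                if partial + lb_total <= best + eps:
                    recurse(cand, depth + 1, next_node + 1)
            else:
                counter = fitch_counter(cand, pm)
                bound = 0.0
                for j, m in enumerate(pm.min_steps):
                    h = ((counter >> (4 * j)) & 0xF) + lbs[j] - m
                    if h > 0:
                        bound += h / (h + k)
                if bound <= best + eps:
                    recurse(cand, depth + 1, next_node + 1)
        for j, s in enumerate(pm.states[leaf]):
            if s is not None:
                remaining[j][s] += 1
                current[j][s] -= 1

    recurse(star_with(order[0], order[1], order[2], n), 3, n + 1)
    return best, optima


def _addition_order(pm: PackedMatrix) -> list[int]:
    """Conflict-rich taxa first: start from the most distant pair, then
    greedily add the taxon with the largest summed Hamming distance to the
    chosen set.  Early conflict makes the length bound bite much sooner."""
    n = pm.n_taxa

    def dist(a: int, b: int) -> int:
        return sum(
            1
            for x, y in zip(pm.states[a], pm.states[b])
            if x is not None and y is not None and x != y
        )

    d = [[dist(a, b) for b in range(n)] for a in range(n)]
    _, a, b = max((d[a][b], a, b) for a in range(n) for b in range(n) if a < b)
    chosen = [a, b]
    rest = [i for i in range(n) if i not in chosen]
    while rest:
        nxt = max(rest, key=lambda i: (sum(d[i][x] for x in chosen), -i))
        chosen.append(nxt)
        rest.remove(nxt)
    return chosen


def _score_tree(
    adj: Adjacency, pm: PackedMatrix, objective: str, k: float
) -> float:
    if objective == "length":
        return float(fitch_length(adj, pm))
    return implied_fit_from_counter(fitch_counter(adj, pm), pm, k)
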