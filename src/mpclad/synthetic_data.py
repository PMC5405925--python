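"""Synthetic morphological matrices with known generating structure.

The generator plants evolution on a known tree so that every quantity the
pipeline later estimates is known exactly:

* each character receives ``arity - 1`` baseline changes, every one
  introducing a brand-new state, so its minimum steps ``m`` equal its
  observed-state count minus one *by construction*;
* homoplasy is planted as ``extra_steps`` explicit re-introductions of
  already-used states, each verified (by rescoring the character on the
  generating tree) to add exactly one step — so on the generating tree
  ``L = sum(m) + E`` and ``CI = sum(m)/(sum(m)+E)`` exactly;
* designated clades get dedicated synapomorphy characters whose defining
  change sits on the clade's stem branch, and no other character is allowed
  an event on a planted stem;
* missing cells are injected at a target fraction but placed so that no
  character's step count or observed state set changes (rejection
  sampling), keeping the bookkeeping exact;
* hierarchically inapplicable characters are overwritten with the
  inapplicable code wherever their controlling character's *true* simulated
  state disallows them (e.g. organ-shape characters when the organ is
  absent).

A rate-based Mk-style mode (``mode="mk"``) exists for realism checks; it
keeps no exact bookkeeping and is excluded from exact-value tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .matrix_io import (
    INAPPLICABLE,
    MISSING,
    CharacterDefinition,
    CharacterMatrix,
)
from .trees import PhyloTree, contains_clade, random_binary_tree, strict_consensus

__all__ = [
    "PlantedClade",
    "SimulationConfig",
    "TruthRecord",
    "simulate_matrix",
    "recovery_experiment",
    "RecoveryReport",
]


@dataclass(frozen=True)
class PlantedClade:
    """A clade to plant, with the 1-based characters dedicated to it."""

    taxa: frozenset[str]
    characters: tuple[int, ...]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated matrix.

    Defaults emulate a small fossil-insect matrix: 14 taxa, 39 mostly
    binary characters, planted homoplasy targeting an ensemble CI of about
    0.6 on the generating tree, and a 20% missing-data fraction.
    """

    n_taxa: int = 14
    n_characters: int = 39
    #: sampling weights for character arities 2/3/4
    arity_weights: dict[int, float] = field(
        default_factory=lambda: {2: 0.85, 3: 0.12, 4: 0.03}
    )
    #: explicit per-character arities (overrides arity_weights)
    arities: list[int] | None = None
    char_labels: list[str] | None = None
    taxa: list[str] | None = None
    generating_tree: PhyloTree | str = "random"
    #: total planted homoplasious extra steps E
    extra_steps: int = 30
    missing_fraction: float = 0.2
    #: (controlling char, required state, dependent char), 1-based
    inapplicable_links: list[tuple[int, int, int]] = field(default_factory=list)
    planted_clades: list[PlantedClade] = field(default_factory=list)
    #: probability a baseline change lands on a pendant branch
    #: (creating an autapomorphy for binary characters)
    pendant_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extra_steps < 0:
            raise ValueError("extra_steps must be >= 0")
        if not 0 <= self.missing_fraction <= 1:
            raise ValueError("missing_fraction must be in [0, 1]")


@dataclass
class TruthRecord:
    """Exact bookkeeping of one simulated matrix."""

    tree: PhyloTree
    outgroup: str
    #: per character: list of (clade-below-edge, introduced state)
    events: dict[int, list[tuple[frozenset[str], int]]]
    sum_m: int
    sum_g: int
    extra_steps: int  # E actually planted (all verified to add one step)
    per_char_steps: dict[int, int]  # s on the generating tree
    missing_cells: int
    planted: dict[frozenset[str], tuple[int, ...]]

    @property
    def expected_ci(self) -> float:
        """CI on the generating tree implied by the bookkeeping."""
        return self.sum_m / (self.sum_m + self.extra_steps)

    def as_text(self) -> str:
        lines = [
            f"outgroup\t{self.outgroup}",
            f"sum_m\t{self.sum_m}",
            f"sum_g\t{self.sum_g}",
            f"extra_steps\t{self.extra_steps}",
            f"missing_cells\t{self.missing_cells}",
            f"expected_ci\t{self.expected_ci:.6f}",
        ]
        for clade, chars in sorted(self.planted.items(), key=lambda x: sorted(x[0])):
            lines.append(
                "planted\t" + ",".join(sorted(clade)) + "\t"
                + ",".join(map(str, chars))
            )
        for j in sorted(self.events):
            for clade, state in self.events[j]:
                lines.append(
                    f"event\t{j}\t{state}\t" + ",".join(sorted(clade))
                )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------


def _rooted_edges(tree: PhyloTree, outgroup: str):
    """(child_node, leafset, is_pendant) for every branch except the
    outgroup's own, rooted on the outgroup."""
    root, children, labels = tree.rooted_at(outgroup)
    og_node = next(u for u, l in labels.items() if l == outgroup)
    leafset: dict[int, frozenset[str]] = {}

    def walk(u):
        if u in labels:
            leafset[u] = frozenset([labels[u]])
        else:
            leafset[u] = frozenset().union(*(walk(v) for v in children[u]))
        return leafset[u]

    for v in children[root]:
        if v != og_node:
            walk(v)
    out = []
    for u, ls in leafset.items():
        out.append((u, ls, u in labels))
    return root, children, labels, og_node, out


def _leaf_states(
    children, labels, root, og_node, events: list[tuple[int, int]]
) -> dict[str, int]:
    """Leaf states given events keyed by child node (root state 0)."""
    by_node = dict(events)
    states: dict[str, int] = {labels[og_node]: by_node.get(og_node, 0)}
    stack = [(v, 0) for v in children[root] if v != og_node]
    while stack:
        u, s = stack.pop()
        s = by_node.get(u, s)
        if u in labels:
            states[labels[u]] = s
        else:
            stack.extend((v, s) for v in children[u])
    return states


def _char_steps_on_tree(
    tree_adj_cache, column: list[int], arity: int, tree: PhyloTree, taxa: list[str]
) -> int:
    """Sankoff steps of one column on the generating tree."""
    from . import parsimony

    key = id(tree)
    if key not in tree_adj_cache:
        tree_adj_cache[key] = tree.to_indexed_adjacency(taxa)
    adj = tree_adj_cache[key]
    costs = []
    for cell in column:
        if cell >= 0:
            costs.append([0 if s == cell else parsimony._INF for s in range(arity)])
        else:
            costs.append([0] * arity)
    return parsimony._char_min_on_tree(adj, costs, arity, len(taxa))


def simulate_matrix(
    config: SimulationConfig, mode: str = "planted"
) -> tuple[CharacterMatrix, TruthRecord]:
    """Simulate a matrix with exact truth bookkeeping (``mode="planted"``)
    or by a simple Mk-style process (``mode="mk"``, no bookkeeping)."""
    rng = random.Random(config.seed)
    n, ncha = config.n_taxa, config.n_characters
    taxa = list(config.taxa) if config.taxa else [f"t{i + 1:02d}" for i in range(n)]
    if len(taxa) != n:
        raise ValueError("taxa list does not match n_taxa")
    outgroup = taxa[0]

    if isinstance(config.generating_tree, PhyloTree):
        tree = config.generating_tree
        if sorted(tree.leaf_labels) != sorted(taxa):
            raise ValueError("generating tree leaves do not match taxa")
    else:
        tree = random_binary_tree(taxa, rng)

    for pc in config.planted_clades:
        if not contains_clade(tree, pc.taxa, outgroup):
            raise ValueError(
                f"planted clade {sorted(pc.taxa)} absent from generating tree"
            )

    # character arities
    if config.arities is not None:
        arities = list(config.arities)
        if len(arities) != ncha:
            raise ValueError("arities list does not match n_characters")
    else:
        choices, weights = zip(*sorted(config.arity_weights.items()))
        arities = rng.choices(choices, weights=weights, k=ncha)
    planted_chars = {
        j: pc for pc in config.planted_clades for j in pc.characters
    }
    for j, pc in planted_chars.items():
        if not 1 <= j <= ncha:
            raise ValueError(f"planted character {j} out of range")

    root, children, labels, og_node, edges = _rooted_edges(tree, outgroup)
    node_of_clade = {ls: u for u, ls, _p in edges}
    stem_nodes = {
        node_of_clade[pc.taxa] for pc in config.planted_clades
    }
    internal_edges = [u for u, ls, pend in edges if not pend]
    free_internal = [u for u in internal_edges if u not in stem_nodes]
    pendant_edges = [u for u, ls, pend in edges if pend]
    leafset_of = {u: ls for u, ls, _p in edges}

    if mode == "mk":
        return _simulate_mk(config, tree, taxa, outgroup, arities, rng), None

    if mode != "planted":
        raise ValueError(f"unknown mode {mode!r}")

    cache: dict = {}
    columns: list[list[int]] = []
    events: dict[int, list[tuple[frozenset[str], int]]] = {}
    node_events: dict[int, list[tuple[int, int]]] = {}
    controllers = {ctrl for ctrl, _r, _d in config.inapplicable_links}
    dependents = {dep: (ctrl, req) for ctrl, req, dep in config.inapplicable_links}
    if set(dependents) & set(planted_chars):
        raise ValueError("a planted synapomorphy character cannot be dependent")

    def place_baseline(j: int) -> list[tuple[int, int]]:
        """Baseline events for character j: arity-1 new-state changes."""
        arity = arities[j - 1]
        pc = planted_chars.get(j)
        for _attempt in range(200):
            ev: list[tuple[int, int]] = []
            used_nodes = set()
            if pc is not None:
                stem = node_of_clade[pc.taxa]
                ev.append((stem, 1))
                used_nodes.add(stem)
            while len(ev) < arity - 1:
                if pc is not None:
                    # keep the synapomorphy clean: avoid the clade's interior
                    # and every planted stem
                    candidates = [
                        u
                        for u in internal_edges
                        if u not in used_nodes
                        and u not in stem_nodes
                        and not leafset_of[u] < pc.taxa
                    ]
                else:
                    pool = (
                        pendant_edges
                        if rng.random() < config.pendant_fraction
                        else free_internal
                    )
                    candidates = [u for u in pool if u not in used_nodes]
                if not candidates:
                    break
                u = rng.choice(candidates)
                used_nodes.add(u)
                ev.append((u, len(ev) + 1))
            if len(ev) != arity - 1:
                continue
            states = _leaf_states(children, labels, root, og_node, ev)
            observed = set(states.values())
            if len(observed) != arity:
                continue
            if pc is not None:
                inside = {states[t] for t in pc.taxa}
                outside = {states[t] for t in taxa if t not in pc.taxa}
                if inside != {1} or 1 in outside:
                    continue
            return ev
        raise RuntimeError(f"could not place baseline changes for character {j}")

    def overwrite_inapplicable(j: int, col: list[int]) -> list[int]:
        """Apply the controlling-character mask to a dependent column."""
        if j not in dependents:
            return col
        ctrl, req = dependents[j]
        ctrl_col = columns[ctrl - 1]
        return [
            INAPPLICABLE if ctrl_col[i] != req else c for i, c in enumerate(col)
        ]

    # Baseline placement: controllers first (dependents need their states),
    # then dependents with the inapplicable mask applied and verified.
    order_js = sorted(range(1, ncha + 1), key=lambda j: j in dependents)
    per_char_m = {}
    per_char_steps = {}
    for j in order_js:
        arity = arities[j - 1]
        for _attempt in range(200):
            ev = place_baseline(j)
            states = _leaf_states(children, labels, root, og_node, ev)
            col = overwrite_inapplicable(j, [states[t] for t in taxa])
            observed = {c for c in col if c >= 0}
            if len(observed) < 2:
                continue  # masked to (near-)constancy; re-place
            steps = _char_steps_on_tree(cache, col, arity, tree, taxa)
            if steps != len(observed) - 1:
                continue  # mask absorbed part of a change unevenly
            break
        else:
            raise RuntimeError(f"could not place character {j} under its mask")
        node_events[j] = ev
        while len(columns) < j:
            columns.append([])
        columns[j - 1] = col
        events[j] = [(leafset_of[u], s) for u, s in ev]
        per_char_m[j] = len(observed) - 1
        per_char_steps[j] = steps

    # plant E homoplasious extra steps, each verified to add exactly one step
    eligible = [
        j
        for j in range(1, ncha + 1)
        if j not in planted_chars and j not in controllers
    ]
    planted_extra = 0
    attempts = 0
    while planted_extra < config.extra_steps and attempts < 5000:
        attempts += 1
        j = rng.choice(eligible)
        arity = arities[j - 1]
        used = {u for u, _s in node_events[j]}
        candidates = [
            u for u in internal_edges + pendant_edges
            if u not in used and u not in stem_nodes
        ]
        if not candidates:
            continue
        u = rng.choice(candidates)
        cur_obs = {c for c in columns[j - 1] if c >= 0}
        state = rng.choice(sorted(cur_obs))  # re-introduce an existing state
        ev = node_events[j] + [(u, state)]
        states = _leaf_states(children, labels, root, og_node, ev)
        col = overwrite_inapplicable(j, [states[t] for t in taxa])
        if {c for c in col if c >= 0} != cur_obs:
            continue  # must not change the observed state set (nor m)
        steps = _char_steps_on_tree(cache, col, arity, tree, taxa)
        if steps != per_char_steps[j] + 1:
            continue  # absorbed or worse; try elsewhere
        node_events[j] = ev
        events[j].append((leafset_of[u], state))
        columns[j - 1] = col
        per_char_steps[j] = steps
        planted_extra += 1
    if planted_extra < config.extra_steps:
        raise RuntimeError(
            f"could only plant {planted_extra} of {config.extra_steps} extra steps"
        )

    cells = [[columns[j][i] for j in range(ncha)] for i in range(n)]

    def column_of(j):
        return [cells[i][j - 1] for i in range(n)]

    # missing data: stochastic-rounded global count, placed without
    # changing any character's step count or observed state set
    total_cells = n * ncha
    target = config.missing_fraction * total_cells
    n_missing = int(target) + (1 if rng.random() < target - int(target) else 0)
    protected_cols = set(planted_chars)
    candidates = [
        (i, j)
        for i in range(1, n)  # outgroup row protected
        for j in range(1, ncha + 1)
        if j not in protected_cols and cells[i][j - 1] != INAPPLICABLE
    ]
    rng.shuffle(candidates)
    placed = 0
    for i, j in candidates:
        if placed >= n_missing:
            break
        old = cells[i][j - 1]
        col = column_of(j)
        observed_before = {c for c in col if c >= 0}
        cells[i][j - 1] = MISSING
        col2 = column_of(j)
        observed_after = {c for c in col2 if c >= 0}
        ok = observed_after == observed_before
        if ok:
            ok = (
                _char_steps_on_tree(cache, col2, arities[j - 1], tree, taxa)
                == per_char_steps[j]
            )
        if ok:
            placed += 1
        else:
            cells[i][j - 1] = old
    missing_cells = placed

    chars = []
    for j in range(1, ncha + 1):
        label = (
            config.char_labels[j - 1]
            if config.char_labels is not None
            else f"char {j}"
        )
        controlling = None
        for ctrl, req, dep in config.inapplicable_links:
            if dep == j:
                controlling = (ctrl, req)
        chars.append(
            CharacterDefinition(
                index=j,
                label=label,
                states=tuple(str(s) for s in range(arities[j - 1])),
                controlling=controlling,
            )
        )
    matrix = CharacterMatrix(taxa, chars, cells, outgroup)

    from .parsimony import min_max_steps

    sum_m = sum(min_max_steps(matrix, j)[0] for j in range(1, ncha + 1))
    sum_g = sum(min_max_steps(matrix, j)[1] for j in range(1, ncha + 1))
    truth = TruthRecord(
        tree=tree,
        outgroup=outgroup,
        events=events,
        sum_m=sum_m,
        sum_g=sum_g,
        extra_steps=planted_extra,
        per_char_steps=dict(per_char_steps),
        missing_cells=missing_cells,
        planted={pc.taxa: tuple(pc.characters) for pc in config.planted_clades},
    )
    return matrix, truth


def _simulate_mk(config, tree, taxa, outgroup, arities, rng) -> CharacterMatrix:
    """Simple Mk-style simulation: per-branch change probability, uniform
    target state.  No truth bookkeeping."""
    root, children, labels, og_node, edges = _rooted_edges(tree, outgroup)
    n, ncha = config.n_taxa, config.n_characters
    p_change = min(0.9, (sum(arities) / ncha - 1 + config.extra_steps / ncha) / (2 * n - 3))
    cells = [[0] * ncha for _ in range(n)]
    tindex = {t: i for i, t in enumerate(taxa)}
    for j in range(1, ncha + 1):
        arity = arities[j - 1]
        stack = [(v, 0) for v in children[root] if v != og_node]
        cells[tindex[outgroup]][j - 1] = 0
        while stack:
            u, s = stack.pop()
            if rng.random() < p_change:
                s = rng.choice([x for x in range(arity) if x != s])
            if u in labels:
                cells[tindex[labels[u]]][j - 1] = s
            else:
                stack.extend((v, s) for v in children[u])
    for i in range(1, n):
        for j in range(ncha):
            if rng.random() < config.missing_fraction:
                cells[i][j] = MISSING
    chars = [
        CharacterDefinition(index=j, states=tuple(str(s) for s in range(arities[j - 1])))
        for j in range(1, ncha + 1)
    ]
    return CharacterMatrix(taxa, chars, cells, outgroup)


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Aggregate outcome of repeated simulate -> search -> map pipelines."""

    n_replicates: int
    clade_recovery: dict[frozenset[str], float]  # fraction of replicates
    synapomorphy_jaccard: dict[frozenset[str], float]  # mean overlap

    @property
    def mean_recovery(self) -> float:
        vals = list(self.clade_recovery.values())
        return sum(vals) / len(vals) if vals else float("nan")


def recovery_experiment(
    config: SimulationConfig,
    n_replicates: int = 10,
    search_replicates: int = 10,
) -> RecoveryReport:
    """Run the full pipeline on fresh simulated matrices and report how
    often each planted clade is recovered in the strict consensus, and how
    well ACCTRAN-mapped stem synapomorphies match the planted ones
    (Jaccard overlap; 0 when the clade is not recovered)."""
    from .parsimony import acctran_map
    from .search import SearchConfig, heuristic_search

    if not config.planted_clades:
        raise ValueError("recovery experiment needs planted clades")
    hits = {pc.taxa: 0 for pc in config.planted_clades}
    jacc = {pc.taxa: 0.0 for pc in config.planted_clades}
    for rep in range(n_replicates):
        cfg = SimulationConfig(**{**config.__dict__, "seed": config.seed + rep})
        matrix, _truth = simulate_matrix(cfg)
        res = heuristic_search(
            matrix,
            SearchConfig(replicates=search_replicates, seed=config.seed + rep),
        )
        cons = strict_consensus(res.trees)
        smap = acctran_map(cons, matrix, matrix.outgroup)
        for pc in config.planted_clades:
            if contains_clade(cons, pc.taxa, matrix.outgroup):
                hits[pc.taxa] += 1
                mapped = smap.characters_of(pc.taxa)
                planted = set(pc.characters)
                union = mapped | planted
                jacc[pc.taxa] += len(mapped & planted) / len(union) if union else 1.0
    return RecoveryReport(
        n_replicates=n_replicates,
        clade_recovery={c: h / n_replicates for c, h in hits.items()},
        synapomorphy_jaccard={c: j / n_replicates for c, j in jacc.items()},
    )
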