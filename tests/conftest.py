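"""Shared fixtures and brute-force oracles."""

from __future__ import annotations

import itertools
import random

import pytest

from mpclad import _engine
from mpclad.matrix_io import MISSING, CharacterDefinition, CharacterMatrix
from mpclad.datasets import synthetic_aphid_matrix


@pytest.fixture(scope="session")
def aphid():
    """The bundled synthetic 14 x 39 example matrix and its truth record."""
    return synthetic_aphid_matrix()


def make_random_matrix(
    n_taxa: int,
    n_char: int,
    rng: random.Random,
    missing: float = 0.15,
    arities=(2, 2, 2, 3, 4),
) -> CharacterMatrix:
    """Unstructured random matrix (no planted signal)."""
    chars, cells = [], [[0] * n_char for _ in range(n_taxa)]
    for j in range(n_char):
        arity = rng.choice(arities)
        chars.append(
            CharacterDefinition(index=j + 1, states=tuple("0123"[:arity]))
        )
        for i in range(n_taxa):
            cells[i][j] = (
                MISSING if rng.random() < missing else rng.randrange(arity)
            )
    return CharacterMatrix(
        [f"t{i:02d}" for i in range(n_taxa)], chars, cells
    )


def brute_force_char_steps(adj, n_taxa: int, column, arity: int) -> int:
    """Minimum changes of one character on an indexed tree, by exhaustive
    enumeration of all internal-node (and missing-leaf) state assignments."""
    free = [u for u in adj if u >= n_taxa or column[u] < 0]
    fixed = {u: column[u] for u in adj if u < n_taxa and column[u] >= 0}
    edges = _engine.edges_of(adj)
    best = None
    for assignment in itertools.product(range(arity), repeat=len(free)):
        state = dict(zip(free, assignment))
        state.update(fixed)
        cost = sum(state[u] != state[v] for u, v in edges)
        if best is None or cost < best:
            best = cost
    return best
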