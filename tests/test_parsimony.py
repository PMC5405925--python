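"""Character optimization: steps, indices, implied weights, ACCTRAN."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpclad import _engine
from mpclad.matrix_io import MISSING, CharacterDefinition, CharacterMatrix
from mpclad.parsimony import (
    acctran_map,
    character_scores,
    ensemble_indices,
    fitch_steps,
    implied_fit,
    min_max_steps,
    round2,
    tree_length,
)
from mpclad.search import all_binary_trees
from mpclad.trees import random_binary_tree, read_newick, write_newick
from tests.conftest import brute_force_char_steps, make_random_matrix


def _matrix(taxa, columns, arities=None):
    nchar = len(columns)
    arities = arities or [max(2, max(c for c in col if c >= 0) + 1) for col in columns]
    chars = [
        CharacterDefinition(index=j + 1, states=tuple("0123"[: arities[j]]))
        for j in range(nchar)
    ]
    cells = [[columns[j][i] for j in range(nchar)] for i in range(len(taxa))]
    return CharacterMatrix(list(taxa), chars, cells)


def test_single_clean_change():
    m = _matrix(["A", "B", "C", "D"], [[0, 0, 1, 1]])
    t = read_newick("((A,B),(C,D));")
    assert fitch_steps(t, m, 1) == 1


def test_constant_character_is_free():
    m = _matrix(["A", "B", "C", "D"], [[1, 1, 1, 1]], arities=[2])
    for t in all_binary_trees(m.taxa):
        assert fitch_steps(t, m, 1) == 0


def test_missing_never_forces_a_step():
    m = _matrix(["A", "B", "C", "D"], [[0, MISSING, MISSING, 0]])
    t = read_newick("((A,B),(C,D));")
    assert fitch_steps(t, m, 1) == 0


def test_char_index_out_of_range():
    m = _matrix(["A", "B", "C", "D"], [[0, 0, 1, 1]])
    t = read_newick("((A,B),(C,D));")
    with pytest.raises(IndexError):
        fitch_steps(t, m, 2)


def test_fitch_equals_bruteforce_on_random_instances():
    """DP (packed Fitch and Sankoff) vs exhaustive assignment enumeration."""
    rng = random.Random(421)
    for _ in range(25):
        n = rng.randrange(4, 8)
        m = make_random_matrix(n, 4, rng, missing=0.25)
        t = random_binary_tree(m.taxa, rng)
        adj = t.to_indexed_adjacency(m.taxa)
        pm = _engine.PackedMatrix(m)
        total = 0
        for j in range(1, 5):
            col = m.column(j)
            expected = brute_force_char_steps(
                adj, n, col, m.characters[j - 1].arity
            )
            assert fitch_steps(t, m, j) == expected
            total += expected
        assert _engine.fitch_length(adj, pm) == total


def test_length_invariant_under_rerooting(aphid):
    matrix, truth = aphid
    L = tree_length(truth.tree, matrix)
    rng = random.Random(9)
    for _ in range(20):
        root = rng.choice(matrix.taxa)
        rerooted = read_newick(write_newick(truth.tree, root_on=root))
        assert tree_length(rerooted, matrix) == L


def test_three_taxa_length_is_sum_of_m():
    rng = random.Random(8)
    m = make_random_matrix(3, 6, rng, missing=0.2)
    t = read_newick(f"({m.taxa[0]},{m.taxa[1]},{m.taxa[2]});")
    assert tree_length(t, m) == sum(
        min_max_steps(m, j)[0] for j in range(1, 7)
    )


# -- m and g ---------------------------------------------------------------


def test_min_steps_counts_states():
    m = _matrix(["A", "B", "C", "D", "E"], [[0, 1, 2, 2, 1]], arities=[3])
    assert min_max_steps(m, 1) == (2, 3)


def test_max_steps_is_nonmodal_count():
    m = _matrix(["A", "B", "C", "D", "E"], [[0, 0, 0, 1, 1]])
    assert min_max_steps(m, 1)[1] == 2


def test_g_equals_max_fitch_steps_over_all_trees():
    """g must equal the worst tree's steps (exhaustive over n=7: 945 trees)."""
    rng = random.Random(55)
    for _ in range(5):
        m = make_random_matrix(7, 2, rng, missing=0.2)
        for j in (1, 2):
            worst = max(
                fitch_steps(t, m, j) for t in all_binary_trees(m.taxa)
            )
            assert min_max_steps(m, j)[1] == worst


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    n_taxa=st.integers(4, 9),
    missing=st.floats(0.0, 0.4),
)
def test_m_le_s_le_g_property(seed, n_taxa, missing):
    rng = random.Random(seed)
    m = make_random_matrix(n_taxa, 5, rng, missing=missing)
    t = random_binary_tree(m.taxa, rng)
    for sc in character_scores(t, m):
        assert sc.m <= sc.s <= sc.g


# -- ensemble indices ------------------------------------------------------


def test_homoplasy_free_matrix_has_ci_ri_one():
    m = _matrix(
        ["A", "B", "C", "D", "E", "F"],
        [[0, 0, 1, 1, 1, 1], [0, 0, 0, 0, 1, 1], [0, 0, 1, 1, 0, 0]],
    )
    t = read_newick("((A,B),(C,D),(E,F));")
    sc = ensemble_indices(t, m)
    assert sc.ci == 1.0 and sc.ri == 1.0


def test_zero_length_ci_signalled():
    m = _matrix(["A", "B", "C", "D"], [[0, 0, 0, 0]], arities=[2])
    sc = ensemble_indices(read_newick("((A,B),(C,D));"), m)
    with pytest.raises(ZeroDivisionError):
        sc.ci


def test_unequal_length_trees_rejected(aphid):
    matrix, truth = aphid
    rng = random.Random(1)
    other = random_binary_tree(matrix.taxa, rng)
    if tree_length(other, matrix) != tree_length(truth.tree, matrix):
        with pytest.raises(ValueError):
            ensemble_indices([truth.tree, other], matrix)


def test_rounding_is_half_up():
    assert round2(0.585) == 0.59
    assert round2(0.6449) == 0.64


# -- implied weighting -----------------------------------------------------


def test_fit_is_zero_without_homoplasy():
    m = _matrix(["A", "B", "C", "D"], [[0, 0, 1, 1]])
    assert implied_fit(read_newick("((A,B),(C,D));"), m, 3.0).fit_total == 0.0


def test_fit_contribution_h3_k3_is_half():
    # one character forced to 4 steps (m=1, h=3) on an alternating tree
    taxa = list("ABCDEFGH")
    col = [0, 1, 0, 1, 0, 1, 0, 1]
    m = _matrix(taxa, [col])
    t = read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    s = fitch_steps(t, m, 1)
    sc = implied_fit(t, m, k=3.0)
    h = s - 1
    assert sc.fit_total == pytest.approx(h / (h + 3.0))
    # and the documented example value: h=3 at k=3 contributes 0.5
    assert 3 / (3 + 3) == 0.5


def test_invalid_concavity_rejected():
    m = _matrix(["A", "B", "C", "D"], [[0, 0, 1, 1]])
    with pytest.raises(ValueError):
        implied_fit(read_newick("((A,B),(C,D));"), m, 0.0)


def test_large_k_ranking_matches_length_ranking():
    """As k grows, ordering trees by fit converges to ordering by length."""
    rng = random.Random(99)
    for _ in range(5):
        m = make_random_matrix(6, 8, rng, missing=0.1)
        trees = [random_binary_tree(m.taxa, rng) for _ in range(10)]
        by_len = sorted(trees, key=lambda t: tree_length(t, m))
        by_fit = sorted(
            trees, key=lambda t: implied_fit(t, m, 1000.0).fit_total
        )
        assert [tree_length(t, m) for t in by_fit] == [
            tree_length(t, m) for t in by_len
        ]


# -- ACCTRAN ----------------------------------------------------------------


def test_constant_character_maps_no_changes():
    m = _matrix(["O", "A", "B", "C"], [[0, 0, 0, 0], [0, 1, 1, 1]],
                arities=[2, 2])
    t = read_newick("(O,(A,(B,C)));")
    smap = acctran_map(t, m, "O")
    assert smap.total_changes(1) == 0
    assert smap.total_changes(2) == 1
    assert smap.characters_of({"A", "B", "C"}) == {2}


def test_acctran_conserves_per_character_steps(aphid):
    matrix, truth = aphid
    smap = acctran_map(truth.tree, matrix, "Juraphis")
    for j in range(1, matrix.n_characters + 1):
        assert smap.total_changes(j) == fitch_steps(truth.tree, matrix, j)


def test_acctran_conservation_on_random_trees():
    rng = random.Random(123)
    for _ in range(10):
        m = make_random_matrix(7, 6, rng, missing=0.2)
        t = random_binary_tree(m.taxa, rng)
        smap = acctran_map(t, m, m.taxa[0])
        for j in range(1, 7):
            assert smap.total_changes(j) == fitch_steps(t, m, j)


def test_acctran_prefers_reversal_over_parallelism():
    """With signal 0011|1100 nested, ACCTRAN pulls the change rootward and
    explains the nested taxon by a reversal, not two parallel gains."""
    taxa = ["O", "A", "B", "C", "D"]
    #        O  A  B  C  D : B,C derived; D reversed inside
    col = [0, 1, 1, 1, 0]
    m = _matrix(taxa, [col])
    t = read_newick("(O,(A,(B,(C,D))));")
    smap = acctran_map(t, m, "O")
    # the gain covers the whole ingroup (rootward), D reverses
    assert smap.characters_of({"A", "B", "C", "D"}) == {1}
    assert smap.characters_of({"D"}) == {1}
    changes = smap.synapomorphies_of({"D"})
    assert changes[0].from_state == 1 and changes[0].to_state == 0


def test_unique_flag_marks_single_change_characters():
    m = _matrix(
        ["O", "A", "B", "C", "D"],
        [[0, 1, 1, 0, 0], [0, 1, 0, 1, 0]],
    )
    t = read_newick("(O,((A,B),(C,D)));")
    smap = acctran_map(t, m, "O")
    flags = {
        (c.char_index, c.unique)
        for chs in smap.changes.values()
        for c in chs
    }
    assert (1, True) in flags  # char 1 changes once (A,B clade)
    assert all(not u for j, u in flags if j == 2)  # char 2 is homoplasious


def test_polytomy_changes_flagged(aphid):
    matrix, truth = aphid
    from mpclad.trees import strict_consensus
    from mpclad.search import branch_and_bound

    res = branch_and_bound(matrix)
    cons = strict_consensus(res.trees)
    smap = acctran_map(cons, matrix, "Juraphis")
    # the consensus has polytomies; mapping still conserves steps
    for j in range(1, matrix.n_characters + 1):
        assert smap.total_changes(j) == fitch_steps(cons, matrix, j)
    assert any(
        c.at_polytomy for chs in smap.changes.values() for c in chs
    )
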