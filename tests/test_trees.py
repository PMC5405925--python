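"""Tree representation, Newick I/O, consensus, collapsing, clade queries."""

import random

import dendropy
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpclad.matrix_io import CharacterDefinition, CharacterMatrix
from mpclad.parsimony import tree_length
from mpclad.trees import (
    PhyloTree,
    collapse_zero_length,
    contains_clade,
    random_binary_tree,
    read_newick,
    strict_consensus,
    write_newick,
)
from tests.conftest import make_random_matrix


def test_four_leaf_tree_has_one_split():
    t = read_newick("((A,B),(C,D));")
    assert t.bipartitions() == frozenset({frozenset({"C", "D"})})


def test_two_leaf_tree_accepted():
    t = read_newick("(A,B);")
    assert t.leaf_labels == ["A", "B"]
    assert t.bipartitions() == frozenset()


def test_malformed_newick_rejected():
    with pytest.raises(ValueError):
        read_newick("((A,B,(C;")


def test_newick_roundtrip_on_random_trees():
    rng = random.Random(2024)
    for i in range(200):
        n = rng.randrange(4, 17)
        t = random_binary_tree([f"x{j}" for j in range(n)], rng)
        again = read_newick(write_newick(t))
        assert t.same_topology(again), i


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20), n=st.integers(2, 20))
def test_newick_roundtrip_property(seed, n):
    """Round trip preserves the bipartition set for any leaf count,
    including awkward labels that need Newick quoting."""
    rng = random.Random(seed)
    labels = [f"x{j}" for j in range(n - 1)] + ["odd name's"]
    t = random_binary_tree(labels, rng)
    again = read_newick(write_newick(t))
    assert t.same_topology(again)


def test_rooted_newick_input_is_unrooted():
    a = read_newick("((A,B),(C,D));")  # degree-2 root
    b = read_newick("(A,B,(C,D));")
    assert a.same_topology(b)


def test_tree_rebuilt_from_own_bipartitions():
    rng = random.Random(5)
    for _ in range(50):
        t = random_binary_tree([f"x{j}" for j in range(rng.randrange(4, 12))], rng)
        rebuilt = PhyloTree.from_bipartitions(t.leaf_labels, t.bipartitions())
        assert t.same_topology(rebuilt)


# -- strict consensus ------------------------------------------------------


def test_consensus_of_identical_trees_is_identity():
    t = read_newick("((A,B),((C,D),(E,F)));")
    assert strict_consensus([t, t.copy(), t]).same_topology(t)


def test_conflicting_subclade_collapses_to_polytomy():
    t1 = read_newick("((A,B),(C,(D,E)));")
    t2 = read_newick("((A,B),((C,D),E));")
    cons = strict_consensus([t1, t2])
    assert cons.bipartitions() == frozenset({frozenset({"C", "D", "E"})})


def test_consensus_splits_are_exact_intersection():
    rng = random.Random(77)
    labels = [f"x{j}" for j in range(10)]
    for _ in range(20):
        trees = [random_binary_tree(labels, rng) for _ in range(3)]
        cons = strict_consensus(trees)
        expected = frozenset.intersection(*(t.bipartitions() for t in trees))
        assert cons.bipartitions() == expected


def test_consensus_agrees_with_dendropy():
    """Independent oracle: dendropy's strict (min_freq=1) consensus."""
    rng = random.Random(13)
    labels = [f"x{j}" for j in range(8)]
    for _ in range(10):
        trees = [random_binary_tree(labels, rng) for _ in range(3)]
        ours = strict_consensus(trees)
        tns = dendropy.TaxonNamespace()
        dtrees = dendropy.TreeList(
            [
                dendropy.Tree.get(
                    data=write_newick(t),
                    schema="newick",
                    taxon_namespace=tns,
                    preserve_underscores=True,
                )
                for t in trees
            ]
        )
        dcons = dtrees.consensus(min_freq=1.0)
        theirs = read_newick(dcons.as_string(schema="newick"))
        assert ours.same_topology(theirs)


def test_consensus_mismatched_leafsets_rejected():
    with pytest.raises(ValueError):
        strict_consensus([read_newick("((A,B),(C,D));"),
                          read_newick("((A,B),(C,E));")])


# -- clade queries ---------------------------------------------------------


def test_contains_clade_basics():
    t = read_newick("(OUT,(A,(B,(C,D))));")
    assert contains_clade(t, {"C"}, "OUT")  # leaves are clades
    assert contains_clade(t, {"A", "B", "C", "D"}, "OUT")  # full ingroup
    assert contains_clade(t, {"C", "D"}, "OUT")
    assert contains_clade(t, {"B", "C", "D"}, "OUT")
    assert not contains_clade(t, {"A", "B"}, "OUT")
    with pytest.raises(ValueError):
        contains_clade(t, {"OUT", "A"}, "OUT")


# -- zero-length collapsing ------------------------------------------------


def _constant_matrix(taxa):
    chars = [CharacterDefinition(index=1, states=("0", "1"))]
    return CharacterMatrix(list(taxa), chars, [[0] for _ in taxa])


def test_constant_characters_collapse_everything():
    t = read_newick("((A,B),((C,D),(E,F)));")
    m = _constant_matrix(t.leaf_labels)
    for rule in ("min", "max"):
        star = collapse_zero_length(t, m, rule)
        assert star.bipartitions() == frozenset()


def test_unambiguously_supported_branches_survive():
    # every internal branch carries a clean binary character
    taxa = ["A", "B", "C", "D", "E", "F"]
    chars = [CharacterDefinition(index=j, states=("0", "1")) for j in (1, 2, 3)]
    # tree ((A,B),(C,D),(E,F)): three cherries around a centre
    patterns = {
        "A": [1, 0, 0], "B": [1, 0, 0],
        "C": [0, 1, 0], "D": [0, 1, 0],
        "E": [0, 0, 1], "F": [0, 0, 1],
    }
    m = CharacterMatrix(taxa, chars, [patterns[t] for t in taxa])
    t = read_newick("((A,B),(C,D),(E,F));")
    for rule in ("min", "max"):
        assert collapse_zero_length(t, m, rule).same_topology(t)


def test_unknown_collapse_rule_rejected(aphid):
    matrix, truth = aphid
    with pytest.raises(ValueError):
        collapse_zero_length(truth.tree, matrix, "median")


def test_max_rule_collapse_preserves_length():
    """Contracting branches that carry a change in *no* reconstruction
    cannot alter the tree's length."""
    rng = random.Random(31)
    for _ in range(10):
        m = make_random_matrix(7, 6, rng, missing=0.25)
        t = random_binary_tree(m.taxa, rng)
        collapsed = collapse_zero_length(t, m, "max")
        assert tree_length(collapsed, m) == tree_length(t, m)
        assert sorted(collapsed.leaf_labels) == sorted(t.leaf_labels)
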