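"""Heuristic and exact tree search, implied weights, Bremer support."""

import random

import pytest

from mpclad.matrix_io import CharacterDefinition, CharacterMatrix
from mpclad.parsimony import implied_fit, tree_length
from mpclad.search import (
    SearchConfig,
    all_binary_trees,
    branch_and_bound,
    bremer_support,
    exact_bremer,
    heuristic_search,
    implied_weight_search,
)
from mpclad.synthetic_data import PlantedClade, SimulationConfig, simulate_matrix
from mpclad.trees import contains_clade, strict_consensus
from tests.conftest import make_random_matrix


def test_four_taxon_exhaustive_coverage():
    """At n=4 the heuristic must find the optimum among all 3 topologies."""
    rng = random.Random(17)
    for seed in range(5):
        m = make_random_matrix(4, 6, rng, missing=0.1)
        res = heuristic_search(m, SearchConfig(replicates=3, seed=seed))
        exact = min(
            tree_length(t, m) for t in all_binary_trees(m.taxa)
        )
        assert res.best_score == exact


def test_heuristic_matches_branch_and_bound_on_random_matrices():
    rng = random.Random(101)
    for seed in range(6):
        m = make_random_matrix(8, 12, rng, missing=0.15)
        res = heuristic_search(m, SearchConfig(replicates=8, seed=seed))
        bb = branch_and_bound(m)
        assert res.best_score == bb.best_score
        assert {t.bipartitions() for t in res.trees} == {
            t.bipartitions() for t in bb.trees
        }


def test_branch_and_bound_agrees_with_full_enumeration():
    rng = random.Random(202)
    for _ in range(4):
        m = make_random_matrix(6, 8, rng, missing=0.15)
        best, keys, count = None, set(), 0
        for t in all_binary_trees(m.taxa):
            count += 1
            L = tree_length(t, m)
            if best is None or L < best:
                best, keys = L, set()
            if L == best:
                keys.add(t.bipartitions())
        assert count == 105
        bb = branch_and_bound(m)
        assert bb.best_score == best
        assert {t.bipartitions() for t in bb.binary_trees} == keys


def test_determinism_of_search():
    rng = random.Random(7)
    m = make_random_matrix(9, 10, rng)
    a = heuristic_search(m, SearchConfig(replicates=6, seed=99))
    b = heuristic_search(m, SearchConfig(replicates=6, seed=99))
    assert a.best_score == b.best_score
    assert [t.bipartitions() for t in a.trees] == [t.bipartitions() for t in b.trees]
    assert a.pool == b.pool


def test_guard_on_large_branch_and_bound():
    rng = random.Random(1)
    m = make_random_matrix(17, 4, rng)
    with pytest.raises(ValueError):
        branch_and_bound(m)


def test_homoplasy_free_data_recovers_generating_tree():
    cfg = SimulationConfig(
        n_taxa=8, n_characters=12, extra_steps=0, missing_fraction=0.0, seed=5
    )
    matrix, truth = simulate_matrix(cfg)
    bb = branch_and_bound(matrix)
    assert bb.best_score == truth.sum_m
    # every recovered grouping is true, and the recovered tree is exactly
    # the identifiable (character-supported) part of the generating tree
    assert len(bb.trees) == 1
    recovered = bb.trees[0]
    assert recovered.bipartitions() <= truth.tree.bipartitions()
    from mpclad.trees import collapse_zero_length

    assert recovered.same_topology(
        collapse_zero_length(truth.tree, matrix, "min")
    )


def test_implied_optimum_equals_equal_weight_optimum_without_homoplasy():
    cfg = SimulationConfig(
        n_taxa=7, n_characters=10, extra_steps=0, missing_fraction=0.0, seed=3
    )
    matrix, truth = simulate_matrix(cfg)
    ew = branch_and_bound(matrix)
    for k in (1.0, 5.0):
        iw = branch_and_bound(matrix, weighting="implied", k=k)
        assert iw.best_score == 0.0  # F = 0 at the true tree
        assert {t.bipartitions() for t in iw.trees} == {
            t.bipartitions() for t in ew.trees
        }


def test_implied_search_runs_independently_per_k():
    rng = random.Random(404)
    m = make_random_matrix(7, 10, rng, missing=0.1)
    runs = implied_weight_search(m, SearchConfig(replicates=5, seed=2), [1.0, 4.0])
    for k, res in runs.items():
        exact = branch_and_bound(m, weighting="implied", k=k)
        assert res.best_score == pytest.approx(exact.best_score, abs=1e-9)
        assert {t.bipartitions() for t in res.trees} == {
            t.bipartitions() for t in exact.trees
        }


def test_implied_ranking_approaches_length_ranking_at_large_k():
    rng = random.Random(19)
    for seed in range(3):
        m = make_random_matrix(8, 10, rng, missing=0.1)
        ew = branch_and_bound(m)
        iw = branch_and_bound(m, weighting="implied", k=1000.0)
        # at huge k the fit only tie-breaks within equal-length trees:
        # every fit optimum must be a length optimum
        assert {t.bipartitions() for t in iw.binary_trees} <= {
            t.bipartitions() for t in ew.binary_trees
        }
        assert tree_length(iw.binary_trees[0], m) == ew.best_score


# -- Bremer support --------------------------------------------------------


def _planted_six_taxon():
    cfg = SimulationConfig(
        n_taxa=6,
        n_characters=10,
        extra_steps=2,
        missing_fraction=0.0,
        planted_clades=[PlantedClade(frozenset({"t05", "t06"}), (1, 2))],
        generating_tree="random",
        seed=11,
    )
    return simulate_matrix(cfg)


def test_pooled_bremer_equals_exact_on_six_taxa():
    matrix, truth = _planted_six_taxon()
    res = heuristic_search(
        matrix, SearchConfig(replicates=20, suboptimal_margin=20, seed=4)
    )
    cons = strict_consensus(res.trees)
    clades = [c for c in cons.clusters(matrix.outgroup)
              if 2 <= len(c) <= matrix.n_taxa - 2]
    pooled = {s.clade: s for s in bremer_support(matrix, clades, res)}
    for clade in clades:
        exact = exact_bremer(matrix, clade, matrix.outgroup)
        got = pooled[frozenset(clade)]
        if got.is_lower_bound:
            assert exact > got.bremer
        else:
            assert got.bremer == exact, sorted(clade)


def test_clade_absent_from_an_optimal_tree_has_zero_support():
    rng = random.Random(6)
    # search random matrices until one yields >= 2 MPTs, then check decay 0
    for seed in range(20):
        m = make_random_matrix(6, 6, rng, missing=0.2)
        res = heuristic_search(m, SearchConfig(replicates=10, seed=seed))
        if len(res.binary_trees) < 2:
            continue
        keys = [t.bipartitions() for t in res.binary_trees]
        contested = set.union(*(set(k) for k in keys)) - set.intersection(
            *(set(k) for k in keys)
        )
        contested = [c for c in contested if m.taxa[0] not in c]
        if not contested:
            continue
        supports = {
            s.clade: s.bremer
            for s in bremer_support(m, [frozenset(c) for c in contested], res)
        }
        assert all(v == 0 for v in supports.values())
        return
    pytest.skip("no contested clade found in 20 random matrices")


def test_enlarging_margin_never_increases_support():
    """A bigger suboptimal pool can only tighten the decay upper bound."""
    from dataclasses import replace as dc_replace

    matrix, truth = _planted_six_taxon()
    res = heuristic_search(
        matrix, SearchConfig(replicates=15, suboptimal_margin=12, seed=8)
    )
    best = int(res.best_score)
    clades = [frozenset({"t05", "t06"}), frozenset({"t03", "t04"})]
    previous = {c: None for c in clades}
    for margin in (2, 6, 12):
        filtered = dc_replace(
            res,
            pool={k: v for k, v in res.pool.items() if v <= best + margin},
            config=dc_replace(res.config, suboptimal_margin=margin),
        )
        for sup in bremer_support(matrix, clades, filtered):
            value = float("inf") if sup.is_lower_bound else sup.bremer
            prev = previous[sup.clade]
            if prev is not None and prev != float("inf"):
                assert value <= prev
            previous[sup.clade] = value


def test_bremer_requires_pool(aphid):
    matrix, truth = aphid
    res = branch_and_bound(matrix)  # no pool in exact search
    with pytest.raises(ValueError):
        bremer_support(matrix, [frozenset({"Canadaphis", "Alloambria"})], res)
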