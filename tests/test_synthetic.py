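"""Generator bookkeeping, inapplicable logic, and recovery experiments."""

import random

import pytest

from mpclad.matrix_io import INAPPLICABLE, MISSING, write_nexus
from mpclad.parsimony import ensemble_indices, fitch_steps, tree_length
from mpclad.search import SearchConfig, exact_bremer, heuristic_search
from mpclad.synthetic_data import (
    PlantedClade,
    SimulationConfig,
    recovery_experiment,
    simulate_matrix,
)
from mpclad.trees import contains_clade, read_newick, strict_consensus
from tests.conftest import brute_force_char_steps


def test_no_extra_steps_means_ci_one():
    cfg = SimulationConfig(n_taxa=8, n_characters=10, extra_steps=0,
                           missing_fraction=0.1, seed=1)
    matrix, truth = simulate_matrix(cfg)
    assert tree_length(truth.tree, matrix) == truth.sum_m
    assert ensemble_indices(truth.tree, matrix).ci == 1.0


@pytest.mark.parametrize("extra", [3, 7])
def test_planted_homoplasy_gives_exact_ci(extra):
    cfg = SimulationConfig(n_taxa=9, n_characters=12, extra_steps=extra,
                           missing_fraction=0.15, seed=2)
    matrix, truth = simulate_matrix(cfg)
    assert truth.extra_steps == extra
    L = tree_length(truth.tree, matrix)
    assert L == truth.sum_m + extra
    sc = ensemble_indices(truth.tree, matrix)
    assert sc.ci == pytest.approx(truth.expected_ci)
    assert sc.ci == pytest.approx(truth.sum_m / (truth.sum_m + extra))


def test_missing_count_is_stochastically_rounded():
    """At 20% of a 14 x 39 grid the generator injects 109 or 110 cells."""
    counts = set()
    for seed in range(4):
        cfg = SimulationConfig(seed=seed)  # defaults: 14 x 39, 20% missing
        matrix, truth = simulate_matrix(cfg)
        n_missing = matrix.missing_count()
        assert n_missing == truth.missing_cells
        counts.add(n_missing)
    assert counts <= {109, 110}


def test_same_seed_gives_identical_nexus_bytes(tmp_path):
    cfg = SimulationConfig(n_taxa=7, n_characters=9, extra_steps=4, seed=33)
    a, _ = simulate_matrix(cfg)
    b, _ = simulate_matrix(SimulationConfig(**{**cfg.__dict__}))
    pa, pb = tmp_path / "a.nex", tmp_path / "b.nex"
    write_nexus(a, str(pa))
    write_nexus(b, str(pb))
    assert pa.read_bytes() == pb.read_bytes()


def test_bookkeeping_against_bruteforce_oracle():
    """Per-character steps on the generating tree match the exhaustive
    assignment oracle, so L = sum(m) + E is not self-referential."""
    cfg = SimulationConfig(n_taxa=6, n_characters=6, extra_steps=3,
                           missing_fraction=0.2, seed=12)
    matrix, truth = simulate_matrix(cfg)
    adj = truth.tree.to_indexed_adjacency(matrix.taxa)
    total = 0
    for j in range(1, 7):
        expected = brute_force_char_steps(
            adj, 6, matrix.column(j), matrix.characters[j - 1].arity
        )
        assert truth.per_char_steps[j] == expected
        total += expected
    assert total == truth.sum_m + truth.extra_steps


def test_inapplicable_follows_controller():
    cfg = SimulationConfig(
        n_taxa=8, n_characters=6, extra_steps=0, missing_fraction=0.0,
        inapplicable_links=[(1, 1, 2)], seed=3,
    )
    matrix, _ = simulate_matrix(cfg)
    ctrl = matrix.column(1)
    dep = matrix.column(2)
    for c, d in zip(ctrl, dep):
        if c != 1:
            assert d == INAPPLICABLE
        else:
            assert d != INAPPLICABLE
    assert matrix.characters[1].controlling == (1, 1)


def test_planted_clade_must_exist_in_tree():
    tree = read_newick("(t01,(t02,(t03,t04)));")
    cfg = SimulationConfig(
        n_taxa=4, n_characters=4, taxa=["t01", "t02", "t03", "t04"],
        generating_tree=tree, extra_steps=0,
        planted_clades=[PlantedClade(frozenset({"t02", "t04"}), (1,))],
        seed=0,
    )
    with pytest.raises(ValueError):
        simulate_matrix(cfg)


def test_perfect_data_recovery_is_total():
    cfg = SimulationConfig(
        n_taxa=8, n_characters=14, extra_steps=0, missing_fraction=0.0,
        planted_clades=[
            PlantedClade(frozenset({"t05", "t06", "t07"}), (1, 2)),
            PlantedClade(frozenset({"t02", "t03"}), (3,)),
        ],
        generating_tree=read_newick(
            "(t01,((t02,t03),(t04,((t05,(t06,t07)),t08))));"
        ),
        taxa=[f"t{i + 1:02d}" for i in range(8)],
        seed=21,
    )
    report = recovery_experiment(cfg, n_replicates=4, search_replicates=6)
    assert report.mean_recovery == 1.0
    assert all(v == 1.0 for v in report.synapomorphy_jaccard.values())


def test_homoplasy_degrades_recovery_in_expectation():
    base = dict(
        n_taxa=8, n_characters=10, missing_fraction=0.1,
        planted_clades=[PlantedClade(frozenset({"t05", "t06"}), (1,))],
        generating_tree=read_newick(
            "(t01,((t02,t03),(t04,((t05,t06),(t07,t08)))));"
        ),
        taxa=[f"t{i + 1:02d}" for i in range(8)],
        seed=40,
    )
    clean = recovery_experiment(
        SimulationConfig(extra_steps=0, **base), n_replicates=4,
        search_replicates=6,
    )
    noisy = recovery_experiment(
        SimulationConfig(extra_steps=12, **base), n_replicates=4,
        search_replicates=6,
    )
    assert clean.mean_recovery >= noisy.mean_recovery


def test_two_synapomorphy_clade_has_decay_at_least_two():
    """A clade defined by 2 clean characters and never contradicted needs
    at least 2 extra steps to break (exact enumeration at n=6)."""
    cfg = SimulationConfig(
        n_taxa=6, n_characters=8, extra_steps=0, missing_fraction=0.0,
        planted_clades=[PlantedClade(frozenset({"t04", "t05"}), (1, 2))],
        generating_tree=read_newick(
            "(t01,(t02,(t03,((t04,t05),t06))));"
        ),
        taxa=[f"t{i + 1:02d}" for i in range(6)],
        seed=9,
    )
    matrix, truth = simulate_matrix(cfg)
    assert exact_bremer(matrix, frozenset({"t04", "t05"})) >= 2


def test_mk_mode_produces_valid_matrix():
    cfg = SimulationConfig(n_taxa=7, n_characters=10, seed=14,
                           missing_fraction=0.1)
    matrix, truth = simulate_matrix(cfg, mode="mk")
    assert truth is None
    assert matrix.n_taxa == 7 and matrix.n_characters == 10
    assert all(
        c in (MISSING,) or 0 <= c < 4 for row in matrix.cells for c in row
    )
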