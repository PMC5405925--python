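"""End-to-end analysis protocol and report generation.

``run_protocol`` reproduces the standard morphological maximum-parsimony
workflow for a matrix: equal-weights heuristic search (random addition +
TBR), zero-length-branch collapsing, strict consensus, ensemble CI/RI,
pool-based Bremer supports, ACCTRAN synapomorphy mapping, and independent
implied-weights searches over a grid of concavity constants (k = 1..10 by
default).  Every number in the report is regenerable from
(matrix, config, seed).
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field, replace

import yaml

from .matrix_io import CharacterMatrix, validate_characters
from .parsimony import (
    SynapomorphyMap,
    acctran_map,
    character_scores,
    ensemble_indices,
    round2,
    scores_tsv,
    synapomorphy_tsv,
)
from .search import (
    CladeSupport,
    SearchConfig,
    SearchResult,
    bremer_support,
    heuristic_search,
    implied_weight_search,
)
from .trees import PhyloTree, strict_consensus, write_newick

__all__ = ["AnalysisReport", "run_protocol", "check_claims"]


@dataclass
class AnalysisReport:
    """Everything the protocol computed, ready for serialisation."""

    n_taxa: int
    n_characters: int
    missing_percent: float
    n_uninformative: int
    outgroup: str

    ew_best_length: int
    ew_n_mpts: int
    ew_mpt_newicks: list[str]
    ew_consensus_newick: str
    ci: float
    ri: float
    ci_informative: float
    ri_informative: float

    iw_k_values: list[float]
    iw_n_trees: dict[float, int]
    iw_fits: dict[float, float]
    iw_newicks: dict[float, str]
    iw_single_tree_per_k: bool
    iw_identical_across_k: bool  # same optimal tree set at every k
    iw_matches_ew_mpt: int | None  # 1-based MPT index the single IW tree equals

    bremer: dict[str, str]  # clade (comma-joined) -> support string
    consensus_synapomorphies: dict[str, list[list]]  # clade -> change rows

    config: dict
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        lines = [
            f"matrix: {self.n_taxa} taxa x {self.n_characters} characters "
            f"({self.missing_percent:.1f}% missing, "
            f"{self.n_uninformative} uninformative characters)",
            f"equal weights: {self.ew_n_mpts} MPT(s), length {self.ew_best_length}, "
            f"CI {round2(self.ci):.2f}, RI {round2(self.ri):.2f} "
            f"(informative only: CI {round2(self.ci_informative):.2f}, "
            f"RI {round2(self.ri_informative):.2f})",
            f"strict consensus: {self.ew_consensus_newick}",
            "implied weights: "
            + ", ".join(
                f"k={k:g}: {self.iw_n_trees[k]} tree(s)" for k in self.iw_k_values
            ),
            f"single tree per k: {self.iw_single_tree_per_k}; "
            f"identical optima across k: {self.iw_identical_across_k}",
        ]
        if self.bremer:
            lines.append("Bremer supports:")
            for clade, sup in sorted(self.bremer.items()):
                lines.append(f"  {sup:>4}  {clade}")
        return "\n".join(lines)


def run_protocol(
    matrix: CharacterMatrix,
    config: SearchConfig | None = None,
    k_values: list[float] | None = None,
    out_dir: str | None = None,
) -> AnalysisReport:
    """Run the full equal-weights + implied-weights protocol on a matrix.

    Writes report, tree files and per-character tables into ``out_dir``
    when given.  Deterministic for a fixed (matrix, config, k grid).
    """
    cfg = config or SearchConfig()
    ks = [float(k) for k in (k_values if k_values is not None else range(1, 11))]

    ew = heuristic_search(matrix, cfg)
    mpts = ew.trees
    consensus = strict_consensus(mpts)
    # indices on the binary optima (post-collapse trees can be longer)
    sc_all = ensemble_indices(ew.binary_trees, matrix)
    sc_inf = ensemble_indices(ew.binary_trees, matrix, variant="informative")

    og = matrix.outgroup
    clades = sorted(
        (c for c in consensus.clusters(og) if 2 <= len(c) <= matrix.n_taxa - 2),
        key=lambda c: (len(c), sorted(c)),
    )
    supports = bremer_support(matrix, clades, ew)
    smap = acctran_map(consensus, matrix, og)

    iw = implied_weight_search(matrix, cfg, ks)
    iw_keys = {
        k: frozenset(t.bipartitions() for t in r.trees) for k, r in iw.items()
    }
    single = all(len(v) == 1 for v in iw_keys.values())
    identical = len(set(iw_keys.values())) == 1
    matches = None
    if single and identical:
        key = next(iter(next(iter(iw_keys.values()))))
        for i, t in enumerate(mpts, start=1):
            if t.bipartitions() == key:
                matches = i
                break

    report = AnalysisReport(
        n_taxa=matrix.n_taxa,
        n_characters=matrix.n_characters,
        missing_percent=100.0
        * matrix.missing_count()
        / (matrix.n_taxa * matrix.n_characters),
        n_uninformative=sum(
            1 for v in validate_characters(matrix) if v.kind == "uninformative"
        ),
        outgroup=og,
        ew_best_length=int(ew.best_score),
        ew_n_mpts=len(mpts),
        ew_mpt_newicks=[write_newick(t, root_on=og) for t in mpts],
        ew_consensus_newick=write_newick(consensus, root_on=og),
        ci=sc_all.ci,
        ri=sc_all.ri,
        ci_informative=sc_inf.ci,
        ri_informative=sc_inf.ri,
        iw_k_values=ks,
        iw_n_trees={k: len(r.trees) for k, r in iw.items()},
        iw_fits={k: float(r.best_score) for k, r in iw.items()},
        iw_newicks={k: write_newick(r.trees[0], root_on=og) for k, r in iw.items()},
        iw_single_tree_per_k=single,
        iw_identical_across_k=identical,
        iw_matches_ew_mpt=matches,
        bremer={
            ",".join(sorted(s.clade)): str(s) for s in supports
        },
        consensus_synapomorphies={
            ",".join(sorted(clade)): [
                [c.char_index, c.from_state, c.to_state, c.unique, c.at_polytomy]
                for c in changes
            ]
            for clade, changes in smap.changes.items()
        },
        config={**asdict(cfg)},
        seed=cfg.seed,
    )

    if out_dir is not None:
        _write_outputs(out_dir, report, matrix, mpts, consensus, supports, smap, ew)
    return report


def _write_outputs(
    out_dir: str,
    report: AnalysisReport,
    matrix: CharacterMatrix,
    mpts: list[PhyloTree],
    consensus: PhyloTree,
    supports: list[CladeSupport],
    smap: SynapomorphyMap,
    ew: SearchResult,
) -> None:
    os.makedirs(out_dir, exist_ok=True)
    og = matrix.outgroup

    def put(name: str, text: str) -> None:
        with open(os.path.join(out_dir, name), "w", encoding="utf-8") as fh:
            fh.write(text)

    put("report.yaml", yaml.safe_dump(report.to_dict(), sort_keys=False))
    put("report.txt", report.summary() + "\n")
    put("mpts.tre", "".join(write_newick(t, root_on=og) + "\n" for t in mpts))
    labels = {s.clade: str(s) for s in supports}
    put("consensus.tre", write_newick(consensus, root_on=og, node_labels=labels) + "\n")
    put("scores.tsv", scores_tsv(character_scores(mpts[0], matrix)))
    put("synapomorphies.tsv", synapomorphy_tsv(smap))
    put(
        "run.log",
        "config: %r\nbest length: %s\npool size: %d (truncated: %s)\n"
        % (ew.config, ew.best_score, len(ew.pool), ew.truncated),
    )


# ---------------------------------------------------------------------------
# Claims checking
# ---------------------------------------------------------------------------

_CMPS = {
    "eq": lambda a, b: a == b,
    "approx": lambda a, b: abs(float(a) - float(b)) <= 1e-2,
    "le": lambda a, b: float(a) <= float(b),
    "ge": lambda a, b: float(a) >= float(b),
}


def check_claims(report: AnalysisReport | dict, claims: list[dict] | str):
    """Compare report fields against declared expectations.

    ``claims`` is a list of ``{"field": dotted.path, "cmp": eq|approx|le|ge,
    "value": expected}`` mappings (or a path to a YAML file of them).
    Returns ``(all_ok, rows)`` where each row is
    ``(field, cmp, expected, actual, ok)``.  An empty claims list passes
    vacuously.
    """
    if isinstance(claims, str):
        with open(claims, encoding="utf-8") as fh:
            claims = yaml.safe_load(fh) or []
    if not isinstance(claims, list):
        raise ValueError("claims must be a list of mappings")
    data = report.to_dict() if isinstance(report, AnalysisReport) else dict(report)
    rows = []
    ok_all = True
    for claim in claims:
        try:
            field_, cmp_, value = claim["field"], claim.get("cmp", "eq"), claim["value"]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed claim {claim!r}") from exc
        if cmp_ not in _CMPS:
            raise ValueError(f"unknown comparator {cmp_!r}")
        actual: object = data
        try:
            for part in str(field_).split("."):
                if isinstance(actual, list):
                    actual = actual[int(part)]
                elif isinstance(actual, dict) and part not in actual:
                    actual = actual[float(part)]
                else:
                    actual = actual[part]
        except (KeyError, IndexError, TypeError, ValueError):
            rows.append((field_, cmp_, value, None, False))
            ok_all = False
            continue
        good = _CMPS[cmp_](actual, value)
        rows.append((field_, cmp_, value, actual, good))
        ok_all = ok_all and good
    return ok_all, rows
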