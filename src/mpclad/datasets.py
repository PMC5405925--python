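"""Bundled example dataset (synthetic).

``synthetic_aphid_matrix()`` builds a *synthetic* stand-in for a small
fossil-aphid morphological matrix: 14 taxa (a juraphidid outgroup, an
oviparosiphid grade, and bajsaphidid + canadaphidid clades) by 39 unordered
characters.  It is generated by :mod:`mpclad.synthetic_data` with a fixed
seed, so every structural property is known exactly:

* the canadaphidid clade (*Canadaphis*, *Alloambria*, *Pseudambria*) is
  defined by synapomorphies in characters 3, 6, 7, 16, 17, 25, 26, 28, 36;
* the bajsaphidid clade (two *Bajsaphis* terminals) by characters 33, 37;
* a well-developed anal plate (character 38) unites bajsaphidids,
  *Vitimaphis* and canadaphidids;
* character 4 (suture connection) is inapplicable where lateral sutures
  are absent (character 3), and character 35 (siphunculus form) where
  siphunculi are absent (character 34);
* 30 homoplasious extra steps are planted, so the ensemble consistency
  index on the generating tree is exactly 45/75 = 0.60, and 15% of cells
  are missing.

This is **not** a published data matrix; taxon names only indicate the
kind of dataset being emulated.
"""

from __future__ import annotations

from .matrix_io import CharacterMatrix
from .synthetic_data import (
    PlantedClade,
    SimulationConfig,
    TruthRecord,
    simulate_matrix,
)
from .trees import read_newick

__all__ = [
    "APHID_TAXA",
    "CANADAPHIDID_CLADE",
    "BAJSAPHIDID_CLADE",
    "synthetic_aphid_config",
    "synthetic_aphid_matrix",
]

APHID_TAXA = [
    "Juraphis",  # outgroup
    "Daoaphis",
    "Khotonaphis",
    "Acanthotrichaphis",
    "Dinaphis",
    "Oviparosiphum",
    "Archeoviparosiphum",
    "Vitimaphis_rasnitsyni",
    "Vitimaphis_subridens",
    "Bajsaphis_kononovae",
    "Bajsaphis_abbreviata",
    "Canadaphis",
    "Alloambria",
    "Pseudambria",
]

CANADAPHIDID_CLADE = frozenset({"Canadaphis", "Alloambria", "Pseudambria"})
BAJSAPHIDID_CLADE = frozenset({"Bajsaphis_kononovae", "Bajsaphis_abbreviata"})
#: bajsaphidids + *Vitimaphis* + canadaphidids
BVC_CLADE = (
    BAJSAPHIDID_CLADE
    | CANADAPHIDID_CLADE
    | {"Vitimaphis_rasnitsyni", "Vitimaphis_subridens"}
)

#: synapomorphy characters dedicated to each planted clade
CANADAPHIDID_SYNAPOMORPHIES = (3, 6, 7, 16, 17, 25, 26, 28, 36)
BAJSAPHIDID_SYNAPOMORPHIES = (33, 37)

_GENERATING_TREE = (
    "(Juraphis,(Daoaphis,((Khotonaphis,(Dinaphis,(Oviparosiphum,"
    "Archeoviparosiphum))),(Acanthotrichaphis,(((Bajsaphis_kononovae,"
    "Bajsaphis_abbreviata),(Vitimaphis_rasnitsyni,Vitimaphis_subridens)),"
    "(Canadaphis,(Alloambria,Pseudambria)))))));"
)

#: character arities: mostly binary; multistate characters 12, 23, 27, 28, 33
_ARITIES = [
    2, 2, 2, 2, 2, 2, 2, 2, 2, 2,  # 1-10
    2, 3, 2, 2, 2, 2, 2, 2, 2, 2,  # 11-20 (12 has 3 states)
    2, 2, 4, 2, 2, 2, 3, 3, 2, 2,  # 21-30 (23 has 4; 27, 28 have 3)
    2, 2, 3, 2, 2, 2, 2, 2, 2,     # 31-39 (33 has 3)
]

_CHAR_LABELS = [
    "body form",
    "epicranial suture",
    "lateral sutures of head",
    "lateral sutures connection",
    "rostrum length",
    "antennal surface",
    "number of antennal segments",
    "antenna length vs body",
    "antenna length vs fore tibia",
    "antenna length vs hind tibia",
    "antennal segment III vs later segments",
    "antennal segment III proportions",
    "flagellar segment lengths",
    "last antennal segment vs previous",
    "last antennal segment narrowing",
    "processus terminalis",
    "primary rhinaria",
    "hind tibia vs body length",
    "hind tarsus vs tibia length",
    "fore wing vs body length",
    "common stem of cubital veins",
    "cubital vein count",
    "cubital vein bases",
    "CuA1 vs CuA2 length",
    "CuA1 course",
    "base of vein M position",
    "ramification of M vs Rs base",
    "base of vein Rs on pterostigma",
    "vein Rs curvature",
    "vein Rs course vs pterostigma",
    "pterostigma ending",
    "pterostigma proportions",
    "ovipositor development",
    "siphunculi on abdomen",
    "siphunculi form",
    "cauda",
    "anal plate lobation",
    "anal plate development",
    "abdominal setae",
]

_SEED = 20170426


def synthetic_aphid_config() -> SimulationConfig:
    """The fixed simulation settings behind the bundled synthetic matrix."""
    return SimulationConfig(
        n_taxa=14,
        n_characters=39,
        arities=list(_ARITIES),
        char_labels=list(_CHAR_LABELS),
        taxa=list(APHID_TAXA),
        generating_tree=read_newick(_GENERATING_TREE),
        extra_steps=30,
        missing_fraction=0.15,
        inapplicable_links=[(3, 0, 4), (34, 1, 35)],
        planted_clades=[
            PlantedClade(CANADAPHIDID_CLADE, CANADAPHIDID_SYNAPOMORPHIES),
            PlantedClade(BAJSAPHIDID_CLADE, BAJSAPHIDID_SYNAPOMORPHIES),
            PlantedClade(frozenset(BVC_CLADE), (38,)),
        ],
        seed=_SEED,
    )


def synthetic_aphid_matrix() -> tuple[CharacterMatrix, TruthRecord]:
    """Deterministically regenerate the synthetic 14 x 39 example matrix
    and its truth record (same output every call)."""
    return simulate_matrix(synthetic_aphid_config())
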