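"""Discrete morphological character matrices and their file formats.

The central object is :class:`CharacterMatrix`: an ordered taxa x characters
grid of small integer state codes with two special cell values, ``MISSING``
(unknown, coded ``?`` in files) and ``INAPPLICABLE`` (logically unscorable,
coded ``-``; typographic en-dashes are accepted on input).  Characters are
unordered multistate with 2-4 states; per-character metadata lives in
:class:`CharacterDefinition`.

NEXUS reading and writing is delegated to dendropy; a minimal TNT ``xread``
reader is provided as a convenience for users holding TNT files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import dendropy

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "CharacterDefinition",
    "CharacterMatrix",
    "Violation",
    "NexusError",
    "read_nexus",
    "write_nexus",
    "read_tnt",
    "validate_characters",
]

#: Cell code for an unknown ("?") state.
MISSING = -1
#: Cell code for a logically inapplicable ("-") state.
INAPPLICABLE = -2

#: Maximum number of states any character may declare.
MAX_STATES = 4

_SYMBOLS = "0123"


class NexusError(ValueError):
    """Raised for malformed matrix files (parse, dimension or symbol errors)."""


@dataclass(frozen=True)
class CharacterDefinition:
    """Metadata for one character column.

    Parameters
    ----------
    index
        1-based character number, matching the published numbering convention.
    label
        Free-text character name (e.g. ``"siphunculi on abdomen"``).
    states
        Ordered state labels; the state *code* of ``states[i]`` is ``i``.
    ordered
        Whether the character is additive.  Always ``False`` here: all
        characters are treated as unordered (Fitch) characters.
    controlling
        Optional ``(controller_index, state_code)`` pair: this character is
        applicable only in taxa where the controlling character takes the
        given state (e.g. siphunculus shape is inapplicable when siphunculi
        are absent).  This is coding-level metadata; scoring treats
        inapplicable cells exactly like missing ones.
    """

    index: int
    label: str = ""
    states: tuple[str, ...] = ("0", "1")
    ordered: bool = False
    controlling: tuple[int, int] | None = None

    @property
    def arity(self) -> int:
        return len(self.states)

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"character index must be >= 1, got {self.index}")
        if not 2 <= len(self.states) <= MAX_STATES:
            raise ValueError(
                f"character {self.index}: needs 2-{MAX_STATES} states, "
                f"got {len(self.states)}"
            )
        if self.ordered:
            raise ValueError("ordered (additive) characters are not supported")


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of discrete states.

    ``cells[i][j]`` holds the state code of taxon ``i`` for character ``j``
    (0-based column; character *numbers* are 1-based), or ``MISSING`` /
    ``INAPPLICABLE``.  The outgroup defaults to the first taxon, following
    the common convention of listing the outgroup first.
    """

    taxa: list[str]
    characters: list[CharacterDefinition]
    cells: list[list[int]]
    outgroup: str | None = None

    def __post_init__(self) -> None:
        if self.outgroup is None and self.taxa:
            self.outgroup = self.taxa[0]
        self._check()

    def _check(self) -> None:
        if not self.taxa:
            raise ValueError("matrix has no taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if len(self.cells) != len(self.taxa):
            raise ValueError(
                f"grid has {len(self.cells)} rows for {len(self.taxa)} taxa"
            )
        ncol = len(self.characters)
        for t, row in zip(self.taxa, self.cells):
            if len(row) != ncol:
                raise ValueError(
                    f"row for {t!r} has {len(row)} cells, expected {ncol}"
                )
        for j, c in enumerate(self.characters):
            if c.index != j + 1:
                raise ValueError(
                    f"character at column {j} numbered {c.index}, expected {j + 1}"
                )
        if self.outgroup not in self.taxa:
            raise ValueError(f"outgroup {self.outgroup!r} not among taxa")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def column(self, char_index: int) -> list[int]:
        """Cells of character ``char_index`` (1-based), in taxon order."""
        if not 1 <= char_index <= self.n_characters:
            raise IndexError(f"character index {char_index} out of range")
        j = char_index - 1
        return [row[j] for row in self.cells]

    def observed_states(self, char_index: int) -> set[int]:
        """Distinct state codes observed (missing/inapplicable excluded)."""
        return {c for c in self.column(char_index) if c >= 0}

    def state_counts(self, char_index: int) -> dict[int, int]:
        counts: dict[int, int] = {}
        for c in self.column(char_index):
            if c >= 0:
                counts[c] = counts.get(c, 0) + 1
        return counts

    def is_informative(self, char_index: int) -> bool:
        """Parsimony-informative: at least two states each in >= 2 taxa."""
        counts = self.state_counts(char_index)
        return sum(1 for n in counts.values() if n >= 2) >= 2

    def missing_count(self) -> int:
        return sum(c == MISSING for row in self.cells for c in row)

    def with_outgroup(self, outgroup: str) -> "CharacterMatrix":
        if outgroup not in self.taxa:
            raise ValueError(f"outgroup {outgroup!r} not among taxa")
        return CharacterMatrix(
            list(self.taxa),
            list(self.characters),
            [list(r) for r in self.cells],
            outgroup,
        )

    def same_data(self, other: "CharacterMatrix") -> bool:
        """Equality of taxa, cells and character state labels (not metadata
        such as controlling-character links, which file formats cannot carry)."""
        return (
            self.taxa == other.taxa
            and self.cells == other.cells
            and [c.states for c in self.characters]
            == [c.states for c in other.characters]
            and [c.label for c in self.characters]
            == [c.label for c in other.characters]
        )


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``kind`` is ``"arity"`` or ``"uninformative"``."""

    kind: str
    char_index: int
    taxon: str | None
    message: str


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

#: en-dash and em-dash, both seen in print for the inapplicable symbol
_DASHES = {"–": "-", "—": "-"}


def _normalise_text(text: str) -> str:
    for bad, good in _DASHES.items():
        text = text.replace(bad, good)
    return text


def _cell_from_symbol(sym: str, char: CharacterDefinition, taxon: str) -> int:
    if sym == "?":
        return MISSING
    if sym == "-":
        return INAPPLICABLE
    if sym not in _SYMBOLS:
        raise NexusError(
            f"undeclared symbol {sym!r} for taxon {taxon!r}, "
            f"character {char.index}"
        )
    return int(sym)


def read_nexus(path: str, outgroup: str | None = None) -> CharacterMatrix:
    """Read a standard-datatype NEXUS matrix (DATA or CHARACTERS block).

    ``?`` maps to ``MISSING``; ``-`` (or a typographic dash) to
    ``INAPPLICABLE``.  Taxon order is preserved exactly as in the file, and
    the declared NTAX/NCHAR are cross-checked against the parsed grid.
    """
    with open(path, encoding="utf-8") as fh:
        text = _normalise_text(fh.read())
    try:
        dmat = dendropy.StandardCharacterMatrix.get(
            data=text, schema="nexus", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NexusError(f"cannot parse NEXUS file {path}: {exc}") from exc

    taxa = [t.label for t in dmat.taxon_namespace]
    rows: list[list[str]] = []
    for taxon in dmat.taxon_namespace:
        seq = dmat[taxon]
        rows.append([s.symbol for s in seq])
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise NexusError(f"ragged matrix in {path}: row lengths {sorted(ncols)}")
    nchar = ncols.pop()

    dims = re.search(
        r"DIMENSIONS[^;]*?NTAX\s*=\s*(\d+)[^;]*?NCHAR\s*=\s*(\d+)",
        text,
        re.IGNORECASE | re.DOTALL,
    )
    if dims:
        ntax_decl, nchar_decl = int(dims.group(1)), int(dims.group(2))
        if ntax_decl != len(taxa) or nchar_decl != nchar:
            raise NexusError(
                f"declared NTAX={ntax_decl} NCHAR={nchar_decl} but parsed "
                f"{len(taxa)} taxa x {nchar} characters"
            )

    labels, state_labels = _parse_charstatelabels(text, nchar)
    chars = []
    for j in range(nchar):
        observed = {r[j] for r in rows} - {"?", "-"}
        bad = observed - set(_SYMBOLS)
        if bad:
            raise NexusError(
                f"undeclared symbol(s) {sorted(bad)} in character {j + 1}"
            )
        arity = max(
            (int(s) + 1 for s in observed),
            default=2,
        )
        arity = max(arity, 2)
        states = state_labels.get(j + 1) or tuple(_SYMBOLS[:arity])
        if len(states) < arity:
            states = tuple(_SYMBOLS[:arity])
        chars.append(
            CharacterDefinition(index=j + 1, label=labels.get(j + 1, ""),
                                states=states)
        )

    cells = [
        [_cell_from_symbol(sym, chars[j], taxa[i]) for j, sym in enumerate(row)]
        for i, row in enumerate(rows)
    ]
    return CharacterMatrix(taxa, chars, cells, outgroup)


def _parse_charstatelabels(
    text: str, nchar: int
) -> tuple[dict[int, str], dict[int, tuple[str, ...]]]:
    """Pull character and state labels out of a CHARSTATELABELS statement.

    dendropy tolerates but does not expose this block for standard data, so
    the labels are recovered here with a targeted scan.
    """
    m = re.search(r"CHARSTATELABELS\s+(.*?);", text, re.IGNORECASE | re.DOTALL)
    labels: dict[int, str] = {}
    state_labels: dict[int, tuple[str, ...]] = {}
    if not m:
        return labels, state_labels
    for entry in m.group(1).split(","):
        entry = entry.strip()
        if not entry:
            continue
        head, _, tail = entry.partition("/")
        toks = _nexus_tokens(head)
        if not toks or not toks[0].isdigit():
            continue
        idx = int(toks[0])
        if not 1 <= idx <= nchar:
            continue
        if len(toks) > 1:
            label = " ".join(toks[1:]).replace("_", " ").strip()
            if label:
                labels[idx] = label
        states = _nexus_tokens(tail)
        if states:
            state_labels[idx] = tuple(s.replace("_", " ") for s in states)
    return labels, state_labels


def _nexus_tokens(text: str) -> list[str]:
    """Split on whitespace, honouring single-quoted tokens."""
    return [
        (t[1:-1].replace("''", "'") if t.startswith("'") else t)
        for t in re.findall(r"'(?:[^']|'')*'|\S+", text)
    ]


def _quote(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _cell_symbol(code: int) -> str:
    if code == MISSING:
        return "?"
    if code == INAPPLICABLE:
        return "-"
    return _SYMBOLS[code]


def write_nexus(matrix: CharacterMatrix, path: str) -> str:
    """Write ``matrix`` as a NEXUS DATA block; returns ``path``.

    Inapplicable cells are always emitted as ASCII ``-``.  The output
    re-parses (:func:`read_nexus`) to an equal matrix.
    """
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{_SYMBOLS}" MISSING=? GAP=-;',
    ]
    # always emitted: state labels carry each character's declared arity,
    # which the matrix cells alone cannot
    lines.append("    CHARSTATELABELS")
    entries = []
    for c in matrix.characters:
        label = _quote(c.label.replace(" ", "_")) if c.label else "_"
        states = " ".join(_quote(s.replace(" ", "_")) for s in c.states)
        entries.append(f"        {c.index} {label} / {states}")
    lines.append(",\n".join(entries) + ";")
    lines.append("    MATRIX")
    width = max(len(_quote(t)) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.cells):
        seq = "".join(_cell_symbol(c) for c in row)
        lines.append(f"        {_quote(taxon):<{width}}{seq}")
    lines += ["    ;", "END;", ""]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
    return path


# ---------------------------------------------------------------------------
# TNT xread (minimal dialect)
# ---------------------------------------------------------------------------

def read_tnt(path: str, outgroup: str | None = None) -> CharacterMatrix:
    """Read a minimal TNT ``xread`` file (nchar ntax header, one row per
    taxon, terminated by ``;``).  Convenience only; NEXUS is the native
    format."""
    with open(path, encoding="utf-8") as fh:
        text = _normalise_text(fh.read())
    m = re.search(
        r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)\s+(.*?);",
        text,
        re.IGNORECASE | re.DOTALL,
    )
    if not m:
        raise NexusError(f"no xread block found in {path}")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    taxa: list[str] = []
    rows: list[str] = []
    for line in m.group(3).splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise NexusError(f"cannot parse xread row: {line!r}")
        taxa.append(parts[0])
        rows.append(parts[1])
    if len(taxa) != ntax or any(len(r) != nchar for r in rows):
        raise NexusError(
            f"xread declared {ntax} taxa x {nchar} characters but parsed "
            f"{len(taxa)} rows of lengths {sorted({len(r) for r in rows})}"
        )
    chars = []
    for j in range(nchar):
        observed = {r[j] for r in rows} - {"?", "-"}
        bad = observed - set(_SYMBOLS)
        if bad:
            raise NexusError(f"undeclared symbol(s) {sorted(bad)} in column {j + 1}")
        arity = max(max((int(s) + 1 for s in observed), default=2), 2)
        chars.append(CharacterDefinition(index=j + 1, states=tuple(_SYMBOLS[:arity])))
    cells = [
        [_cell_from_symbol(sym, chars[j], taxa[i]) for j, sym in enumerate(row)]
        for i, row in enumerate(rows)
    ]
    return CharacterMatrix(taxa, chars, cells, outgroup)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_characters(matrix: CharacterMatrix) -> list[Violation]:
    """Report arity breaches and parsimony-uninformative characters.

    Report-only: no exception is raised.  A cell whose state code is not a
    declared state of its character yields an ``"arity"`` violation; a
    character with fewer than two observed states, or whose variation is
    confined to a single taxon, is flagged ``"uninformative"``.
    """
    out: list[Violation] = []
    for c in matrix.characters:
        col = matrix.column(c.index)
        for taxon, cell in zip(matrix.taxa, col):
            if cell >= c.arity:
                out.append(
                    Violation(
                        "arity",
                        c.index,
                        taxon,
                        f"state {cell} exceeds declared arity {c.arity} "
                        f"of character {c.index} in {taxon!r}",
                    )
                )
        if not matrix.is_informative(c.index):
            n_obs = len(matrix.observed_states(c.index))
            what = "constant" if n_obs <= 1 else "autapomorphic"
            out.append(
                Violation(
                    "uninformative",
                    c.index,
                    None,
                    f"character {c.index} is parsimony-uninformative ({what})",
                )
            )
    return out
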