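"""32-cell codon-anticodon representation of the genetic code.

The 64 mRNA codons collapse to 32 anticodon classes because the anticodon
wobble position only resolves purine versus pyrimidine at the codon third
position.  A cell is addressed by (column, row, half):

* column = anticodon position 2 base (pairs the codon 2nd base),
* row    = anticodon position 3 base (pairs the codon 1st base),
* half A = wobble G (reads codon-3rd U/C), half B = wobble C/U (reads A/G).

Column/row numbering follows 1=A, 2=G, 3=U, 4=C.  The internal
representation is per-codon (64 entries); the 32-cell table is a view, so
mixed cells (Ile/Met at AUA/AUG, STOP/Trp at UGA/UGG) lose nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Literal

from Bio.Data import CodonTable

from .trna_model import revcomp

BASES = ("A", "G", "U", "C")
BASE_NUMBER = {b: i + 1 for i, b in enumerate(BASES)}
STOP = "STOP"

Half = Literal["A", "B"]

#: anticodon base preference ordinals at positions 2 and 3: C > (U ~ G) > A
PREFERENCE_ORDINAL = {"C": 2, "U": 1, "G": 1, "A": 0}


@dataclass(frozen=True)
class Anticodon:
    """Anticodon written 5'->3' as (wobble, p2, p3).

    The wobble pairs the codon 3rd base, p2 the codon 2nd, p3 the codon 1st.
    """

    wobble: str
    p2: str
    p3: str

    def __post_init__(self) -> None:
        for b in (self.wobble, self.p2, self.p3):
            if b not in BASES:
                raise ValueError(f"invalid anticodon base {b!r}")

    def __str__(self) -> str:
        return self.wobble + self.p2 + self.p3


def anticodon_for_codon(codon: str) -> Anticodon:
    """The Watson-Crick anticodon of a codon, reported 5'->3'."""
    if len(codon) != 3:
        raise ValueError(f"codon must be a triplet, got {codon!r}")
    return Anticodon(*revcomp(codon))


def wobble_reads(wobble_base: str) -> frozenset[str]:
    """Codon third-position bases read by an anticodon wobble base.

    Wobble A is represented but effectively unused in archaea/bacteria; it
    returns the empty set with a warning.
    """
    if wobble_base not in BASES:
        raise ValueError(f"invalid base {wobble_base!r}")
    if wobble_base == "A":
        warnings.warn(
            "anticodon wobble A is disfavored/unused; returning empty read set",
            stacklevel=2,
        )
        return frozenset()
    return {"G": frozenset("UC"), "C": frozenset("G"), "U": frozenset("AG")}[wobble_base]


@dataclass(frozen=True)
class CellKey:
    """Address of one of the 32 cells."""

    column: str  # anticodon p2 base
    row: str  # anticodon p3 base
    half: Half  # A = wobble G, B = wobble C/U

    def __post_init__(self) -> None:
        if self.column not in BASES or self.row not in BASES:
            raise ValueError(f"invalid cell address {self}")
        if self.half not in ("A", "B"):
            raise ValueError(f"half must be 'A' or 'B', got {self.half!r}")

    @property
    def column_number(self) -> int:
        return BASE_NUMBER[self.column]

    @property
    def row_number(self) -> int:
        return BASE_NUMBER[self.row]

    @property
    def codons(self) -> tuple[str, str]:
        """The two codons this cell reads (third position U/C or A/G)."""
        first = revcomp(self.row)
        second = revcomp(self.column)
        thirds = ("U", "C") if self.half == "A" else ("A", "G")
        return tuple(first + second + t for t in thirds)

    def label(self) -> str:
        return f"{self.column_number}-{self.row_number}{self.half}"


def cell_for_codon(codon: str) -> CellKey:
    ac = anticodon_for_codon(codon)
    half: Half = "A" if codon[2] in "UC" else "B"
    return CellKey(column=ac.p2, row=ac.p3, half=half)


def enumerate_cells() -> list[CellKey]:
    """All 32 cells in column-major, row-major, half order."""
    return [
        CellKey(column=c, row=r, half=h)
        for c in BASES
        for r in BASES
        for h in ("A", "B")
    ]


@dataclass(frozen=True)
class CodeCell:
    """A cell of a CodeState: the address plus its two codon assignments."""

    key: CellKey
    assignments: tuple[tuple[str, str], ...]  # ((codon, amino acid or STOP), ...)

    @property
    def mixed(self) -> bool:
        return len({aa for _, aa in self.assignments}) > 1

    @property
    def amino_acids(self) -> frozenset[str]:
        return frozenset(aa for _, aa in self.assignments)


@dataclass(frozen=True)
class CodeState:
    """A full per-codon assignment of the 64 codons, viewable as 32 cells."""

    assignments: dict[str, str]
    stage: str = ""

    def __post_init__(self) -> None:
        expected = {f + s + t for f in BASES for s in BASES for t in BASES}
        if set(self.assignments) != expected:
            missing = expected - set(self.assignments)
            extra = set(self.assignments) - expected
            raise ValueError(f"codon set mismatch: missing={missing}, extra={extra}")

    def __getitem__(self, codon: str) -> str:
        return self.assignments[codon]

    def cell(self, key: CellKey) -> CodeCell:
        return CodeCell(
            key=key,
            assignments=tuple((c, self.assignments[c]) for c in key.codons),
        )

    def cells(self) -> Iterator[CodeCell]:
        for key in enumerate_cells():
            yield self.cell(key)

    def amino_acids(self) -> frozenset[str]:
        """Distinct amino acids assigned, excluding STOP."""
        return frozenset(self.assignments.values()) - {STOP}

    def with_assignments(self, updates: dict[str, str], stage: str | None = None) -> "CodeState":
        merged = dict(self.assignments)
        merged.update(updates)
        return CodeState(merged, stage=self.stage if stage is None else stage)


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def standard_code_state() -> CodeState:
    """The standard genetic code as a CodeState (three-letter amino acids)."""
    table = CodonTable.unambiguous_rna_by_id[1]
    assignments = {c: _AA3[aa] for c, aa in table.forward_table.items()}
    for stop in table.stop_codons:
        assignments[stop] = STOP
    return CodeState(assignments, stage="standard")


def preference_score(obj: CellKey | Anticodon) -> tuple[int, int]:
    """(p2 ordinal, p3 ordinal) on the C>(U~G)>A scale; compare lexicographically."""
    if isinstance(obj, CellKey):
        p2, p3 = obj.column, obj.row
    else:
        p2, p3 = obj.p2, obj.p3
    return (PREFERENCE_ORDINAL[p2], PREFERENCE_ORDINAL[p3])


def rank_cells(state: CodeState) -> list[list[CodeCell]]:
    """Cells sorted by descending preference, grouped into tie groups.

    The sort is stable over the canonical enumerate_cells order, so the
    output is invariant to how the state was produced.
    """
    groups: dict[tuple[int, int], list[CodeCell]] = {}
    for cell in state.cells():
        groups.setdefault(preference_score(cell.key), []).append(cell)
    return [groups[score] for score in sorted(groups, reverse=True)]
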