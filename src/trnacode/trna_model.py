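"""Repeat-derived tRNA origin model.

Builds the three 31-nt minihelices from the primordial repeat sequences,
ligates them into the 93-nt precursor, and applies internal 9-nt junction
deletions to produce type I (75 nt) and type II (84 nt) tRNA core models,
optionally with the 3'-ACCA extension.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

RNA_BASES = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

MinihelixKind = Literal["dloop", "anticodon", "tloop"]
Retain = Literal["five_prime", "three_prime"]
TrnaType = Literal["I", "II"]


def revcomp(sequence: str) -> str:
    """Reverse complement of an RNA sequence (A<->U, G<->C)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(sequence))
    except KeyError as exc:
        raise ValueError(
            f"non-RNA symbol {exc.args[0]!r} in sequence {sequence!r}"
        ) from None


def _check_rna(sequence: str, what: str) -> None:
    bad = set(sequence) - RNA_BASES
    if bad:
        raise ValueError(f"{what} contains non-RNA symbols: {sorted(bad)}")


@dataclass(frozen=True)
class PrimordialSpec:
    """The primordial repeat sequences from which the model tRNA is assembled.

    ``sls17`` (the shared anticodon/T stem-loop-stem) is a constructor
    parameter because its 7-nt loop is the one slightly ambiguous stretch;
    the printed sequence is the default.
    """

    acc5: str = "GCGGCGG"
    dloop17: str = "UAGCCUAGCCUAGCCUA"
    sls17: str = "CCGGGUUAAAAACCCGG"
    acca: str = "ACCA"
    motifs: tuple[str, ...] = ("GCG", "CGC", "UAGCC")

    def __post_init__(self) -> None:
        for name in ("acc5", "dloop17", "sls17", "acca"):
            _check_rna(getattr(self, name), name)
        if len(self.acc5) != 7:
            raise ValueError("acc5 must be a 7-mer")
        if len(self.dloop17) != 17 or len(self.sls17) != 17:
            raise ValueError("dloop17 and sls17 must be 17-mers")
        if revcomp(self.sls17[:5]) != self.sls17[12:]:
            raise ValueError("sls17 stems (1-5 vs 13-17) are not complementary")

    @property
    def acc3(self) -> str:
        """3'-acceptor strand: reverse complement of the 5' strand."""
        return revcomp(self.acc5)

    @property
    def junction14(self) -> str:
        """The 14-mer spelled at each minihelix seam (acc3 + acc5)."""
        return self.acc3 + self.acc5

    @property
    def remnant_d(self) -> str:
        """5-mer left at junction 1 (last 5 of the 14-mer)."""
        return self.junction14[-5:]

    @property
    def remnant_v(self) -> str:
        """5-mer left at junction 2 (first 5 of the 14-mer); the type I V loop."""
        return self.junction14[:5]


DEFAULT_SPEC = PrimordialSpec()


@dataclass(frozen=True)
class Segment:
    """A named, 1-based inclusive span of a model sequence with provenance."""

    name: str
    sequence: str
    start: int
    end: int
    origin: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"segment {self.name}: span {self.start}-{self.end} does not "
                f"match sequence length {len(self.sequence)}"
            )

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _tile(parts: Iterable[tuple[str, str, str]], offset: int = 0) -> list[Segment]:
    """Lay out (name, sequence, origin) triples as contiguous segments."""
    segments = []
    pos = offset + 1
    for name, seq, origin in parts:
        segments.append(Segment(name, seq, pos, pos + len(seq) - 1, origin))
        pos += len(seq)
    return segments


def concat(segments: Iterable[Segment]) -> str:
    return "".join(s.sequence for s in segments)


def build_minihelix(kind: MinihelixKind, spec: PrimordialSpec = DEFAULT_SPEC) -> list[Segment]:
    """One 31-nt minihelix: acc5(7) + 17-nt inner + acc3(7).

    The inner 17-mer is the D-loop repeat for kind='dloop' and the shared
    stem-loop-stem for 'anticodon' and 'tloop' (those two are identical by
    construction).
    """
    inners = {"dloop": spec.dloop17, "anticodon": spec.sls17, "tloop": spec.sls17}
    if kind not in inners:
        raise ValueError(f"unknown minihelix kind {kind!r}")
    origin = f"minihelix:{kind}"
    inner_name = {"dloop": "dloop", "anticodon": "acloop", "tloop": "tloop"}[kind]
    return _tile(
        [
            ("acc5", spec.acc5, origin),
            (inner_name, inners[kind], origin),
            ("acc3", spec.acc3, origin),
        ]
    )


def assemble_precursor(spec: PrimordialSpec = DEFAULT_SPEC) -> list[Segment]:
    """The 93-nt precursor: three minihelices ligated in D, anticodon, T order.

    Segment names at the two internal seams are suffixed _j1/_j2 so the
    junction 14-mers (acc3+acc5) remain addressable after ligation.
    """
    parts = [
        ("acc5", spec.acc5, "minihelix:dloop"),
        ("dloop", spec.dloop17, "minihelix:dloop"),
        ("acc3_j1", spec.acc3, "minihelix:dloop"),
        ("acc5_j1", spec.acc5, "minihelix:anticodon"),
        ("acloop", spec.sls17, "minihelix:anticodon"),
        ("acc3_j2", spec.acc3, "minihelix:anticodon"),
        ("acc5_j2", spec.acc5, "minihelix:tloop"),
        ("tloop", spec.sls17, "minihelix:tloop"),
        ("acc3", spec.acc3, "minihelix:tloop"),
    ]
    return _tile(parts)


def delete_junction(
    sequence: str,
    junction_ordinal: Literal[1, 2],
    retain: Retain,
    junction: str | None = None,
) -> str:
    """Remove 9 contiguous bases from within a junction 14-mer occurrence.

    ``junction_ordinal`` 1 addresses the 5'-most occurrence of the 14-mer,
    2 the 3'-most (so ordinal 2 still works on an intermediate in which
    junction 1 has already been processed).  retain='three_prime' keeps the
    last 5 bases of the 14-mer (canonically GGCGG); retain='five_prime'
    keeps the first 5 (canonically CCGCC).
    """
    junction = DEFAULT_SPEC.junction14 if junction is None else junction
    if junction_ordinal not in (1, 2):
        raise ValueError("junction_ordinal must be 1 or 2")
    if retain not in ("five_prime", "three_prime"):
        raise ValueError("retain must be 'five_prime' or 'three_prime'")
    occurrences = []
    i = sequence.find(junction)
    while i != -1:
        occurrences.append(i)
        i = sequence.find(junction, i + 1)
    if not occurrences:
        raise ValueError(f"junction 14-mer {junction!r} not found in sequence")
    pos = occurrences[0] if junction_ordinal == 1 else occurrences[-1]
    if retain == "three_prime":
        # delete the maximal prefix of the 14-mer
        cut_start = pos
    else:
        # delete the maximal suffix
        cut_start = pos + len(junction) - 9
    return sequence[:cut_start] + sequence[cut_start + 9 :]


@dataclass(frozen=True)
class TRNAModel:
    """A segmented type I or type II primordial tRNA model."""

    trna_type: TrnaType
    segments: tuple[Segment, ...]
    with_acca: bool
    spec: PrimordialSpec = field(default=DEFAULT_SPEC, repr=False)

    @property
    def sequence(self) -> str:
        return concat(self.segments)

    @property
    def core(self) -> str:
        """The core sequence without any 3'-ACCA extension."""
        return "".join(s.sequence for s in self.segments if s.name != "acca")

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def core_length(self) -> int:
        return len(self.core)


def build_trna_pri(
    trna_type: TrnaType = "I",
    with_acca: bool = False,
    spec: PrimordialSpec = DEFAULT_SPEC,
) -> TRNAModel:
    """Apply internal-deletion processing to the precursor.

    Type II processes junction 1 only (the intact junction 2 becomes the
    expanded V loop); type I processes both junctions.  Segment annotations
    are carried through the deletions: junction remnants keep the provenance
    of the strand they descend from.
    """
    if trna_type not in ("I", "II"):
        raise ValueError(f"trna_type must be 'I' or 'II', got {trna_type!r}")
    parts: list[tuple[str, str, str]] = [
        ("acc5", spec.acc5, "minihelix:dloop"),
        ("dloop", spec.dloop17, "minihelix:dloop"),
        # junction 1 processed in both types: 9-nt deletion retains the
        # 3' five bases (GGCGG), a remnant of the anticodon minihelix acc5
        ("acc5_j1", spec.remnant_d, "minihelix:anticodon acc5, junction-1 remnant"),
        ("acloop", spec.sls17, "minihelix:anticodon"),
    ]
    if trna_type == "I":
        # junction 2 processed: deletion retains the 5' five bases (CCGCC)
        parts.append(
            ("vloop", spec.remnant_v, "minihelix:anticodon acc3, junction-2 remnant")
        )
    else:
        parts.append(("vloop", spec.junction14, "junction 2, unprocessed acc3+acc5"))
    parts += [
        ("tloop", spec.sls17, "minihelix:tloop"),
        ("acc3", spec.acc3, "minihelix:tloop"),
    ]
    if with_acca:
        parts.append(("acca", spec.acca, "3'-ACCA addition"))
    model = TRNAModel(
        trna_type=trna_type,
        segments=tuple(_tile(parts)),
        with_acca=with_acca,
        spec=spec,
    )
    # cross-check against the string-level construction
    expected = assemble_precursor_sequence(spec)
    expected = delete_junction(expected, 1, "three_prime", spec.junction14)
    if trna_type == "I":
        expected = delete_junction(expected, 2, "five_prime", spec.junction14)
    if model.core != expected:
        raise AssertionError("segmented model disagrees with junction-deletion construction")
    return model


def assemble_precursor_sequence(spec: PrimordialSpec = DEFAULT_SPEC) -> str:
    return concat(assemble_precursor(spec))


@dataclass(frozen=True)
class Check:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[Check, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[Check]:
        return [c for c in self.checks if not c.passed]


def validate_model(model: TRNAModel) -> ValidationReport:
    """Structural self-consistency checks; failures are reported, not raised."""
    checks: list[Check] = []
    seq = model.sequence

    # segment tiling
    tiled = all(
        a.end + 1 == b.start for a, b in zip(model.segments, model.segments[1:])
    ) and model.segments[0].start == 1 and model.segments[-1].end == len(seq)
    checks.append(Check("segment_tiling", tiled))

    # acceptor stem: 7-bp complementarity between acc5 and acc3
    acc5 = model.segment("acc5").sequence
    acc3 = model.segment("acc3").sequence
    mismatches = [
        i + 1 for i, (a, b) in enumerate(zip(acc5, reversed(acc3)))
        if _COMPLEMENT[a] != b
    ]
    checks.append(
        Check(
            "acceptor_stem_7bp",
            not mismatches,
            f"mismatched acc5 positions: {mismatches}" if mismatches else "",
        )
    )

    # both stem-loop-stems: 5-bp stems, 7-nt loop
    for name in ("acloop", "tloop"):
        sls = model.segment(name).sequence
        ok_len = len(sls) == 17
        checks.append(Check(f"{name}_length_17", ok_len))
        if ok_len:
            bad = [
                i + 1 for i, (a, b) in enumerate(zip(sls[:5], reversed(sls[12:])))
                if _COMPLEMENT[a] != b
            ]
            checks.append(
                Check(
                    f"{name}_stem_5bp",
                    not bad,
                    f"mismatched stem positions: {bad}" if bad else "",
                )
            )
            checks.append(Check(f"{name}_loop_length_7", len(sls[5:12]) == 7))

    expected_core = {"I": 75, "II": 84}[model.trna_type]
    checks.append(
        Check(
            "core_length",
            model.core_length == expected_core,
            f"expected {expected_core}, got {model.core_length}",
        )
    )
    if model.with_acca:
        checks.append(Check("acca_suffix", seq.endswith(model.spec.acca)))
    return ValidationReport(tuple(checks))
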