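"""Stepwise sectoring model of genetic code evolution.

Starting from an all-Gly 32-cell table, amino acids invade in four stages
(columns, split8, post_latch_16, completion), each event displacing an
incumbent from a set of cells (or individual codons for the two mixed
cells).  The stage event lists are data: a packaged TSV encodes the shipped
trajectory, and alternative orderings can be supplied as files with the
same schema.

The displacement audit checks the anticodon preference rule: within a
column and wobble half, an incumbent's retained cells are never less
favored (third-position ordinal) than the cells it ceded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .code_table import (
    BASES,
    PREFERENCE_ORDINAL,
    CellKey,
    CodeState,
    cell_for_codon,
)

STAGES = ("columns", "split8", "post_latch_16", "completion")
_PRE_STAGE = "initial"


@dataclass(frozen=True)
class SectoringEvent:
    stage: str
    cells: tuple[CellKey, ...]
    codons: tuple[str, ...]  # the codons actually reassigned
    incoming: str
    displaced: str
    rule: str = ""

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("event must target at least one cell")
        if self.incoming == self.displaced:
            raise ValueError("incoming and displaced must differ")


def _parse_multi(token: str, valid: Sequence[str]) -> tuple[str, ...]:
    if token == "*":
        return tuple(valid)
    values = tuple(t.strip() for t in token.split(","))
    for v in values:
        if v not in valid:
            raise ValueError(f"invalid token {v!r} (expected one of {list(valid)} or '*')")
    return values


def load_events(path: str | Path | None = None) -> list[SectoringEvent]:
    """Read an event TSV (stage, column, rows, half, codons, incoming, displaced, rule).

    With no path, the packaged trajectory is loaded.
    """
    if path is None:
        ref = resources.files("trnacode.data").joinpath("sectoring_events.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    events: list[SectoringEvent] = []
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for lineno, row in enumerate(reader, start=2):
        stage = row["stage"].strip()
        if stage not in STAGES:
            raise ValueError(f"line {lineno}: unknown stage {stage!r}")
        rows = _parse_multi(row["rows"].strip(), BASES)
        halves = _parse_multi(row["half"].strip(), ("A", "B"))
        cells = tuple(
            CellKey(column=row["column"].strip(), row=r, half=h)
            for r in rows
            for h in halves
        )
        cell_codons = [c for key in cells for c in key.codons]
        codon_token = row["codons"].strip()
        if codon_token in ("-", ""):
            codons = tuple(cell_codons)
        else:
            codons = tuple(t.strip() for t in codon_token.split(","))
            bad = set(codons) - set(cell_codons)
            if bad:
                raise ValueError(f"line {lineno}: codons {sorted(bad)} outside target cells")
        events.append(
            SectoringEvent(
                stage=stage,
                cells=cells,
                codons=codons,
                incoming=row["incoming"].strip(),
                displaced=row["displaced"].strip(),
                rule=row.get("rule", "").strip(),
            )
        )
    if not events:
        raise ValueError("event file contains no events")
    return events


def initial_state() -> CodeState:
    """The primordial one-letter code: every codon reads Gly."""
    assignments = {f + s + t: "Gly" for f in BASES for s in BASES for t in BASES}
    return CodeState(assignments, stage=_PRE_STAGE)


def apply_event(state: CodeState, event: SectoringEvent) -> CodeState:
    """Reassign the event's codons to the incoming amino acid.

    Every target codon must currently be held by the declared displaced
    incumbent; anything else means the event list is inconsistent with the
    state it is being applied to.
    """
    updates = {}
    for codon in event.codons:
        holder = state[codon]
        if holder != event.displaced:
            raise ValueError(
                f"event {event.incoming}<-{event.displaced}: codon {codon} is "
                f"held by {holder}, not {event.displaced}"
            )
        updates[codon] = event.incoming
    return state.with_assignments(updates)


def _apply_stage(state: CodeState, stage: str, events: Sequence[SectoringEvent]) -> CodeState:
    expected_prev = _PRE_STAGE if stage == STAGES[0] else STAGES[STAGES.index(stage) - 1]
    if state.stage != expected_prev:
        raise ValueError(
            f"stage {stage!r} must be applied to a {expected_prev!r} state, "
            f"got {state.stage!r}"
        )
    for event in events:
        if event.stage != stage:
            continue
        state = apply_event(state, event)
    return state.with_assignments({}, stage=stage)


def stage_columns(state: CodeState, events: Sequence[SectoringEvent] | None = None) -> CodeState:
    return _apply_stage(state, "columns", events or load_events())


def stage_split8(state: CodeState, events: Sequence[SectoringEvent] | None = None) -> CodeState:
    return _apply_stage(state, "split8", events or load_events())


def stage_post_latch(state: CodeState, events: Sequence[SectoringEvent] | None = None) -> CodeState:
    return _apply_stage(state, "post_latch_16", events or load_events())


def stage_completion(state: CodeState, events: Sequence[SectoringEvent] | None = None) -> CodeState:
    return _apply_stage(state, "completion", events or load_events())


@dataclass(frozen=True)
class Trajectory:
    """The event log and the state after each stage (initial state first)."""

    events: tuple[SectoringEvent, ...]
    states: tuple[CodeState, ...]  # initial + one per stage

    @property
    def initial(self) -> CodeState:
        return self.states[0]

    @property
    def final(self) -> CodeState:
        return self.states[-1]

    def state_after(self, stage: str) -> CodeState:
        for s in self.states:
            if s.stage == stage:
                return s
        raise KeyError(stage)


def run_full_trajectory(events: Sequence[SectoringEvent] | None = None) -> Trajectory:
    """Apply the four stages in order from the all-Gly state."""
    events = list(load_events() if events is None else events)
    states = [initial_state()]
    for stage in STAGES:
        states.append(_apply_stage(states[-1], stage, events))
    return Trajectory(events=tuple(events), states=tuple(states))


@dataclass(frozen=True)
class AuditRow:
    incumbent: str
    column: str
    half: str
    ceded_cells: tuple[str, ...]
    retained_cells: tuple[str, ...]
    ceded_ordinals: tuple[int, ...]
    retained_ordinals: tuple[int, ...]

    @property
    def ok(self) -> bool:
        if not self.ceded_ordinals or not self.retained_ordinals:
            return True
        return min(self.retained_ordinals) >= max(self.ceded_ordinals)


def displacement_audit(trajectory: Trajectory) -> list[AuditRow]:
    """Check that displaced incumbents ended up keeping their favored cells.

    For each incumbent, within each column and wobble half: the minimum
    third-position preference ordinal over the cells it holds in the final
    state must be >= the maximum ordinal over the cells it ceded during the
    trajectory.  Halves are compared separately so the column-3 wobble
    split (where the incumbent exits a half entirely, with no row-preference
    content) stays vacuous.  Pairs where the incumbent retains nothing in
    the column are also vacuous: the rule concerns what retained cells look
    like, not whether any were retained.
    """
    ceded: dict[tuple[str, str, str], set[CellKey]] = {}
    for event in trajectory.events:
        for codon in event.codons:
            key = cell_for_codon(codon)
            ceded.setdefault((event.displaced, key.column, key.half), set()).add(key)
    final = trajectory.final
    rows: list[AuditRow] = []
    for (incumbent, column, half), ceded_cells in sorted(
        ceded.items(), key=lambda kv: kv[0]
    ):
        retained = [
            k
            for k in (CellKey(column, r, half) for r in BASES)
            if any(final[c] == incumbent for c in k.codons)
        ]
        rows.append(
            AuditRow(
                incumbent=incumbent,
                column=column,
                half=half,
                ceded_cells=tuple(sorted(k.label() for k in ceded_cells)),
                retained_cells=tuple(sorted(k.label() for k in retained)),
                ceded_ordinals=tuple(
                    PREFERENCE_ORDINAL[k.row] for k in sorted(ceded_cells, key=lambda k: k.label())
                ),
                retained_ordinals=tuple(PREFERENCE_ORDINAL[k.row] for k in retained),
            )
        )
    return rows


def audit_violations(rows: Iterable[AuditRow]) -> list[AuditRow]:
    return [r for r in rows if not r.ok]
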