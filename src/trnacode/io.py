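"""FASTA and score-matrix CSV I/O, plus run manifests.

The matrix dialect mirrors the printed homology tables: a square CSV with a
``query`` header column, integer scores, ``ND`` for not detected
(off-diagonal, treated as missing) and ``NR`` on the diagonal (self
comparisons, never scored).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("trnacode")

ND = "ND"
NR = "NR"


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file into uppercase RNA records.

    DNA-alphabet input (T) is normalized to U with a logged warning.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(f"{path}:{lineno}: expected FASTA header '>' first")
            break
    records: list[FastaRecord] = []
    seen: set[str] = set()
    normalized = False
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: record with empty identifier")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record identifier {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "T" in seq:
            seq = seq.replace("T", "U")
            normalized = True
        records.append(FastaRecord(rec.id, seq))
    if normalized:
        logger.warning("%s: DNA alphabet detected; T normalized to U", path)
    return records


def write_fasta(records: list[FastaRecord], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")
    del width  # SeqIO wraps at 60 already


def read_matrix_csv(path: str | Path) -> tuple[list[str], dict[tuple[str, str], int]]:
    """Parse a directed score matrix; returns (names, {(query, target): score}).

    ND cells are omitted from the score dict; NR is required on (and only
    on) the diagonal.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    header = [h.strip() for h in rows[0][1:]]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate enzyme names {dupes}")
    body = [r for r in rows[1:] if any(c.strip() for c in r)]
    if len(body) != len(header):
        raise ValueError(
            f"{path}: non-square matrix ({len(body)} rows vs {len(header)} columns)"
        )
    scores: dict[tuple[str, str], int] = {}
    row_names: list[str] = []
    for i, row in enumerate(body):
        qname = row[0].strip()
        row_names.append(qname)
        if len(row) - 1 != len(header):
            raise ValueError(f"{path}: row {qname!r} has {len(row) - 1} cells")
        for j, cell in enumerate(row[1:]):
            token = cell.strip()
            tname = header[j]
            diagonal = qname == tname
            if token == NR:
                if not diagonal:
                    raise ValueError(
                        f"{path}: NR off the diagonal at ({qname!r}, {tname!r})"
                    )
                continue
            if diagonal:
                raise ValueError(f"{path}: diagonal ({qname!r}) must be NR, got {token!r}")
            if token == ND:
                continue
            try:
                value = int(token)
            except ValueError:
                raise ValueError(
                    f"{path}: unknown token {token!r} at ({qname!r}, {tname!r})"
                ) from None
            if value <= 0:
                raise ValueError(
                    f"{path}: scores must be positive, got {value} at ({qname!r}, {tname!r})"
                )
            scores[(qname, tname)] = value
    if row_names != header:
        raise ValueError(f"{path}: row names do not match column names")
    return header, scores


def write_matrix_csv(
    names: list[str],
    scores: dict[tuple[str, str], int],
    path: str | Path,
    corner: str = "query",
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow([corner, *names])
        for q in names:
            row = [q]
            for t in names:
                if q == t:
                    row.append(NR)
                else:
                    row.append(str(scores[(q, t)]) if (q, t) in scores else ND)
            writer.writerow(row)


@dataclass
class RunManifest:
    """Provenance record emitted by every CLI run."""

    command: str
    parameters: dict
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())

    def add_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_digests[str(path)] = digest

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
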