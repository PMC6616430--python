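"""Scoring tRNA sequences against the segmented primordial model.

Includes per-segment identity profiles, a positional-identity permutation
test for loop homology, repeat-motif phase scoring, and pairwise tRNAome
distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .io import FastaRecord
from .trna_model import RNA_BASES, TRNAModel

INSERTION = "insertion"

#: default alignment parameters (match, mismatch, gap open, gap extend)
DEFAULT_SCORING = (1.0, -1.0, -4.0, -1.0)


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass(frozen=True)
class SegmentAssignment:
    """Per-position segment labels for a query aligned to a model core."""

    labels: tuple[str, ...]  # one per query position; segment name or 'insertion'
    aligned_pairs: tuple[tuple[int, int], ...]  # (query index, core index), 0-based


def _position_segments(model: TRNAModel) -> list[str]:
    labels: list[str] = []
    for seg in model.segments:
        if seg.name == "acca":
            continue
        labels.extend([seg.name] * len(seg.sequence))
    return labels


def segment_sequence(
    trna_seq: str,
    model: TRNAModel,
    gap_open: float = DEFAULT_SCORING[2],
    gap_extend: float = DEFAULT_SCORING[3],
    match: float = DEFAULT_SCORING[0],
    mismatch: float = DEFAULT_SCORING[1],
    length_slack: tuple[int, int] = (10, 8),
) -> SegmentAssignment:
    """Assign each query position to a model segment (or 'insertion').

    A query exactly the core length maps positionally; otherwise the query
    is globally aligned to the core with affine gaps and positions inherit
    the segment label of the core position they align to.

    The default length window rejects a type II query against a type I
    model (upper slack 8 < the 9-nt V-loop expansion); widen
    ``length_slack`` to accept longer queries deliberately.
    """
    bad = set(trna_seq) - RNA_BASES
    if bad:
        raise ValueError(f"query contains non-RNA symbols: {sorted(bad)}")
    core = model.core
    lo, hi = len(core) - length_slack[0], len(core) + length_slack[1]
    if not lo <= len(trna_seq) <= hi:
        raise ValueError(
            f"query length {len(trna_seq)} outside [{lo}, {hi}] for a type "
            f"{model.trna_type} model; check the tRNA type"
        )
    core_labels = _position_segments(model)
    if len(trna_seq) == len(core):
        return SegmentAssignment(
            labels=tuple(core_labels),
            aligned_pairs=tuple((i, i) for i in range(len(core))),
        )
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    alignment = aligner.align(trna_seq, core)[0]
    labels = [INSERTION] * len(trna_seq)
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (cs, ce) in zip(*alignment.aligned):
        for k in range(qe - qs):
            labels[qs + k] = core_labels[cs + k]
            pairs.append((qs + k, cs + k))
    return SegmentAssignment(labels=tuple(labels), aligned_pairs=tuple(pairs))


@dataclass(frozen=True)
class IdentityProfile:
    per_segment: dict[str, float]
    overall: float
    aligned_length: int


def identity_to_pri(trna_seq: str, model: TRNAModel, **align_kwargs) -> IdentityProfile:
    """Fraction of aligned positions identical to the model, per segment and overall."""
    assignment = segment_sequence(trna_seq, model, **align_kwargs)
    core = model.core
    seg_total: dict[str, int] = {}
    seg_match: dict[str, int] = {}
    for q, c in assignment.aligned_pairs:
        name = assignment.labels[q]
        seg_total[name] = seg_total.get(name, 0) + 1
        if trna_seq[q] == core[c]:
            seg_match[name] = seg_match.get(name, 0) + 1
    aligned = sum(seg_total.values())
    matches = sum(seg_match.values())
    per_segment = {name: seg_match.get(name, 0) / n for name, n in seg_total.items()}
    return IdentityProfile(
        per_segment=per_segment,
        overall=matches / aligned if aligned else 0.0,
        aligned_length=aligned,
    )


@dataclass(frozen=True)
class PermutationResult:
    statistic: float
    n_perm: int
    p_value: float
    seed: int
    null_mean: float
    null_sd: float


def loop_homology_test(seq_a: str, seq_b: str, n_perm: int = 9999, seed: int = 0) -> PermutationResult:
    """Positional-identity permutation test for homology of two loops.

    The null redraws seq_b as uniform position shuffles (composition is
    preserved exactly); p-value uses the add-one rule
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequences differ in length: {len(seq_a)} vs {len(seq_b)}")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    statistic = float(np.mean(a == b))
    rng = np.random.default_rng(seed)
    n = len(seq_b)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    null = np.mean(b[perms] == a[None, :], axis=1)
    p = (1 + int(np.sum(null >= statistic))) / (n_perm + 1)
    return PermutationResult(
        statistic=statistic,
        n_perm=n_perm,
        p_value=p,
        seed=seed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
    )


def repeat_score(seq: str, motif: str) -> float:
    """Best-phase fraction of positions matching the infinitely tiled motif.

    Maximum over all cyclic phases of the motif; invariant to cyclic
    rotation of the motif by construction.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    m = len(motif)
    best = 0.0
    for phase in range(m):
        hits = sum(1 for i, base in enumerate(seq) if base == motif[(i + phase) % m])
        best = max(best, hits / len(seq)) if seq else 0.0
    return best


def _pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    alignment = aligner.align(a, b)[0]
    matches = 0
    columns = 0
    prev_q = prev_t = 0
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        columns += max(qs - prev_q, ts - prev_t)  # gap columns between blocks
        for k in range(qe - qs):
            columns += 1
            if a[qs + k] == b[ts + k]:
                matches += 1
        prev_q, prev_t = qe, te
    columns += max(len(a) - prev_q, len(b) - prev_t)
    return matches / columns if columns else 1.0


def trnaome_distance(
    records: list[FastaRecord],
    match: float = DEFAULT_SCORING[0],
    mismatch: float = DEFAULT_SCORING[1],
    gap_open: float = DEFAULT_SCORING[2],
    gap_extend: float = DEFAULT_SCORING[3],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise (1 - global-alignment identity) distances and nearest neighbors.

    Nearest-neighbor ties break lexicographically on the record identifier.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record identifiers: {dupes}")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - _pairwise_identity(records[i].sequence, records[j].sequence, aligner)
            dist[i, j] = dist[j, i] = d
    frame = pd.DataFrame(dist, index=ids, columns=ids)
    nearest: dict[str, str] = {}
    for i, rid in enumerate(ids):
        candidates = [(dist[i, j], ids[j]) for j in range(n) if j != i]
        nearest[rid] = min(candidates)[1]
    return frame, nearest
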