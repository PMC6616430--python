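"""Seeded synthetic data: mutated tRNAomes and planted-tree score matrices.

Everything here is a pure function of (config, seed): identical inputs give
byte-identical outputs, so the analysis stages are testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .aars_network import ScoreMatrix
from .code_table import STOP, CodeState, standard_code_state
from .io import FastaRecord
from .trna_model import RNA_BASES, build_trna_pri, revcomp

_BASES = sorted(RNA_BASES)

#: anticodon span (0-based, half-open) inside the type I core: loop
#: positions 3-5 of the anticodon stem-loop-stem
ANTICODON_SPAN = (36, 39)

#: spans (0-based, half-open) where indels are tolerated: the D loop and V
#: loop, where real tRNA length variation occurs
INDEL_SPANS_TYPE_I = ((7, 24), (46, 51))


@dataclass(frozen=True)
class MutationConfig:
    substitution_rate: float
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")


def mutate_sequence(
    seq: str,
    config: MutationConfig,
    indel_spans: tuple[tuple[int, int], ...] | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Per-site substitution (uniform over the 3 alternatives) and indel noise.

    Indels are restricted to ``indel_spans`` (0-based half-open; default:
    anywhere).  Pass an externally seeded ``rng`` to chain mutations, e.g.
    for parent/child tRNAome construction.
    """
    bad = set(seq) - RNA_BASES
    if bad:
        raise ValueError(f"sequence contains non-RNA symbols: {sorted(bad)}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: list[str] = []
    indel_ok = (
        (lambda i: True)
        if indel_spans is None
        else (lambda i: any(lo <= i < hi for lo, hi in indel_spans))
    )
    for i, base in enumerate(seq):
        if config.indel_rate and indel_ok(i) and rng.random() < config.indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(_BASES[rng.integers(4)])  # insertion before the site
        if rng.random() < config.substitution_rate:
            alternatives = [b for b in _BASES if b != base]
            out.append(alternatives[rng.integers(3)])
        else:
            out.append(base)
    return "".join(out)


def _usable_codons(code_state: CodeState) -> list[str]:
    """Codons with an amino acid assignment whose anticodon avoids wobble A.

    Anticodon wobble A corresponds to codon third-position U, which is
    effectively unused, so those codons are excluded.
    """
    return sorted(
        codon
        for codon, aa in code_state.assignments.items()
        if aa != STOP and codon[2] != "U"
    )


def synth_trnaome(
    n_records: int,
    config: MutationConfig,
    code_state: CodeState | None = None,
) -> list[FastaRecord]:
    """Synthetic tRNAome: mutated copies of the type I core with real anticodons.

    Each record derives from the primordial type I core by seeded mutation
    (indels confined to the D and V loops), then has its anticodon triplet
    overwritten with the anticodon of a codon drawn from ``code_state``.
    Identifiers encode the amino acid and the anticodon.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    code_state = standard_code_state() if code_state is None else code_state
    core = build_trna_pri("I").core
    codons = _usable_codons(code_state)
    rng = np.random.default_rng(config.seed)
    lo, hi = ANTICODON_SPAN
    # the anticodon triplet itself is overwritten, so the flanks are mutated
    # independently; indel spans are re-expressed relative to each flank
    prefix_spans = tuple(
        (a, min(b, lo)) for a, b in INDEL_SPANS_TYPE_I if a < lo
    )
    suffix_spans = tuple(
        (max(a, hi) - hi, b - hi) for a, b in INDEL_SPANS_TYPE_I if b > hi
    )
    records: list[FastaRecord] = []
    for i in range(n_records):
        codon = codons[rng.integers(len(codons))]
        anticodon = revcomp(codon)
        aa = code_state[codon]
        prefix = mutate_sequence(core[:lo], config, indel_spans=prefix_spans, rng=rng)
        suffix = mutate_sequence(core[hi:], config, indel_spans=suffix_spans, rng=rng)
        records.append(
            FastaRecord(
                id=f"tRNA-{aa}-{anticodon}-{i:03d}",
                sequence=prefix + anticodon + suffix,
            )
        )
    return records


@dataclass(frozen=True)
class PlantedMatrixConfig:
    n_nodes: int
    base_score: float = 1000.0
    decay: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0
    tree: tuple[tuple[str, str], ...] | None = None  # optional user tree (name pairs)
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.base_score <= 0:
            raise ValueError("base_score must be positive")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.names and len(self.names) != self.n_nodes:
            raise ValueError("names must match n_nodes")

    @property
    def min_edge_gap(self) -> float:
        """Noiseless weight gap between tree edges and distance-2 pairs."""
        return self.base_score * self.decay * (1.0 - self.decay)


def planted_tree_matrix(
    config: PlantedMatrixConfig,
) -> tuple[ScoreMatrix, tuple[tuple[str, str], ...]]:
    """Directed integer score matrix with a planted tree and Gaussian noise.

    score(i, j) = base_score * decay ** tree_distance(i, j) + noise, rounded
    to an integer and clamped to >= 1, with independent noise per direction.
    Returns the matrix and the true tree (sorted name pairs) for recovery
    scoring.
    """
    rng = np.random.default_rng(config.seed)
    names = (
        tuple(config.names)
        if config.names
        else tuple(f"N{i:02d}" for i in range(config.n_nodes))
    )
    graph = nx.Graph()
    graph.add_nodes_from(names)
    if config.tree is not None:
        edges = [tuple(sorted(e)) for e in config.tree]
        graph.add_edges_from(edges)
        if not nx.is_tree(graph):
            raise ValueError("supplied edges do not form a spanning tree")
    else:
        skeleton = nx.random_labeled_tree(config.n_nodes, seed=int(rng.integers(2**31)))
        edges = [tuple(sorted((names[u], names[v]))) for u, v in skeleton.edges]
        graph.add_edges_from(edges)
    dist = dict(nx.all_pairs_shortest_path_length(graph))
    directed: dict[tuple[str, str], int] = {}
    for q in names:
        for t in names:
            if q == t:
                continue
            value = config.base_score * config.decay ** dist[q][t]
            if config.noise_sd:
                value += rng.normal(0.0, config.noise_sd)
            directed[(q, t)] = max(1, round(value))
    matrix = ScoreMatrix(enzymes=names, directed=directed)
    return matrix, tuple(sorted(edges))
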