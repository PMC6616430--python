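"""Homology networks over directed aaRS score matrices.

Consumes the packaged class I / class II score tables (or user CSVs),
symmetrizes directed scores into a weighted graph, extracts the
maximum-score spanning tree with a designated root, builds the best-hit
digraph, and tests whether same-genetic-code-column enzymes score higher
than expected by a label permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np

from .io import read_matrix_csv

SymmetrizeMethod = Literal["max", "mean"]

#: genetic-code column membership of the class I enzymes (anticodon p2 base)
CLASS1_COLUMN_MAP = {
    "ValRS-IA": 1, "IleRS-IA": 1, "LeuRS-IA": 1, "MetRS-IA": 1,
    "GluRS-IB": 3, "GlnRS-IB": 3, "LysRS-IE": 3,
    "CysRS-IB": 4, "ArgRS-ID": 4,
}

#: genetic-code column membership of the class II enzymes
CLASS2_COLUMN_MAP = {
    "ProRS-IIA": 2, "ThrRS-IIA": 2, "SerRS-IIA": 2,
    "AspRS-IIB": 3, "AsnRS-IIB": 3, "HisRS-IIA": 3,
    "GlyRS-IIA": 4,
}


@dataclass(frozen=True)
class ScoreMatrix:
    """Directed homology scores between named enzymes.

    ``directed`` holds only detected scores; not-detected (ND) pairs and the
    NR diagonal are simply absent.  ``evalues`` optionally carries e-values
    quoted in running text for specific directed pairs.
    """

    enzymes: tuple[str, ...]
    directed: dict[tuple[str, str], int]
    evalues: dict[tuple[str, str], float] = field(default_factory=dict)

    def score(self, query: str, target: str) -> int | None:
        return self.directed.get((query, target))

    def drop(self, names: set[str] | list[str]) -> "ScoreMatrix":
        names = set(names)
        unknown = names - set(self.enzymes)
        if unknown:
            raise ValueError(f"cannot exclude unknown enzymes: {sorted(unknown)}")
        return ScoreMatrix(
            enzymes=tuple(e for e in self.enzymes if e not in names),
            directed={
                (q, t): s
                for (q, t), s in self.directed.items()
                if q not in names and t not in names
            },
            evalues={
                (q, t): v
                for (q, t), v in self.evalues.items()
                if q not in names and t not in names
            },
        )


def load_matrix(path: str | Path) -> ScoreMatrix:
    """Load a directed score matrix CSV (row = query, column = target)."""
    names, scores = read_matrix_csv(path)
    return ScoreMatrix(enzymes=tuple(names), directed=scores)


def packaged_matrix(which: Literal["class1", "class2"]) -> ScoreMatrix:
    """The packaged fixtures transcribed from the printed score tables."""
    name = {"class1": "class1_scores.csv", "class2": "class2_scores.csv"}[which]
    ref = resources.files("trnacode.data").joinpath(name)
    with resources.as_file(ref) as path:
        return load_matrix(path)


@dataclass(frozen=True)
class Network:
    """Symmetrized undirected homology graph."""

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]  # keys sorted pairs
    method: SymmetrizeMethod

    def weight(self, u: str, v: str) -> float | None:
        return self.edges.get(tuple(sorted((u, v))))


def symmetrize(matrix: ScoreMatrix, method: SymmetrizeMethod = "max") -> Network:
    """Collapse directed scores to undirected weights.

    An edge exists iff at least one direction was detected; the weight is
    the max (default; the better direction is the reported connection
    strength) or the mean of the available directions.
    """
    if method not in ("max", "mean"):
        raise ValueError(f"unknown symmetrization method {method!r}")
    edges: dict[tuple[str, str], float] = {}
    for i, u in enumerate(matrix.enzymes):
        for v in matrix.enzymes[i + 1 :]:
            values = [s for s in (matrix.score(u, v), matrix.score(v, u)) if s is not None]
            if not values:
                continue
            key = tuple(sorted((u, v)))
            edges[key] = float(max(values)) if method == "max" else float(np.mean(values))
    return Network(nodes=tuple(matrix.enzymes), edges=edges, method=method)


@dataclass(frozen=True)
class SpanningTree:
    """Maximum-weight spanning forest with parent directions from a root."""

    edges: tuple[tuple[str, str, float], ...]
    root: str
    parent: dict[str, str | None]

    @property
    def total_weight(self) -> float:
        return sum(w for _, _, w in self.edges)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def max_spanning_tree(network: Network, root: str | None = None) -> SpanningTree:
    """Kruskal maximum-weight spanning forest, deterministic under ties.

    Ties are broken lexicographically on the edge's sorted endpoint names.
    Parent directions radiate from ``root`` in its component; other
    components are rooted at their lexicographically smallest node.
    """
    if not network.nodes:
        raise ValueError("empty network")
    if root is not None and root not in network.nodes:
        raise ValueError(f"root {root!r} is not a network node")
    ordered = sorted(network.edges.items(), key=lambda kv: (-kv[1], kv[0]))
    uf = _UnionFind(network.nodes)
    chosen: list[tuple[str, str, float]] = []
    adjacency: dict[str, list[str]] = {n: [] for n in network.nodes}
    for (u, v), w in ordered:
        if uf.union(u, v):
            chosen.append((u, v, w))
            adjacency[u].append(v)
            adjacency[v].append(u)

    parent: dict[str, str | None] = {}
    roots = []
    if root is not None:
        roots.append(root)
    # remaining components rooted at their smallest node
    components: dict[str, list[str]] = {}
    for n in network.nodes:
        components.setdefault(uf.find(n), []).append(n)
    for members in components.values():
        if root is not None and root in members:
            continue
        roots.append(min(members))
    for r in roots:
        parent[r] = None
        stack = [r]
        while stack:
            node = stack.pop()
            for nbr in sorted(adjacency[node]):
                if nbr not in parent:
                    parent[nbr] = node
                    stack.append(nbr)
    return SpanningTree(
        edges=tuple(chosen),
        root=root if root is not None else min(network.nodes),
        parent=parent,
    )


def best_hit_digraph(matrix: ScoreMatrix) -> dict[str, tuple[str, int]]:
    """Each query's argmax target: {query: (target, score)}.

    Queries with no detected score have no out-edge; ties break
    lexicographically on the target name.
    """
    out: dict[str, tuple[str, int]] = {}
    for q in matrix.enzymes:
        hits = [
            (t, s)
            for t in matrix.enzymes
            if t != q and (s := matrix.score(q, t)) is not None
        ]
        if hits:
            out[q] = min(hits, key=lambda ts: (-ts[1], ts[0]))
    return out


@dataclass(frozen=True)
class CoherenceResult:
    statistic: float
    n_perm: int
    p_value: float
    seed: int
    null_mean: float
    null_sd: float


def column_coherence(
    network: Network,
    column_map: dict[str, int],
    n_perm: int = 9999,
    seed: int = 0,
) -> CoherenceResult:
    """Mean same-column edge weight versus a column-label permutation null.

    The null permutes column labels uniformly among the mapped nodes; the
    p-value uses the add-one rule.
    """
    members: dict[int, list[str]] = {}
    for node, col in column_map.items():
        if node not in network.nodes:
            raise ValueError(f"column_map node {node!r} is not in the network")
        members.setdefault(col, []).append(node)
    if len(members) < 2 or any(len(m) < 2 for m in members.values()):
        raise ValueError("column_map must cover >=2 columns with >=2 members each")
    nodes = sorted(column_map)
    labels = np.array([column_map[n] for n in nodes])

    def mean_same_column(lbls: np.ndarray) -> float:
        weights = []
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if lbls[i] != lbls[j]:
                    continue
                w = network.weight(nodes[i], nodes[j])
                if w is not None:
                    weights.append(w)
        return float(np.mean(weights)) if weights else float("nan")

    statistic = mean_same_column(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = mean_same_column(labels[rng.permutation(len(labels))])
    exceed = int(np.sum(null >= statistic))
    return CoherenceResult(
        statistic=statistic,
        n_perm=n_perm,
        p_value=(1 + exceed) / (n_perm + 1),
        seed=seed,
        null_mean=float(np.nanmean(null)),
        null_sd=float(np.nanstd(null, ddof=1)),
    )


def tree_report(tree: SpanningTree, matrix: ScoreMatrix) -> list[dict]:
    """Tree edges sorted ascending by weight (weakest connections first)."""
    report = []
    for u, v, w in sorted(tree.edges, key=lambda e: (e[2], e[0], e[1])):
        report.append(
            {
                "node_a": u,
                "node_b": v,
                "weight": w,
                "score_ab": matrix.score(u, v),
                "score_ba": matrix.score(v, u),
                "evalue_ab": matrix.evalues.get((u, v)),
                "evalue_ba": matrix.evalues.get((v, u)),
            }
        )
    return report
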