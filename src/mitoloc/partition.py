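"""Homology-aware cross-validation partitioning.

Detectable sequence similarity between training and test proteins
inflates cross-validation estimates. The guard implemented here: build a
similarity graph from an all-against-all pairwise alignment hit list
(nodes = proteins; an edge whenever some hit exceeds 30% identity at
e-value <= 0.001), take connected components (single-linkage clusters),
and assign whole clusters to folds. By construction no similarity edge
can cross a fold boundary, so any residual redundancy — even local — is
confined to a single cross-validation set.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise alignment hit (blastp tabular style)."""

    query_id: str
    subject_id: str
    identity_percent: float
    evalue: float


#: Column names of 12-column tabular alignment output (outfmt-6 dialect).
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | os.PathLike) -> list[SimilarityHit]:
    """Read a 12-column tabular hit list (qseqid sseqid pident ... evalue bitscore)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=OUTFMT6_COLUMNS)
    return [
        SimilarityHit(str(r.qseqid), str(r.sseqid), float(r.pident), float(r.evalue))
        for r in df.itertuples(index=False)
    ]


def write_hits(hits: list[SimilarityHit], path: str | os.PathLike) -> None:
    """Write hits in the 12-column tabular dialect (placeholder alignment columns)."""
    with open(path, "w") as fh:
        for h in hits:
            fields = [
                h.query_id, h.subject_id, f"{h.identity_percent:.2f}",
                "0", "0", "0", "0", "0", "0", "0", f"{h.evalue:.2g}", "0",
            ]
            fh.write("\t".join(fields) + "\n")


@dataclass
class SimilarityGraph:
    """Undirected similarity graph over protein ids."""

    nodes: set[str]
    edges: set[frozenset[str]] = field(default_factory=set)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g


def build_graph(
    ids: set[str],
    hits: list[SimilarityHit],
    identity_threshold: float = 30.0,
    evalue_threshold: float = 0.001,
) -> SimilarityGraph:
    """Build the similarity graph from a hit list.

    An edge (a, b) is added iff some hit in either direction has identity
    strictly above ``identity_threshold`` and e-value at most
    ``evalue_threshold``. Self-hits are ignored; ids without any
    qualifying hit remain isolated nodes.
    """
    ids = set(ids)
    unknown = sorted(({h.query_id for h in hits} | {h.subject_id for h in hits}) - ids)
    if unknown:
        raise ValueError(f"hit list references unknown ids: {unknown}")
    edges: set[frozenset[str]] = set()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.identity_percent > identity_threshold and h.evalue <= evalue_threshold:
            edges.add(frozenset((h.query_id, h.subject_id)))
    return SimilarityGraph(nodes=ids, edges=edges)


def connected_components(graph: SimilarityGraph) -> list[list[str]]:
    """Single-linkage clusters = connected components of the graph.

    Deterministic output: clusters sorted by decreasing size, ties by
    smallest member id; members sorted within each cluster.
    """
    comps = [sorted(c) for c in nx.connected_components(graph.to_networkx())]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


@dataclass
class FoldAssignment:
    """Mapping of every protein id to a fold index in [0, k)."""

    mapping: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        bad = {i for i in self.mapping.values() if not 0 <= i < self.k}
        if bad:
            raise ValueError(f"fold indices out of range: {sorted(bad)}")

    def fold_members(self, fold: int) -> list[str]:
        return sorted(pid for pid, f in self.mapping.items() if f == fold)

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.mapping.values():
            sizes[f] += 1
        return sizes

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("#id\tfold\n")
            for pid in sorted(self.mapping):
                fh.write(f"{pid}\t{self.mapping[pid]}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "FoldAssignment":
        mapping: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                pid, fold = line.rstrip("\n").split("\t")
                mapping[pid] = int(fold)
        return cls(mapping=mapping, k=max(mapping.values()) + 1 if mapping else 0)


def assign_folds(clusters: list[list[str]], k: int, seed: int = 0) -> FoldAssignment:
    """Assign whole clusters to k folds, balancing fold sizes.

    Greedy: clusters in decreasing size order each go to the currently
    smallest fold (ties among equally small folds broken by a seeded
    draw). Cluster atomicity guarantees zero cross-fold similarity edges.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(clusters) < k:
        raise ValueError(
            f"cannot make {k} folds from {len(clusters)} clusters"
        )
    rng = np.random.default_rng(seed)
    ordered = sorted(clusters, key=lambda c: (-len(c), min(c)))
    sizes = [0] * k
    mapping: dict[str, int] = {}
    for cluster in ordered:
        smallest = min(sizes)
        candidates = [i for i, s in enumerate(sizes) if s == smallest]
        fold = int(candidates[rng.integers(len(candidates))])
        for pid in cluster:
            if pid in mapping:
                raise ValueError(f"id {pid} appears in more than one cluster")
            mapping[pid] = fold
        sizes[fold] += len(cluster)
    return FoldAssignment(mapping=mapping, k=k)


def random_split(ids: set[str], k: int, seed: int = 0) -> FoldAssignment:
    """Uniform random balanced k-fold split ignoring similarity.

    Fold sizes differ by at most one; reproducible given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = sorted(ids)
    rng.shuffle(order)
    mapping = {pid: i % k for i, pid in enumerate(order)}
    return FoldAssignment(mapping=mapping, k=k)


def cross_fold_edges(graph: SimilarityGraph, assignment: FoldAssignment) -> int:
    """Count similarity edges whose endpoints lie in different folds."""
    return sum(
        1
        for e in graph.edges
        for a, b in [tuple(e)]
        if assignment.mapping[a] != assignment.mapping[b]
    )
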