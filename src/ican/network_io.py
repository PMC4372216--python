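"""Interaction-source parsing and the Human Background Network (HBN).

The HBN is the undirected union of pathway interaction files (Cytoscape SIF
dialect) and plain two-column PPI edge lists. Relation types are recorded but
carry no topological meaning; self-loops and duplicate (A-B vs B-A) edges are
removed on union.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "EdgeList",
    "BackgroundNetwork",
    "SifParseError",
    "read_sif",
    "read_tsv_edges",
    "build_hbn",
    "write_edge_tsv",
    "read_edge_tsv",
]


class SifParseError(ValueError):
    """Raised for a malformed interaction-file line; names the line number."""


@dataclass
class EdgeList:
    """Ordered list of (source, target, relation-tag) records from one source."""

    edges: list[tuple[str, str, str]] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class BackgroundNetwork:
    """Undirected simple graph of gene symbols (no self-loops, no duplicates)."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def read_sif(path: str | os.PathLike) -> EdgeList:
    """Parse a SIF file into an :class:`EdgeList`.

    Each non-empty line reads ``source relation target [target2 ...]``; a
    multi-target line expands to one edge per target (Cytoscape convention).
    Lines with a single field raise :class:`SifParseError`.
    """
    edges: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise SifParseError(
                    f"{path}: line {lineno}: expected >=3 fields "
                    f"(source relation target...), got {len(fields)}"
                )
            source, relation, *targets = fields
            for target in targets:
                edges.append((source.strip(), target.strip(), relation))
    return EdgeList(edges=edges, name=str(path))


def read_tsv_edges(path: str | os.PathLike, tag: str = "ppi") -> EdgeList:
    """Parse an HPRD-style two-column tab/whitespace edge list.

    A header line whose first field is ``gene_a`` (case-insensitive) is
    skipped. Extra columns beyond the first two are ignored.
    """
    edges: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if lineno == 1 and fields[0].lower() in {"gene_a", "source", "#gene_a"}:
                continue
            if len(fields) < 2:
                raise SifParseError(
                    f"{path}: line {lineno}: expected >=2 fields, got {len(fields)}"
                )
            edges.append((fields[0].strip(), fields[1].strip(), tag))
    return EdgeList(edges=edges, name=str(path))


def build_hbn(sources: list[EdgeList]) -> BackgroundNetwork:
    """Union interaction sources into the Human Background Network.

    Deduplicates unordered pairs, drops self-loops, and keeps every endpoint
    that survives cleanup as a node. Raises ``ValueError`` on an empty union.
    """
    if not sources:
        raise ValueError("build_hbn requires at least one edge-list source")
    g: nx.Graph = nx.Graph()
    for source in sources:
        for a, b, _tag in source.edges:
            if not a or not b or a == b:
                continue
            g.add_edge(a, b)
    if g.number_of_edges() == 0:
        raise ValueError("union of interaction sources contains no valid edges")
    return BackgroundNetwork(graph=g)


def write_edge_tsv(network: BackgroundNetwork, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\n")


def read_edge_tsv(path: str | os.PathLike) -> BackgroundNetwork:
    return build_hbn([read_tsv_edges(path, tag="tsv")])
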