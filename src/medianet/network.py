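"""Undirected protein-interaction graph model, file I/O and centrality indices.

The graph is simple (no self-loops, no parallel edges) and unweighted; node
identifiers are opaque, case-sensitive strings (UniProt accessions in
practice, but nothing is validated against UniProt). Degree and betweenness
are reported both raw and with the Freeman normalizations

    nD_i = D_i / (N - 1)
    nB_i = B_i / ((N - 1)(N - 2) / 2)

so that values from networks of different size are comparable and lie in
[0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "ParseError",
    "read_edge_list",
    "write_edge_list",
    "write_graphml",
    "degree",
    "normalized_degree",
    "betweenness",
    "normalized_betweenness",
    "centrality_table",
]


class ParseError(ValueError):
    """Raised when an input table cannot be parsed; message names the line."""


@dataclass
class InteractionNetwork:
    """A simple undirected network of protein nodes.

    Thin wrapper around :class:`networkx.Graph` that enforces the model's
    invariants at construction: self-loops are dropped (with a logged count)
    and duplicate or reversed edge records collapse to a single undirected
    edge. Isolated nodes are permitted.
    """

    name: str = "network"
    _graph: nx.Graph = field(default_factory=nx.Graph, repr=False)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        name: str = "network",
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        dropped = 0
        for u, v in edges:
            if u == v:
                dropped += 1
                continue
            g.add_edge(u, v)
        if dropped:
            logger.warning("%s: dropped %d self-loop record(s)", name, dropped)
        return cls(name=name, _graph=g)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> list[str]:
        return list(self._graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._graph.edges)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def has_node(self, i: str) -> bool:
        return self._graph.has_node(i)

    def has_edge(self, i: str, j: str) -> bool:
        return self._graph.has_edge(i, j)

    def neighbors(self, i: str) -> list[str]:
        self._require(i)
        return list(self._graph.neighbors(i))

    def degree(self, i: str) -> int:
        self._require(i)
        return int(self._graph.degree[i])

    def subgraph_equal(self, other: "InteractionNetwork") -> bool:
        return set(self.nodes) == set(other.nodes) and {
            frozenset(e) for e in self.edges
        } == {frozenset(e) for e in other.edges}

    def _require(self, *nodes: str) -> None:
        for i in nodes:
            if not self._graph.has_node(i):
                raise KeyError(f"node {i!r} not in network {self.name!r}")

    def __contains__(self, i: str) -> bool:
        return self._graph.has_node(i)

    def __iter__(self) -> Iterator[str]:
        return iter(self._graph.nodes)


def _open_lines(source: str | Path | IO[str]) -> tuple[list[str], str]:
    if hasattr(source, "read"):
        return source.read().splitlines(), getattr(source, "name", "<stream>")
    path = Path(source)
    return path.read_text().splitlines(), str(path)


def read_edge_list(
    source: str | Path | IO[str],
    delimiter: str = "\t",
    header: bool = False,
    name: str | None = None,
) -> InteractionNetwork:
    """Read a two-column edge list into an :class:`InteractionNetwork`.

    Lines starting with ``#`` and blank lines are ignored. Each remaining
    line must have at least two delimited fields; extra fields (weights,
    provenance) are ignored. Self-loops are dropped and duplicate/reversed
    records collapsed. Raises :class:`ParseError` naming the offending line
    for malformed rows, and for entirely empty input.
    """
    lines, label = _open_lines(source)
    edges: list[tuple[str, str]] = []
    data_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if header and not data_seen:
            data_seen = True
            continue
        data_seen = True
        fields = line.split(delimiter)
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(
                f"{label}: line {lineno}: expected 2 delimited node ids, got {raw!r}"
            )
        edges.append((fields[0], fields[1]))
    if not edges:
        raise ParseError(f"{label}: no edge records found")
    return InteractionNetwork.from_edges(edges, name=name or label)


def write_edge_list(
    net: InteractionNetwork, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write the network's edges, one per line, endpoints sorted per edge."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{u}{delimiter}{v}\n")


def write_graphml(
    net: InteractionNetwork,
    path: str | Path,
    roles: Mapping[str, str] | None = None,
) -> None:
    """Export to GraphML; nodes carry a ``role`` attribute when supplied."""
    g = net.graph.copy()
    if roles is not None:
        nx.set_node_attributes(g, dict(roles), "role")
    nx.write_graphml(g, path)


def degree(net: InteractionNetwork, i: str) -> int:
    """Number of distinct neighbors of node *i* (its degree D_i)."""
    return net.degree(i)


def normalized_degree(net: InteractionNetwork, i: str) -> float:
    """Degree normalized by the maximum possible, nD_i = D_i / (N - 1)."""
    if net.n_nodes < 2:
        raise ValueError("normalized degree undefined for N < 2")
    return net.degree(i) / (net.n_nodes - 1)


def betweenness(net: InteractionNetwork, i: str) -> float:
    """Shortest-path betweenness B_i.

    Sum over unordered pairs {j, k} (both distinct from i) of the fraction
    of geodesics between j and k that pass through i; pairs in different
    components contribute zero.
    """
    net._require(i)
    return float(nx.betweenness_centrality(net.graph, normalized=False)[i])


def normalized_betweenness(net: InteractionNetwork, i: str) -> float:
    """Betweenness divided by its maximum (N-1)(N-2)/2; in [0, 1]."""
    if net.n_nodes < 3:
        raise ValueError("normalized betweenness undefined for N < 3")
    net._require(i)
    return float(nx.betweenness_centrality(net.graph, normalized=True)[i])


def centrality_table(net: InteractionNetwork) -> pd.DataFrame:
    """Per-node degree and betweenness values with competition ranks.

    Columns: node, D, nD, nD_rank, B, nB, nB_rank. Rank 1 is the largest
    value; ties share the smallest applicable rank.
    """
    if net.n_nodes < 3:
        raise ValueError("centrality table requires N >= 3")
    b_raw = nx.betweenness_centrality(net.graph, normalized=False)
    b_norm = nx.betweenness_centrality(net.graph, normalized=True)
    n = net.n_nodes
    rows = []
    for node in net.nodes:
        d = net.degree(node)
        rows.append(
            {
                "node": node,
                "D": d,
                "nD": d / (n - 1),
                "B": float(b_raw[node]),
                "nB": float(b_norm[node]),
            }
        )
    table = pd.DataFrame(rows).set_index("node")
    table["nD_rank"] = table["nD"].rank(method="min", ascending=False).astype(int)
    table["nB_rank"] = table["nB"].rank(method="min", ascending=False).astype(int)
    return table[["D", "nD", "nD_rank", "B", "nB", "nB_rank"]]
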