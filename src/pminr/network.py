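"""Network topologies: named nodes, undirected edges, and the edge indicator.

A topology fixes the node order used by every downstream matrix (sample
matrices, design matrices, edge-feature matrices).  Edges are stored as
unordered index pairs ``(i, j)`` with ``i < j``; the connectivity indicator
``I[i, j]`` is 1 exactly when ``{i, j}`` is an edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkTopology",
    "load_edge_list",
    "write_edge_list",
    "insulin_resistance_fixture",
]


class TopologyError(ValueError):
    """Raised when an edge list violates the undirected-simple-graph contract."""


@dataclass(frozen=True)
class NetworkTopology:
    """An undirected simple graph over named nodes.

    Parameters
    ----------
    node_names
        Ordered, unique node identifiers.  This order is authoritative for
        every matrix indexed by nodes.
    edges
        Unordered pairs of node indices, normalized to ``i < j``.
    """

    node_names: tuple[str, ...]
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.node_names)) != len(self.node_names):
            raise TopologyError("duplicate node names")
        p = len(self.node_names)
        norm = set()
        for i, j in self.edges:
            if i == j:
                raise TopologyError(f"self-loop on node index {i}")
            if not (0 <= i < p and 0 <= j < p):
                raise TopologyError(f"edge ({i}, {j}) indexes outside {p} nodes")
            norm.add((min(i, j), max(i, j)))
        object.__setattr__(self, "edges", frozenset(norm))

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_list(self) -> list[tuple[int, int]]:
        """Edges sorted by ``(i, j)``; fixes the edge-feature column order."""
        return sorted(self.edges)

    def edge_names(self, sep: str = "~") -> list[str]:
        return [f"{self.node_names[i]}{sep}{self.node_names[j]}" for i, j in self.edge_list()]

    def indicator_matrix(self) -> np.ndarray:
        """Symmetric 0/1 connectivity matrix with zero diagonal."""
        p = self.n_nodes
        ind = np.zeros((p, p), dtype=int)
        for i, j in self.edges:
            ind[i, j] = ind[j, i] = 1
        return ind

    def degrees(self) -> np.ndarray:
        return self.indicator_matrix().sum(axis=1)

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    def node_index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}") from None

    def is_connected(self) -> bool:
        import networkx as nx

        return nx.is_connected(self.to_networkx())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_names)
        g.add_edges_from(
            (self.node_names[i], self.node_names[j]) for i, j in self.edge_list()
        )
        return g

    @classmethod
    def from_named_edges(
        cls, edges: Iterable[tuple[str, str]], node_names: Sequence[str] | None = None
    ) -> "NetworkTopology":
        """Build a topology from name pairs; node order is first appearance
        unless ``node_names`` is given explicitly."""
        edges = list(edges)
        if node_names is None:
            seen: dict[str, int] = {}
            for a, b in edges:
                for name in (a, b):
                    seen.setdefault(name, len(seen))
            names = tuple(seen)
        else:
            names = tuple(node_names)
        index = {name: k for k, name in enumerate(names)}
        idx_edges = set()
        for a, b in edges:
            if a == b:
                raise TopologyError(f"self-loop {a!r}-{b!r}")
            try:
                i, j = index[a], index[b]
            except KeyError as missing:
                raise TopologyError(f"edge endpoint {missing} not in node list") from None
            idx_edges.add((min(i, j), max(i, j)))
        if len(idx_edges) < len(edges):
            logger.warning(
                "collapsed %d duplicate edge(s)", len(edges) - len(idx_edges)
            )
        return cls(names, frozenset(idx_edges))


def load_edge_list(path: str | Path) -> NetworkTopology:
    """Read a whitespace-delimited two-column edge list.

    Lines starting with ``#`` are comments.  Node order is first-appearance
    order; duplicate edges in either orientation are collapsed with a warning;
    self-loops and malformed lines raise :class:`TopologyError` naming the
    offending line.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    node_order: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#nodes:"):
                # optional directive making the node order explicit, so a
                # written file round-trips even when edge order would imply
                # a different first-appearance order
                node_order = line.removeprefix("#nodes:").split()
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise TopologyError(
                    f"{path}:{lineno}: expected two node names, got {line!r}"
                )
            a, b = parts
            if a == b:
                raise TopologyError(f"{path}:{lineno}: self-loop {a!r}")
            pairs.append((a, b))
    if not pairs:
        raise TopologyError(f"{path}: no edges found")
    return NetworkTopology.from_named_edges(pairs, node_names=node_order)


def write_edge_list(topology: NetworkTopology, path: str | Path) -> None:
    """Write a topology in the same two-column format read by
    :func:`load_edge_list` (node order is preserved through a round trip)."""
    with open(path, "w") as fh:
        fh.write("#nodes: " + " ".join(topology.node_names) + "\n")
        for i, j in topology.edge_list():
            fh.write(f"{topology.node_names[i]}\t{topology.node_names[j]}\n")


def insulin_resistance_fixture() -> NetworkTopology:
    """The packaged 26-node / 37-edge simulation topology.

    A connected stand-in for the KEGG insulin-resistance pathway used by the
    simulation harness; it reproduces the pathway's node and edge counts with
    generic ``X1..X26`` labels (see the data file header).
    """
    ref = resources.files("pminr.data").joinpath("insulin_resistance_edges.tsv")
    with resources.as_file(ref) as path:
        topo = load_edge_list(path)
    assert topo.n_nodes == 26 and topo.n_edges == 37
    return topo
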