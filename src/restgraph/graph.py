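"""Undirected, unweighted graph container used across the package.

A :class:`BinaryGraph` is a thin wrapper over a symmetric boolean
adjacency matrix with an empty diagonal, optionally carrying node
labels (region abbreviations).  Conversion helpers to and from
:mod:`networkx` are provided for interoperability and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["BinaryGraph"]


@dataclass(frozen=True)
class BinaryGraph:
    adjacency: np.ndarray
    labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if adj.diagonal().any():
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if self.labels is not None and len(self.labels) != adj.shape[0]:
            raise ValueError("labels length must match node count")
        object.__setattr__(self, "adjacency", adj)
        self.adjacency.setflags(write=False)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edge_array(self) -> np.ndarray:
        """Edges as an (m, 2) integer array with i < j."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([i, j])

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.adjacency[i, j])

    @classmethod
    def from_edges(
        cls, n_nodes: int, edges, labels: tuple[str, ...] | None = None
    ) -> "BinaryGraph":
        adj = np.zeros((n_nodes, n_nodes), dtype=bool)
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            adj[i, j] = adj[j, i] = True
        return cls(adj, labels)

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "BinaryGraph":
        nodes = sorted(graph.nodes())
        adj = nx.to_numpy_array(graph, nodelist=nodes, dtype=bool)
        return cls(adj, tuple(str(n) for n in nodes))

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        if self.labels is not None:
            nx.set_node_attributes(
                g, {i: lab for i, lab in enumerate(self.labels)}, "label"
            )
        return g
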