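"""Graph containers shared across the pipeline.

Two containers cover every network in the method: :class:`WeightedNetwork`
(undirected, weights in [0, 1]; consensus co-expression and drug MOA
networks) and :class:`BinaryNetwork` (undirected, unweighted; prior-knowledge
layers and their merges). Both are deliberately thin: dense numpy adjacency
for the weighted case, a set of canonical node pairs for the binary case,
with converters to :mod:`networkx` and 3-column TSV edge lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["WeightedNetwork", "BinaryNetwork", "canonical_edge"]


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Order an unordered gene pair deterministically (lexicographic)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class WeightedNetwork:
    """Undirected weighted gene network with a dense adjacency matrix.

    Invariants: the adjacency is square and symmetric with a zero diagonal,
    weights lie in [0, 1], and node ids are unique.
    """

    nodes: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.nodes)
        if len(set(self.nodes)) != n:
            raise ValueError("duplicate node ids in WeightedNetwork")
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match {n} nodes"
            )
        if not np.allclose(self.adjacency, self.adjacency.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-loops are not allowed")
        if np.any(self.adjacency < -1e-12) or np.any(self.adjacency > 1 + 1e-12):
            raise ValueError("edge weights must lie in [0, 1]")
        np.clip(self.adjacency, 0.0, 1.0, out=self.adjacency)
        self._index = {g: i for i, g in enumerate(self.nodes)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def weight(self, a: str, b: str) -> float:
        return float(self.adjacency[self._index[a], self._index[b]])

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield (gene_a, gene_b, weight) for every positive-weight edge."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(iu, ju):
            w = self.adjacency[i, j]
            if w > 0:
                yield self.nodes[i], self.nodes[j], float(w)

    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def edge_set(self) -> set[tuple[str, str]]:
        return {canonical_edge(a, b) for a, b, _ in self.edges()}

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str, float]],
    ) -> "WeightedNetwork":
        nodes = list(nodes)
        index = {g: i for i, g in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)))
        for a, b, w in edges:
            if a == b:
                continue
            i, j = index[a], index[b]
            adj[i, j] = adj[j, i] = w
        return cls(nodes, adj)

    def to_networkx(self, distance_epsilon: float = 1e-6) -> nx.Graph:
        """Convert to networkx, attaching ``weight`` and ``distance`` (1 - w + eps)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, w in self.edges():
            g.add_edge(a, b, weight=w, distance=1.0 - w + distance_epsilon)
        return g

    # -- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, w) for a, b, w in self.edges()]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path, nodes: Sequence[str] | None = None) -> "WeightedNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        if nodes is None:
            nodes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
        return cls.from_edges(
            nodes, zip(df["gene_a"], df["gene_b"], df["weight"].astype(float))
        )


@dataclass
class BinaryNetwork:
    """Undirected unweighted network stored as a set of canonical node pairs."""

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-loops are not allowed")
            canon.add(canonical_edge(a, b))
        self.edges = canon
        self.nodes |= {g for e in self.edges for g in e}

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "BinaryNetwork":
        pairs = [canonical_edge(a, b) for a, b in pairs if a != b]
        return cls(nodes=set(nodes), edges=set(pairs))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self.edges

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        return pd.DataFrame(rows, columns=["gene_a", "gene_b"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BinaryNetwork":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))
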