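"""Graph data model, file I/O, induced subgraphs, resampling and clustering coefficients.

The central object is a :class:`FunctionalNetwork`: an undirected graph whose
nodes are gene identifiers and whose edges carry a probability weight in
``[0, 1]`` encoding confidence of pathway co-membership.  Candidate gene lists
(for example, putative transcription-factor targets called from ChIP peaks)
induce a subgraph whose topology is what the coherence statistics analyse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FunctionalNetwork",
    "NodeList",
    "InducedSubgraph",
    "read_network",
    "write_network",
    "read_node_list",
    "write_node_list",
    "induce_subgraph",
    "resample_subgraph",
    "global_clustering_coefficient",
]


class NetworkFormatError(ValueError):
    """Raised for malformed network or node-list files."""


class FunctionalNetwork:
    """Weighted undirected gene network.

    Invariants enforced on construction: no self-loops, weights in [0, 1],
    each unordered pair stored once (order-insensitive lookup).
    Gene identifiers are case-sensitive opaque strings.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], nodes: Iterable[str] = ()
    ) -> "FunctionalNetwork":
        net = cls()
        for extra in nodes:
            net._g.add_node(str(extra))
        for a, b, w in edges:
            net.add_edge(str(a), str(b), float(w))
        return net

    def add_edge(self, a: str, b: str, weight: float) -> None:
        if a == b:
            raise NetworkFormatError(f"self-loop on node {a!r} not allowed")
        if not (0.0 <= weight <= 1.0) or not np.isfinite(weight):
            raise NetworkFormatError(
                f"edge ({a!r}, {b!r}) weight {weight} outside [0, 1]"
            )
        if self._g.has_edge(a, b):
            old = self._g[a][b]["weight"]
            if old != weight:
                logger.info(
                    "duplicate edge (%s, %s): weights %g and %g differ, keeping max",
                    a, b, old, weight,
                )
            weight = max(old, weight)
        self._g.add_edge(a, b, weight=weight)

    # -- queries -----------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def node_list(self) -> list[str]:
        """Nodes in sorted order (the canonical iteration order)."""
        return sorted(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for a, b, data in self._g.edges(data=True):
            yield a, b, data["weight"]

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def weight(self, a: str, b: str) -> float:
        return self._g[a][b]["weight"]

    def neighbors(self, a: str) -> set[str]:
        return set(self._g[a])

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def __repr__(self) -> str:  # pragma: no cover
        return f"FunctionalNetwork({self.n_nodes} nodes, {self.n_edges} edges)"


@dataclass
class NodeList:
    """Ordered list of candidate genes, optionally labelled.

    Labels mark provenance in benchmark data: a pathway identifier for
    planted (functional) genes, or ``"SNTG"`` for synthetic neutral target
    genes.  Duplicate identifiers are removed on construction, keeping first
    occurrence.
    """

    genes: list[str]
    labels: Optional[dict[str, str]] = None
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        unique = []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                unique.append(g)
        if len(unique) != len(self.genes):
            logger.info(
                "node list %s: removed %d duplicate identifiers",
                self.name or "<anon>", len(self.genes) - len(unique),
            )
        self.genes = unique

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)


@dataclass
class InducedSubgraph:
    """Subgraph of a parent network induced by a node subset.

    ``graph`` holds exactly the parent edges with both endpoints in
    ``nodes``; isolated nodes are kept (they matter for clustering-coefficient
    and NFCS conventions).  ``n_dropped`` counts list identifiers absent from
    the parent network.
    """

    parent: FunctionalNetwork
    graph: nx.Graph
    n_dropped: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_list(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return [(a, b) if a <= b else (b, a) for a, b in self.graph.edges()]

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph[gene])

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)


# ---------------------------------------------------------------------------
# I/O


def read_network(path: str | Path) -> FunctionalNetwork:
    """Read a three-column TSV edge list (gene_a, gene_b, weight).

    Lines starting with ``#`` and blank lines are skipped.  Symmetric
    duplicates collapse to the maximum weight; self-loops and weights outside
    [0, 1] are rejected with the offending line number.
    """
    net = FunctionalNetwork()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            a, b, raw_w = parts[0], parts[1], parts[2]
            try:
                w = float(raw_w)
            except ValueError as exc:
                raise NetworkFormatError(
                    f"{path}:{lineno}: non-numeric weight {raw_w!r}"
                ) from exc
            try:
                net.add_edge(a, b, w)
            except NetworkFormatError as exc:
                raise NetworkFormatError(f"{path}:{lineno}: {exc}") from exc
    return net


def write_network(net: FunctionalNetwork, path: str | Path) -> None:
    """Write the canonicalised edge list: sorted pairs, sorted rows."""
    rows = sorted(
        (min(a, b), max(a, b), w) for a, b, w in net.edges()
    )
    with Path(path).open("w") as fh:
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:g}\n")


def read_node_list(path: str | Path) -> NodeList:
    """Read one gene identifier per line; optional second tab column is a label."""
    genes: list[str] = []
    labels: dict[str, str] = {}
    path = Path(path)
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            genes.append(parts[0])
            if len(parts) > 1:
                labels[parts[0]] = parts[1]
    return NodeList(genes, labels=labels or None, name=path.stem)


def write_node_list(nodelist: NodeList, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in nodelist.genes:
            if nodelist.labels and g in nodelist.labels:
                fh.write(f"{g}\t{nodelist.labels[g]}\n")
            else:
                fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# Core operations


def induce_subgraph(
    network: FunctionalNetwork, nodelist: NodeList | Sequence[str]
) -> InducedSubgraph:
    """Induce the subgraph of ``network`` over ``nodelist``.

    Identifiers absent from the network are dropped (count recorded and
    logged); an empty intersection is an error.
    """
    genes = list(nodelist)
    if not genes:
        raise ValueError("node list is empty")
    present = [g for g in genes if g in network]
    n_dropped = len(genes) - len(present)
    if not present:
        raise ValueError("no nodes mapped to network")
    if n_dropped:
        logger.info("induce_subgraph: dropped %d identifiers absent from network",
                    n_dropped)
    sub = nx.Graph()
    sub.add_nodes_from(sorted(present))
    node_set = set(present)
    for a in sorted(present):
        for b in network.neighbors(a):
            if b in node_set and a < b:
                sub.add_edge(a, b, weight=network.weight(a, b))
    return InducedSubgraph(parent=network, graph=sub, n_dropped=n_dropped)


def resample_subgraph(
    network: FunctionalNetwork, n: int, rng: np.random.Generator
) -> NodeList:
    """Sample ``n`` distinct nodes uniformly without replacement from the network."""
    pool = network.node_list()
    if n > len(pool):
        raise ValueError(
            f"cannot resample {n} nodes from a network of {len(pool)}"
        )
    idx = rng.choice(len(pool), size=n, replace=False)
    return NodeList([pool[i] for i in idx], name=f"resample_{n}")


def global_clustering_coefficient(subgraph: InducedSubgraph | nx.Graph) -> float:
    """Mean local clustering coefficient over *all* nodes.

    Nodes of degree < 2 (including isolated nodes) contribute zero, so a
    dataset whose induced subgraph is mostly disconnected scores near zero.
    This is nx ``average_clustering`` with ``count_zeros=True``.
    """
    g = subgraph.graph if isinstance(subgraph, InducedSubgraph) else subgraph
    if g.number_of_nodes() == 0:
        raise ValueError("clustering coefficient undefined for empty graph")
    return nx.average_clustering(g, count_zeros=True)
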