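"""Edge-level hypergeometric mutual clustering (HMC) and node coherence scores.

For each edge (i, j) of an induced subgraph S we ask whether i and j share
more neighbours within S than expected by chance.  Conditioning on the
connectivity of every other node v in S to i and to j gives a 2x2 table;
the one-sided (enrichment) hypergeometric tail probability is the edge's
HMC p-value.  The per-node summary is the NFCS: the degree-normalised sum
of -log p over incident edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from scipy.stats import hypergeom

from .graph_core import InducedSubgraph

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeScoreSet",
    "NodeScoreSet",
    "edge_contingency",
    "hmc_pvalue",
    "score_all_edges",
    "nfcs",
    "P_FLOOR",
]

#: p-values are clamped to this floor before taking logarithms.
P_FLOOR = 1e-300


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeScoreSet:
    """HMC p-values (the H1 distribution) for every edge of a subgraph.

    ``q`` holds per-edge positive-FDR annotations once
    :func:`netnc.fdr.estimate_pfdr` has run; until then it is empty.
    """

    p: dict[tuple[str, str], float]
    subgraph_size: int
    q: dict[tuple[str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.p)

    def p_values(self) -> list[float]:
        return list(self.p.values())

    def get_p(self, a: str, b: str) -> float:
        return self.p[_key(a, b)]

    def get_q(self, a: str, b: str) -> float:
        return self.q[_key(a, b)]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("gene_a\tgene_b\tp\tq\n")
            for (a, b) in sorted(self.p):
                qv = self.q.get((a, b))
                fh.write(
                    f"{a}\t{b}\t{self.p[(a, b)]:.6g}\t"
                    f"{'' if qv is None else format(qv, '.6g')}\n"
                )


@dataclass
class NodeScoreSet:
    """Node functional coherence scores and subgraph degrees."""

    scores: dict[str, float]
    degrees: dict[str, int]

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("gene\tdegree\tnfcs\n")
            for g in sorted(self.scores):
                fh.write(f"{g}\t{self.degrees[g]}\t{self.scores[g]:.6g}\n")


def edge_contingency(
    subgraph: InducedSubgraph, edge: tuple[str, str]
) -> tuple[int, int, int, int]:
    """2x2 neighbour table for an edge (i, j) of S.

    Candidate nodes are S minus {i, j}.  Returns
    ``(n11, n10, n01, n00)``: adjacent to both, to i only, to j only,
    to neither.  Cells sum to ``|S| - 2``.
    """
    i, j = edge
    if not subgraph.graph.has_edge(i, j):
        raise ValueError(f"edge ({i!r}, {j!r}) not in subgraph")
    ni = subgraph.neighbors(i) - {j}
    nj = subgraph.neighbors(j) - {i}
    n11 = len(ni & nj)
    n10 = len(ni) - n11
    n01 = len(nj) - n11
    n00 = subgraph.n_nodes - 2 - n11 - n10 - n01
    return n11, n10, n01, n00


def hmc_pvalue(table: tuple[int, int, int, int]) -> float:
    """One-sided upper-tail hypergeometric probability P(X >= n11).

    Population ``N = sum(table)``, success states = neighbours of i
    (``n11 + n10``), draws = neighbours of j (``n11 + n01``).  Degenerate
    zero-margin tables return 1.0.  Computed via the log survival function
    for numerical stability on large subgraphs.
    """
    n11, n10, n01, n00 = table
    if min(table) < 0:
        raise ValueError(f"negative cell in contingency table {table}")
    total = n11 + n10 + n01 + n00
    k_i = n11 + n10
    k_j = n11 + n01
    if n11 == 0 or k_i == 0 or k_j == 0:
        return 1.0
    logp = hypergeom.logsf(n11 - 1, total, k_i, k_j)
    p = math.exp(logp) if logp < 0 else 1.0
    return min(max(p, 0.0), 1.0)


def score_all_edges(subgraph: InducedSubgraph) -> EdgeScoreSet:
    """HMC p-value for every edge of the subgraph (the H1 distribution)."""
    if subgraph.n_edges == 0:
        logger.warning("score_all_edges: subgraph has no edges; empty score set")
        return EdgeScoreSet(p={}, subgraph_size=subgraph.n_nodes)
    n_nodes = subgraph.n_nodes
    nbrs = {v: set(subgraph.graph[v]) for v in subgraph.graph}
    p: dict[tuple[str, str], float] = {}
    for a, b in subgraph.edges():
        ni = nbrs[a] - {b}
        nj = nbrs[b] - {a}
        n11 = len(ni & nj)
        n10 = len(ni) - n11
        n01 = len(nj) - n11
        n00 = n_nodes - 2 - n11 - n10 - n01
        p[_key(a, b)] = hmc_pvalue((n11, n10, n01, n00))
    return EdgeScoreSet(p=p, subgraph_size=n_nodes)


def nfcs(subgraph: InducedSubgraph, scores: EdgeScoreSet) -> NodeScoreSet:
    """Node functional coherence score for every subgraph node.

    ``NFCS_i = -(1/d_i) * sum_j ln(p_ij)`` over edges incident to i;
    isolated nodes score exactly zero.  p-values are clamped at
    :data:`P_FLOOR` before the log.
    """
    out: dict[str, float] = {}
    deg: dict[str, int] = {}
    for v in subgraph.graph:
        d = subgraph.degree(v)
        deg[v] = d
        if d == 0:
            out[v] = 0.0
            continue
        s = 0.0
        for u in subgraph.graph[v]:
            s += math.log(max(scores.get_p(v, u), P_FLOOR))
        out[v] = -s / d
    return NodeScoreSet(scores=out, degrees=deg)
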