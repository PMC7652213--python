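"""Functional-target prediction: FTI (pFDR + iterative min cut) and FBT (GMM).

FTI keeps edges whose pFDR q is at most Q, then repeatedly splits any
connected component whose density falls below Z by a global minimum
weighted cut (edge weights are -ln p from H1); components of fewer than
three nodes are discarded at output.  FBT is parameter-free: it fits
Gaussian mixtures with 1..9 components to the NFCS distribution, selects
by BIC, and keeps the high-scoring mode(s).
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
from sklearn.mixture import GaussianMixture

from .coherence import EdgeScoreSet, NodeScoreSet, P_FLOOR
from .graph_core import FunctionalNetwork, InducedSubgraph

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSet",
    "GmmFit",
    "fti",
    "iterative_min_cut",
    "fbt",
    "fbt_network",
    "default_parameters",
    "graph_density",
    "ROBUST_Q",
    "ROBUST_Z",
    "DEFAULT_EDGE_Q",
]

#: Robust (Q, Z) parameters from benchmark optimisation without a noise prior.
ROBUST_Q = 0.120
ROBUST_Z = 0.306

#: Default edge pFDR threshold when exporting a network from FBT nodes.
DEFAULT_EDGE_Q = 0.1

#: Modes with mean NFCS below this are discarded (edgeless-node mass).
NFCS_MODE_FLOOR = 0.05

#: SD of the Gaussian noise injected into NFCS == 0 nodes when a unimodal
#: mixture is returned (GN0 fallback).
GN0_NOISE_SD = 0.01


def graph_density(g: nx.Graph) -> float:
    """2m / (n(n-1)); single nodes count as density 1 (trivially dense)."""
    n = g.number_of_nodes()
    if n <= 1:
        return 1.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


@dataclass
class Cluster:
    nodes: list[str]
    edges: list[tuple[str, str]]
    density: float
    mean_neglogp: float


@dataclass
class ClusterSet:
    """Disjoint node clusters output by FTI, each size >= 3 and density >= Z."""

    clusters: list[Cluster]
    Q: float
    Z: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def all_nodes(self) -> set[str]:
        return {g for c in self.clusters for g in c.nodes}

    def all_edges(self) -> set[tuple[str, str]]:
        return {e for c in self.clusters for e in c.edges}

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("gene\tcluster_id\n")
            for cid, c in enumerate(self.clusters, start=1):
                for g in sorted(c.nodes):
                    fh.write(f"{g}\t{cid}\n")

    def summary_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("cluster_id\tsize\tdensity\tmean_neglogp\n")
            for cid, c in enumerate(self.clusters, start=1):
                fh.write(
                    f"{cid}\t{len(c.nodes)}\t{c.density:.6g}\t{c.mean_neglogp:.6g}\n"
                )


def _component_subgraphs(g: nx.Graph) -> list[nx.Graph]:
    """Connected components as standalone graphs, descending size then lexical."""
    comps = sorted(
        nx.connected_components(g),
        key=lambda c: (-len(c), min(c)),
    )
    out = []
    for comp in comps:
        sub = nx.Graph()
        sub.add_nodes_from(sorted(comp))
        for a, b, data in g.subgraph(comp).edges(data=True):
            sub.add_edge(a, b, **data)
        out.append(sub)
    return out


def iterative_min_cut(g: nx.Graph, Z: float) -> list[nx.Graph]:
    """Split components by global minimum weighted cut until density >= Z.

    Edge weights must be positive under the 'weight' attribute.  Components
    are processed in descending size order; singleton components terminate
    trivially.  Deterministic: graphs are rebuilt with sorted node insertion
    before each Stoer-Wagner cut, which fixes the cut returned among ties.
    """
    done: list[nx.Graph] = []
    queue = deque(_component_subgraphs(g))
    while queue:
        comp = queue.popleft()
        if comp.number_of_nodes() <= 1 or graph_density(comp) >= Z:
            done.append(comp)
            continue
        if comp.number_of_edges() == 0:
            # disconnected inside a "component" cannot happen; defensive
            done.append(comp)
            continue
        _, (side_a, side_b) = nx.stoer_wagner(comp)
        for side in (side_a, side_b):
            sub = nx.Graph()
            sub.add_nodes_from(sorted(side))
            side_set = set(side)
            for a, b, data in comp.edges(data=True):
                if a in side_set and b in side_set:
                    sub.add_edge(a, b, **data)
            # a cut side may itself be disconnected; re-split
            queue.extend(_component_subgraphs(sub))
    return done


def fti(
    subgraph: InducedSubgraph,
    h1: EdgeScoreSet,
    Q: float = ROBUST_Q,
    Z: float = ROBUST_Z,
) -> ClusterSet:
    """Functional Target Identification clustering.

    Induces the graph C of edges with q <= Q, weights each edge -ln p,
    applies :func:`iterative_min_cut` to density Z and discards components
    of fewer than three nodes.
    """
    if not h1.q:
        raise ValueError("edge q annotations missing; run estimate_pfdr first")
    if not (0.0 < Q <= 1.0) or not (0.0 < Z <= 1.0):
        raise ValueError(f"thresholds out of range: Q={Q}, Z={Z}")
    c = nx.Graph()
    for (a, b), q in sorted(h1.q.items()):
        if q <= Q:
            w = -math.log(max(h1.p[(a, b)], P_FLOOR))
            c.add_edge(a, b, weight=w, neglogp=w)
    if c.number_of_edges() == 0:
        logger.warning("fti: no edge passed Q=%g; empty cluster set", Q)
        return ClusterSet(clusters=[], Q=Q, Z=Z)
    comps = iterative_min_cut(c, Z)
    clusters = []
    for comp in comps:
        if comp.number_of_nodes() < 3:
            continue
        edges = [(a, b) if a <= b else (b, a) for a, b in comp.edges()]
        neglogp = [comp[a][b]["neglogp"] for a, b in edges]
        clusters.append(
            Cluster(
                nodes=sorted(comp.nodes),
                edges=sorted(edges),
                density=graph_density(comp),
                mean_neglogp=float(np.mean(neglogp)) if neglogp else 0.0,
            )
        )
    clusters.sort(key=lambda cl: (-len(cl.nodes), cl.nodes[0]))
    return ClusterSet(clusters=clusters, Q=Q, Z=Z)


@dataclass
class GmmFit:
    """Selected Gaussian mixture over NFCS values."""

    n_components: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bic: dict[int, float]
    assignment: dict[str, int]
    gn0_applied: bool = False
    surviving_modes: list[int] = field(default_factory=list)


def _fit_gmm(values: np.ndarray, rng: np.random.Generator) -> GaussianMixture:
    """BIC selection over 1..9 full-covariance 1-D Gaussian mixtures."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    x = values.reshape(-1, 1)
    max_k = min(9, len(values))
    best = None
    best_bic = math.inf
    bics: dict[int, float] = {}
    for k in range(1, max_k + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=10,
            reg_covar=1e-6,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        with warnings.catch_warnings():
            # degenerate inputs (e.g. all-zero NFCS) legitimately collapse
            # duplicate components; BIC still ranks the candidates
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm.fit(x)
        b = gm.bic(x)
        bics[k] = float(b)
        if b < best_bic:
            best_bic = b
            best = gm
    best._bics = bics  # type: ignore[attr-defined]
    return best


def fbt(
    node_scores: NodeScoreSet, rng: np.random.Generator
) -> tuple[list[str], GmmFit]:
    """Functional Binding Target prediction from the NFCS distribution.

    Fits mixtures of 1..9 Gaussians (independent mean/sd per component),
    selects by BIC.  If the selected model is unimodal, the GN0 fallback
    adds N(0, 0.01) noise to NFCS == 0 nodes and refits — a large
    non-Gaussian spike at zero can otherwise confound fitting.  Modes with
    mean NFCS < 0.05 are excluded (edgeless-node mass); if more than one
    mode then remains, the lowest-scoring one is also eliminated.  Returns
    the genes of surviving modes and the fit.
    """
    genes = sorted(node_scores.scores)
    if len(genes) < 3:
        raise ValueError("need at least 3 scored nodes for FBT")
    values = np.array([node_scores.scores[g] for g in genes])
    gm = _fit_gmm(values, rng)
    gn0 = False
    if gm.n_components == 1:
        gn0 = True
        noisy = values.copy()
        zero = noisy == 0.0
        noisy[zero] = rng.normal(0.0, GN0_NOISE_SD, size=int(zero.sum()))
        gm = _fit_gmm(noisy, rng)
        values_fit = noisy
    else:
        values_fit = values
    labels = gm.predict(values_fit.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(-1))
    surviving = [k for k in range(gm.n_components) if means[k] >= NFCS_MODE_FLOOR]
    if len(surviving) > 1:
        surviving = sorted(surviving, key=lambda k: means[k])[1:]
    functional = [g for g, lab in zip(genes, labels) if lab in set(surviving)]
    fit = GmmFit(
        n_components=gm.n_components,
        means=means,
        sds=sds,
        weights=gm.weights_.ravel(),
        bic=getattr(gm, "_bics", {}),
        assignment=dict(zip(genes, labels.tolist())),
        gn0_applied=gn0,
        surviving_modes=sorted(surviving),
    )
    if gn0:
        logger.info("fbt: GN0 fallback applied (unimodal first fit)")
    return sorted(functional), fit


def fbt_network(
    functional_genes: list[str],
    h1: EdgeScoreSet,
    edge_q_threshold: float = DEFAULT_EDGE_Q,
) -> FunctionalNetwork:
    """Network over FBT-predicted genes keeping edges with q <= threshold."""
    if not h1.q:
        raise ValueError("edge q annotations missing")
    keep = set(functional_genes)
    net = FunctionalNetwork.from_edges([], nodes=functional_genes)
    for (a, b), q in h1.q.items():
        if a in keep and b in keep and q <= edge_q_threshold:
            net.add_edge(a, b, min(q, 1.0))
    return net


def default_parameters(
    sntg_estimate: Optional[float] = None,
    parameter_map: Optional[dict[float, tuple[float, float]]] = None,
) -> tuple[float, float]:
    """(Q, Z) selection.

    Without a noise estimate the robust pair (0.120, 0.306) is returned.
    With an estimate, a user-supplied noise-fraction -> (Q, Z) map (as fit
    on their own benchmark via :mod:`netnc.evaluation`) is consulted at the
    nearest key.
    """
    if sntg_estimate is None:
        return ROBUST_Q, ROBUST_Z
    if not (0.0 <= sntg_estimate <= 1.0):
        raise ValueError(f"sntg_estimate {sntg_estimate} outside [0, 1]")
    if not parameter_map:
        logger.info("no SNTG parameter map supplied; using robust defaults")
        return ROBUST_Q, ROBUST_Z
    key = min(parameter_map, key=lambda k: abs(k - sntg_estimate))
    return parameter_map[key]
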