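"""Synthetic gold-standard benchmark generation and the CC-vs-size model.

Real evaluation of functional-target callers is confounded by indirect
regulation and redundant TFs, so the benchmark is synthetic: biological
pathways stand in for functional targets and uniformly resampled network
genes stand in for neutral binding (synthetic neutral target genes, SNTGs).
A planted-partition fixture network — dense pathway modules over a sparse
background — lets every stage run without external downloads.  A per-noise-
level linear model of global clustering coefficient on log dataset size maps
real candidate lists onto the synthetic noise scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .graph_core import (
    FunctionalNetwork,
    InducedSubgraph,
    NodeList,
    global_clustering_coefficient,
    induce_subgraph,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayCollection",
    "GoldStandardDataset",
    "BenchmarkCollection",
    "CcSizeModel",
    "read_gmt",
    "write_gmt",
    "generate_dataset",
    "generate_collection",
    "synthetic_network",
    "fit_cc_model",
    "predict_cc",
]

SNTG_LABEL = "SNTG"

#: Default %SNTG grid: 5% through 80% in 5% steps.
DEFAULT_FRACTIONS = tuple(round(0.05 * i, 2) for i in range(1, 17))


@dataclass
class PathwayCollection:
    """Ordered pathway definitions: name -> member genes."""

    pathways: dict[str, list[str]]

    @property
    def names(self) -> list[str]:
        return list(self.pathways)

    def genes(self, names: Optional[Sequence[str]] = None) -> list[str]:
        """Union of member genes over the given pathways (order-preserving)."""
        seen: set[str] = set()
        out: list[str] = []
        for name in names if names is not None else self.names:
            for g in self.pathways[name]:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    def subset(self, names: Sequence[str]) -> "PathwayCollection":
        return PathwayCollection({n: list(self.pathways[n]) for n in names})

    def __len__(self) -> int:
        return len(self.pathways)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT-style pathway file: name, description, members (tab-separated)."""
    pathways: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT rows need name, description, >=1 member"
                )
            pathways[parts[0]] = [g for g in parts[2:] if g]
    return PathwayCollection(pathways)


def write_gmt(pathways: PathwayCollection, path: str | Path,
              description: str = "synthetic") -> None:
    with Path(path).open("w") as fh:
        for name, members in pathways.pathways.items():
            fh.write(name + "\t" + description + "\t" + "\t".join(members) + "\n")


@dataclass
class GoldStandardDataset:
    """Pathway genes plus SNTGs, with per-gene labels.

    ``sntg_fraction`` is the target proportion of the *final* list that is
    neutral; the realised count is within one gene of the target.
    """

    nodelist: NodeList
    sntg_fraction: float
    pathway_subset: list[str]
    replicate_id: int = 0

    @property
    def genes(self) -> list[str]:
        return self.nodelist.genes

    def positives(self) -> list[str]:
        return [g for g in self.genes if self.nodelist.labels[g] != SNTG_LABEL]

    def negatives(self) -> list[str]:
        return [g for g in self.genes if self.nodelist.labels[g] == SNTG_LABEL]


@dataclass
class BenchmarkCollection:
    datasets: list[GoldStandardDataset]
    subset_sizes: list[int]
    fractions: list[float]
    n_replicates: int
    pathway_order: list[str]

    def __len__(self) -> int:
        return len(self.datasets)

    def at(self, subset_size: Optional[int] = None,
           fraction: Optional[float] = None) -> list[GoldStandardDataset]:
        out = self.datasets
        if subset_size is not None:
            out = [d for d in out if len(d.pathway_subset) == subset_size]
        if fraction is not None:
            out = [d for d in out if abs(d.sntg_fraction - fraction) < 1e-9]
        return out


def generate_dataset(
    pathways: PathwayCollection,
    network: FunctionalNetwork,
    sntg_fraction: float,
    rng: np.random.Generator,
    replicate_id: int = 0,
) -> GoldStandardDataset:
    """Combine pathway genes with SNTGs resampled from the network.

    With n_path pathway genes and target final SNTG proportion f, the
    number of neutral genes is ``round(n_path * f / (1 - f))``; draws are
    uniform without replacement from network nodes excluding the current
    pathway genes.
    """
    if not (0.0 <= sntg_fraction < 1.0):
        raise ValueError(f"sntg_fraction {sntg_fraction} must be in [0, 1)")
    path_genes = pathways.genes()
    missing = [g for g in path_genes if g not in network]
    if missing:
        raise ValueError(
            f"{len(missing)} pathway genes absent from network: "
            + ", ".join(missing[:10])
        )
    n_path = len(path_genes)
    n_sntg = int(round(n_path * sntg_fraction / (1.0 - sntg_fraction)))
    exclude = set(path_genes)
    pool = [g for g in network.node_list() if g not in exclude]
    if n_sntg > len(pool):
        raise ValueError("network too small for requested SNTG count")
    idx = rng.choice(len(pool), size=n_sntg, replace=False)
    sntgs = [pool[i] for i in idx]
    labels: dict[str, str] = {}
    for name, members in pathways.pathways.items():
        for g in members:
            labels.setdefault(g, name)
    for g in sntgs:
        labels[g] = SNTG_LABEL
    return GoldStandardDataset(
        nodelist=NodeList(path_genes + sntgs, labels=labels),
        sntg_fraction=sntg_fraction,
        pathway_subset=pathways.names,
        replicate_id=replicate_id,
    )


def generate_collection(
    pathways: PathwayCollection,
    network: FunctionalNetwork,
    subset_sizes: Sequence[int],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_replicates: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> BenchmarkCollection:
    """Grid of datasets: pathway-subset sizes x noise fractions x replicates.

    Pathway subsets are nested prefixes of the collection's pathway order,
    so cardinality is exactly ``len(subset_sizes) * len(fractions) *
    n_replicates``.
    """
    if rng is None:
        rng = np.random.default_rng()
    order = pathways.names
    if max(subset_sizes) > len(order):
        raise ValueError("subset size exceeds pathway count")
    datasets: list[GoldStandardDataset] = []
    for size in subset_sizes:
        subset = pathways.subset(order[:size])
        for frac in fractions:
            for rep in range(n_replicates):
                datasets.append(
                    generate_dataset(subset, network, frac, rng, replicate_id=rep)
                )
    return BenchmarkCollection(
        datasets=datasets,
        subset_sizes=list(subset_sizes),
        fractions=list(fractions),
        n_replicates=n_replicates,
        pathway_order=order,
    )


def synthetic_network(
    n_pathways: int = 8,
    genes_per_pathway: int = 25,
    n_background: int = 2000,
    p_within: float = 0.35,
    p_between: float = 0.01,
    rng: Optional[np.random.Generator] = None,
) -> tuple[FunctionalNetwork, PathwayCollection]:
    """Planted-partition fixture network with GMT-compatible pathway labels.

    Each pathway is a dense Bernoulli(p_within) module; all other pairs
    (background-background, background-pathway, cross-pathway) connect with
    probability p_between.  Edge weights are drawn uniform on [0.78, 1.0]
    to mimic a thresholded high-confidence network.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not (0.0 <= p_between <= 1.0) or not (0.0 <= p_within <= 1.0):
        raise ValueError("densities must lie in [0, 1]")
    if p_within <= p_between:
        raise ValueError("p_within must exceed p_between")
    membership: dict[str, list[str]] = {}
    names: list[str] = []
    block: dict[str, int] = {}
    for p in range(n_pathways):
        pname = f"pw{p:02d}"
        members = [f"pw{p:02d}g{i:03d}" for i in range(genes_per_pathway)]
        membership[pname] = members
        for g in members:
            block[g] = p
        names.extend(members)
    for i in range(n_background):
        g = f"bg{i:05d}"
        block[g] = -1
        names.append(g)
    n = len(names)
    net = FunctionalNetwork.from_edges([], nodes=names)
    # vectorised Bernoulli draw over the upper triangle, chunked by row
    blocks = np.array([block[g] for g in names])
    for i in range(n - 1):
        m = n - i - 1
        same = (blocks[i + 1:] == blocks[i]) & (blocks[i] >= 0)
        probs = np.where(same, p_within, p_between)
        hits = np.nonzero(rng.random(m) < probs)[0]
        if hits.size:
            weights = 0.78 + 0.22 * rng.random(hits.size)
            for h, w in zip(hits, weights):
                net.add_edge(names[i], names[i + 1 + h], float(w))
    return net, PathwayCollection(membership)


@dataclass
class CcSizeModel:
    """Per-noise-level linear model CC = intercept + coefficient * log(n)."""

    intercept: float
    coefficient: float
    sntg_fraction: float
    n_points: int


def fit_cc_model(
    collection: BenchmarkCollection,
    network: FunctionalNetwork,
    sntg_fraction: float,
) -> CcSizeModel:
    """OLS of mean induced-subgraph CC on log node count at one noise level.

    For each pathway-subset size, the mean CC across replicates and the
    mean log dataset size give one point; at least two distinct sizes are
    required.
    """
    points = []
    for size in sorted(set(collection.subset_sizes)):
        ds = collection.at(subset_size=size, fraction=sntg_fraction)
        if not ds:
            continue
        ccs, logns = [], []
        for d in ds:
            sub = induce_subgraph(network, d.nodelist)
            ccs.append(global_clustering_coefficient(sub))
            logns.append(np.log(len(d.genes)))
        points.append((float(np.mean(ccs)), float(np.mean(logns))))
    if len(points) < 2:
        raise ValueError("need >= 2 distinct dataset sizes to fit the CC model")
    y = np.array([p[0] for p in points])
    x = np.array([p[1] for p in points])
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    return CcSizeModel(
        intercept=float(ols.params[0]),
        coefficient=float(ols.params[1]),
        sntg_fraction=sntg_fraction,
        n_points=len(points),
    )


def predict_cc(model: CcSizeModel, n_nodes: int) -> float:
    """Predicted CC at a dataset size, clamped to [0, 1]."""
    val = model.intercept + model.coefficient * np.log(n_nodes)
    return float(np.clip(val, 0.0, 1.0))
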