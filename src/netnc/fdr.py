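"""Empirical-null positive FDR and local FDR for HMC edge p-values.

The null distribution H0 pools HMC p-values over Y subgraphs of the same
size as S resampled uniformly from G, so it reflects the structure of G
(degree distribution included) at the observed sample size while remaining
agnostic about the structure of S itself.  The positive false discovery
rate at a threshold p_alpha is E(V/R | R > 0), with V estimated from the
null and a running-maximum monotonicity constraint.  Local FDR per node is
derived from consecutive global pFDR levels by a telescoping construction:
the false positives added between two adjacent significance levels are
attributed to the nodes entering at the later level.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .coherence import EdgeScoreSet, score_all_edges
from .graph_core import (
    FunctionalNetwork,
    NodeList,
    induce_subgraph,
    resample_subgraph,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "PfdrMap",
    "NodeLcfdr",
    "build_null",
    "estimate_pfdr",
    "node_pfdr_min",
    "lcfdr",
    "FunctionalBindingEstimate",
    "functional_binding_estimate",
]

#: Default number of null resamples (Y).
DEFAULT_Y = 100

#: pfdr_min values are rounded to this many significant digits before
#: grouping into lcFDR levels, guarding against platform float jitter.
_LEVEL_SIGFIGS = 12


@dataclass
class NullDistribution:
    """Pooled HMC p-values from Y resampled induced subgraphs (H0)."""

    pooled_p: np.ndarray  # sorted ascending
    Y: int
    n_nodes: int

    def count_leq(self, p_alpha: float) -> int:
        return bisect_right(self.pooled_p, p_alpha)


@dataclass
class PfdrMap:
    """Positive FDR per candidate threshold stepped through H1 p-values."""

    thresholds: np.ndarray  # ascending distinct p-values from H1
    pfdr: np.ndarray        # monotone non-decreasing, in [0, 1]
    V: np.ndarray           # estimated false positives at each threshold
    R: np.ndarray           # significant-edge count at each threshold

    def lookup(self, p: float) -> float:
        """pFDR at the smallest stored threshold >= p (p is always in H1)."""
        idx = int(np.searchsorted(self.thresholds, p, side="left"))
        idx = min(idx, len(self.thresholds) - 1)
        return float(self.pfdr[idx])


def build_null(
    network: FunctionalNetwork,
    n_nodes: int,
    Y: int,
    rng: np.random.Generator,
) -> NullDistribution:
    """Pool HMC p-values over Y uniformly resampled subgraphs of n_nodes."""
    if Y < 1:
        raise ValueError("Y must be >= 1")
    pooled: list[float] = []
    for _ in range(Y):
        nodes = resample_subgraph(network, n_nodes, rng)
        sub = induce_subgraph(network, nodes)
        scores = score_all_edges(sub)
        pooled.extend(scores.p_values())
    arr = np.sort(np.asarray(pooled, dtype=float))
    return NullDistribution(pooled_p=arr, Y=Y, n_nodes=n_nodes)


def estimate_pfdr(h1: EdgeScoreSet, h0: NullDistribution) -> PfdrMap:
    """Estimate pFDR over the H1 p-values against the resampled null.

    At each candidate threshold p_alpha (the sorted distinct observed H1
    p-values): ``V = #{H0 <= p_alpha} / Y``, ``R = #{H1 <= p_alpha}``,
    ``pFDR = min(V / R, 1)``; a running maximum then enforces monotonicity.
    Per-edge q annotations are written back into ``h1``.
    """
    if len(h1) == 0:
        raise ValueError("cannot estimate pFDR from an empty edge score set")
    h1_sorted = np.sort(np.asarray(h1.p_values(), dtype=float))
    thresholds = np.unique(h1_sorted)
    R = np.searchsorted(h1_sorted, thresholds, side="right").astype(float)
    counts = np.searchsorted(h0.pooled_p, thresholds, side="right")
    V = counts / h0.Y
    raw = np.minimum(V / R, 1.0)
    pfdr = np.maximum.accumulate(raw)
    pmap = PfdrMap(thresholds=thresholds, pfdr=pfdr, V=V, R=R)
    for edge, p in h1.p.items():
        h1.q[edge] = pmap.lookup(p)
    return pmap


def node_pfdr_min(h1: EdgeScoreSet) -> dict[str, float]:
    """Most significant (minimum) edge pFDR per node.

    This is the pFDR level at which the node first enters a thresholded
    network.  Nodes with no scored edges are omitted.
    """
    if not h1.q:
        raise ValueError("edge q annotations missing; run estimate_pfdr first")
    out: dict[str, float] = {}
    for (a, b), q in h1.q.items():
        for g in (a, b):
            if g not in out or q < out[g]:
                out[g] = q
    return out


@dataclass
class NodeLcfdr:
    """Per-node local FDR derived from grouped pfdr_min levels."""

    lcfdr: dict[str, float]
    pfdr_min: dict[str, float]
    levels: np.ndarray        # distinct ascending pfdr_min values
    level_counts: np.ndarray  # X per level
    level_lcfdr: np.ndarray   # lcFDR per level

    def mean(self) -> float:
        return float(np.mean(list(self.lcfdr.values())))


def lcfdr(pfdr_min: dict[str, float]) -> NodeLcfdr:
    """Local FDR per node from its pfdr_min level.

    Nodes are grouped by distinct ascending pfdr_min (levels).  The first
    level's lcFDR equals its pFDR (global and local FDR coincide when all
    objects sit at one level).  For a later level k with previous level l:
    ``lcFDR_k = (n * pFDR_k - (n - X) * pFDR_l) / X`` where n counts nodes
    at or below level k and X counts nodes exactly at k.  Values are not
    clipped: the telescoping conservation
    ``sum_k X_k * lcFDR_k = n_total * pFDR_last`` holds exactly.
    """
    if not pfdr_min:
        raise ValueError("pfdr_min is empty")
    rounded = {
        g: float(np.format_float_positional(
            v, precision=_LEVEL_SIGFIGS, unique=False, fractional=False))
        for g, v in pfdr_min.items()
    }
    levels = np.array(sorted(set(rounded.values())))
    counts = np.zeros(len(levels), dtype=int)
    level_index = {v: i for i, v in enumerate(levels)}
    for v in rounded.values():
        counts[level_index[v]] += 1
    level_lc = np.empty(len(levels))
    n_cum = 0
    for k, (lvl, X) in enumerate(zip(levels, counts)):
        n_cum += X
        if k == 0:
            level_lc[k] = lvl
        else:
            prev = levels[k - 1]
            level_lc[k] = (n_cum * lvl - (n_cum - X) * prev) / X
    per_node = {g: float(level_lc[level_index[v]]) for g, v in rounded.items()}
    return NodeLcfdr(
        lcfdr=per_node,
        pfdr_min=dict(pfdr_min),
        levels=levels,
        level_counts=counts,
        level_lcfdr=level_lc,
    )


def mean_lcfdr_for_list(
    nodelist: NodeList | Sequence[str],
    network: FunctionalNetwork,
    Y: int,
    rng: np.random.Generator,
    null: Optional[NullDistribution] = None,
) -> float:
    """Run induce -> HMC -> pFDR -> lcFDR and return the mean node lcFDR.

    Nodes of the induced subgraph with no edges never receive a pfdr_min;
    they are counted as fully neutral (lcFDR 1), since isolation in G-context
    is the signature of no pathway co-membership with the rest of the list.
    """
    sub = induce_subgraph(network, nodelist)
    scores = score_all_edges(sub)
    if len(scores) == 0:
        raise ValueError("induced subgraph has no edges; lcFDR undefined")
    if null is None:
        null = build_null(network, sub.n_nodes, Y, rng)
    estimate_pfdr(scores, null)
    pmin = node_pfdr_min(scores)
    result = lcfdr(pmin)
    vals = [min(max(v, 0.0), 1.0) for v in result.lcfdr.values()]
    n_isolated = sub.n_nodes - len(vals)
    vals.extend([1.0] * n_isolated)
    return float(np.mean(vals))


@dataclass
class FunctionalBindingEstimate:
    """Calibrated estimate of the functional fraction of a candidate list."""

    functional_fraction: float          # calibrated, in [0, 1]
    ci_low: float
    ci_high: float
    mean_lcfdr: float                   # real list
    faux_mean_lcfdr: float              # mean over faux resampled lists
    raw_functional_fraction: float      # uncalibrated 1 - mean lcFDR
    n_calibration: int
    faux_means: np.ndarray = field(repr=False, default=None)


def functional_binding_estimate(
    nodelist: NodeList,
    network: FunctionalNetwork,
    Y: int,
    n_calibration: int,
    rng: np.random.Generator,
    null: Optional[NullDistribution] = None,
) -> FunctionalBindingEstimate:
    """Estimate the fraction of a candidate list that is functionally coherent.

    The full pipeline runs on the real list and on ``n_calibration`` faux
    lists of identical size resampled uniformly from the network.  Fully
    neutral lists must map to zero functional fraction, so the calibrated
    estimate is ``1 - mean_lcfdr(real) / mean_lcfdr(faux)`` clipped to
    [0, 1]; the 95% CI comes from quantiles of the same statistic computed
    against each individual faux baseline.
    """
    present = [g for g in nodelist if g in network]
    if len(present) < 3:
        raise ValueError("node list maps to fewer than 3 network nodes")
    n = len(present)
    if null is None:
        null = build_null(network, n, Y, rng)
    real_mean = mean_lcfdr_for_list(present, network, Y, rng, null=null)
    faux_means = np.empty(n_calibration)
    for i in range(n_calibration):
        faux = resample_subgraph(network, n, rng)
        faux_means[i] = mean_lcfdr_for_list(faux, network, Y, rng, null=null)
    baseline = float(np.mean(faux_means))
    if baseline <= 0:
        logger.warning("faux baseline mean lcFDR is zero; calibration degenerate")
        frac = 1.0 - real_mean
        per_faux = np.full(n_calibration, frac)
    else:
        frac = 1.0 - real_mean / baseline
        per_faux = 1.0 - real_mean / np.maximum(faux_means, 1e-12)
    frac = float(np.clip(frac, 0.0, 1.0))
    lo, hi = np.quantile(np.clip(per_faux, 0.0, 1.0), [0.025, 0.975])
    return FunctionalBindingEstimate(
        functional_fraction=frac,
        ci_low=float(lo),
        ci_high=float(hi),
        mean_lcfdr=real_mean,
        faux_mean_lcfdr=baseline,
        raw_functional_fraction=float(np.clip(1.0 - real_mean, 0.0, 1.0)),
        n_calibration=n_calibration,
        faux_means=faux_means,
    )
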