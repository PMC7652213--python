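"""Classification metrics, parameter optimisation and robustness procedures.

The benchmark task is binary: pathway genes are positives, SNTGs negatives,
and a clustering run's predicted-functional set is scored by MCC/FPR/TPR.
Parameter selection sweeps an FTI pipeline over a (Q, Z) grid, masks the
high-performing region and takes the centre of the largest circle inscribed
in it — favouring parameters that generalise over narrow ridges.  A Fisher
exact overlap test compares two networks over their shared genes, and a
subsampling procedure quantifies output stability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.stats import hypergeom, rankdata

from .benchmark import BenchmarkCollection, GoldStandardDataset
from .graph_core import FunctionalNetwork, NodeList

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "PerformanceGrid",
    "score_predictions",
    "mcc",
    "auc",
    "parameter_grid_search",
    "select_parameters",
    "network_overlap_test",
    "OverlapTest",
    "subsample_robustness",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def mcc(self) -> float:
        return mcc(self.tp, self.fp, self.tn, self.fn)

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def f_measure(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any margin is zero."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def score_predictions(
    predicted: set[str] | Sequence[str], gold: GoldStandardDataset
) -> ConfusionCounts:
    """Confusion counts for a predicted-functional gene set against a
    gold-standard dataset (pathway genes positive, SNTGs negative)."""
    pred = set(predicted)
    universe = set(gold.genes)
    outside = pred - universe
    if outside:
        raise ValueError(
            f"{len(outside)} predicted genes outside the gold standard: "
            + ", ".join(sorted(outside)[:5])
        )
    pos = set(gold.positives())
    neg = set(gold.negatives())
    return ConfusionCounts(
        tp=len(pred & pos),
        fp=len(pred & neg),
        tn=len(neg - pred),
        fn=len(pos - pred),
    )


def auc(scores: dict[str, float], gold: GoldStandardDataset) -> float:
    """Rank-based (Mann-Whitney) AUC of scores for pathway-vs-SNTG labels.

    Ties receive midranks.  Genes without a score are assigned the minimum
    observed score (scored below everything else).
    """
    pos = set(gold.positives())
    neg = set(gold.negatives())
    if not pos or not neg:
        raise ValueError("both classes must be present for AUC")
    floor = min(scores.values()) if scores else 0.0
    genes = gold.genes
    vals = np.array([scores.get(g, floor) for g in genes])
    labels = np.array([g in pos for g in genes])
    ranks = rankdata(vals)
    n_pos = int(labels.sum())
    n_neg = len(genes) - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class PerformanceGrid:
    """Mean MCC per (Q, Z) cell, with per-dataset distributions retained."""

    Q_values: np.ndarray
    Z_values: np.ndarray
    mean_mcc: np.ndarray              # shape (len(Q), len(Z))
    per_dataset: np.ndarray           # shape (len(Q), len(Z), n_datasets)
    n_failures: int = 0


def parameter_grid_search(
    collection: BenchmarkCollection | Sequence[GoldStandardDataset],
    Q_grid: Sequence[float],
    Z_grid: Sequence[float],
    runner: Callable[[GoldStandardDataset, float, float], set[str]],
) -> PerformanceGrid:
    """Mean MCC over datasets at every (Q, Z) cell.

    ``runner(dataset, Q, Z)`` returns the predicted-functional gene set;
    failures are logged and the cell mean is taken over successes.
    """
    if not len(Q_grid) or not len(Z_grid):
        raise ValueError("parameter grids must be non-empty")
    datasets = (
        collection.datasets
        if isinstance(collection, BenchmarkCollection)
        else list(collection)
    )
    per = np.full((len(Q_grid), len(Z_grid), len(datasets)), np.nan)
    failures = 0
    for qi, Q in enumerate(Q_grid):
        for zi, Z in enumerate(Z_grid):
            for di, ds in enumerate(datasets):
                try:
                    pred = runner(ds, Q, Z)
                    per[qi, zi, di] = score_predictions(pred, ds).mcc
                except Exception as exc:  # noqa: BLE001 - batch robustness
                    failures += 1
                    logger.warning("grid cell (%g, %g) dataset %d failed: %s",
                                   Q, Z, di, exc)
    if failures:
        logger.warning("parameter_grid_search: %d dataset runs failed", failures)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per, axis=2)
    return PerformanceGrid(
        Q_values=np.asarray(Q_grid, dtype=float),
        Z_values=np.asarray(Z_grid, dtype=float),
        mean_mcc=mean,
        per_dataset=per,
        n_failures=failures,
    )


def _largest_circle_centre(mask: np.ndarray) -> tuple[int, int]:
    """Index of the centre of the largest circle inscribed in a boolean mask.

    Computed by Euclidean distance transform in normalised grid coordinates;
    ties broken toward the larger first index, then larger second index.
    """
    if not mask.any():
        raise ValueError(
            "admissible region is empty; refine the parameter grid"
        )
    dist = distance_transform_edt(mask)
    best = np.max(dist)
    cands = np.argwhere(dist == best)
    # prefer larger Q index, then larger Z index
    order = sorted(map(tuple, cands), key=lambda t: (-t[0], -t[1]))
    return order[0]


def select_parameters(
    grids: PerformanceGrid | Sequence[PerformanceGrid],
    mode: str = "robust",
    robust_fraction_threshold: float = 0.5,
    normalised_floor: float = 0.75,
    region_level: float = 0.95,
) -> tuple[float, float]:
    """Choose (Q, Z) from one or more performance grids.

    ``sntg_specified`` mode: each grid (one per pathway-subset) is
    normalised to its maximum MCC, values below ``normalised_floor`` zeroed,
    grids averaged; the admissible region is cells at >= ``region_level`` of
    the averaged maximum and the centre of its largest inscribed circle is
    returned.  ``robust`` mode: the admissible region is cells where the
    fraction of individual datasets beating ``normalised_floor`` of the
    per-dataset maximum exceeds ``robust_fraction_threshold``; the same
    circle rule applies.
    """
    if isinstance(grids, PerformanceGrid):
        grids = [grids]
    Q_values, Z_values = grids[0].Q_values, grids[0].Z_values
    if mode == "sntg_specified":
        normed = []
        for g in grids:
            m = np.nan_to_num(g.mean_mcc, nan=0.0)
            top = m.max()
            nm = m / top if top > 0 else m
            nm = np.where(nm < normalised_floor, 0.0, nm)
            normed.append(nm)
        avg = np.mean(normed, axis=0)
        mask = avg >= region_level * avg.max() if avg.max() > 0 else avg > 0
    elif mode == "robust":
        per = np.concatenate([g.per_dataset for g in grids], axis=2)
        best_per_ds = np.nanmax(per, axis=(0, 1))
        valid = best_per_ds > 0  # a dataset nothing scores on is uninformative
        if not valid.any():
            raise ValueError(
                "admissible region is empty; refine the parameter grid"
            )
        per = per[:, :, valid]
        best_per_ds = best_per_ds[valid]
        with np.errstate(invalid="ignore"):
            beats = per >= normalised_floor * best_per_ds[None, None, :]
            frac = np.nanmean(np.where(np.isnan(per), np.nan, beats), axis=2)
        frac = np.nan_to_num(frac, nan=0.0)
        mask = frac >= robust_fraction_threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    qi, zi = _largest_circle_centre(mask)
    return float(Q_values[qi]), float(Z_values[zi])


@dataclass
class OverlapTest:
    """2x2 edge-overlap contingency between two networks on shared genes."""

    n_shared_genes: int
    both: int
    a_only: int
    b_only: int
    neither: int
    log10_p: float
    shared_edge_fraction: float  # of the smaller network's edges found in both

    @property
    def table(self) -> tuple[int, int, int, int]:
        return self.both, self.a_only, self.b_only, self.neither


def _overlap_from_counts(
    n_shared: int, both: int, a_only: int, b_only: int
) -> OverlapTest:
    total_pairs = n_shared * (n_shared - 1) // 2
    neither = total_pairs - both - a_only - b_only
    if neither < 0:
        raise ValueError("edge counts exceed the number of possible pairs")
    # one-sided enrichment: P(X >= both) for hypergeometric with
    # population = all pairs, successes = edges of A, draws = edges of B
    k_a = both + a_only
    k_b = both + b_only
    log_p = hypergeom.logsf(both - 1, total_pairs, k_a, k_b) / math.log(10)
    smaller = min(k_a, k_b)
    frac = both / smaller if smaller else 0.0
    return OverlapTest(
        n_shared_genes=n_shared,
        both=both,
        a_only=a_only,
        b_only=b_only,
        neither=neither,
        log10_p=float(log_p),
        shared_edge_fraction=frac,
    )


def network_overlap_test(
    net_a: FunctionalNetwork | None = None,
    net_b: FunctionalNetwork | None = None,
    *,
    counts: Optional[tuple[int, int, int, int]] = None,
) -> OverlapTest:
    """Fisher exact test for edge overlap between two networks.

    Both networks are restricted to their shared genes; cells count pairs
    with an edge in both, in one only, or in neither (possible pairs minus
    the rest).  The one-sided p-value is computed in log space, so
    arbitrarily extreme enrichment reports a finite log10 p.  Alternatively
    pass precomputed ``counts = (n_shared_genes, both, a_only, b_only)``.
    """
    if counts is not None:
        return _overlap_from_counts(*counts)
    if net_a is None or net_b is None:
        raise ValueError("provide two networks or precomputed counts")
    shared = net_a.nodes & net_b.nodes
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes between networks")
    edges_a = {
        (min(a, b), max(a, b))
        for a, b, _ in net_a.edges()
        if a in shared and b in shared
    }
    edges_b = {
        (min(a, b), max(a, b))
        for a, b, _ in net_b.edges()
        if a in shared and b in shared
    }
    both = len(edges_a & edges_b)
    return _overlap_from_counts(
        len(shared), both, len(edges_a) - both, len(edges_b) - both
    )


@dataclass
class SubsampleSummary:
    rate: float
    edge_overlap_median: float
    edge_overlap_ci: tuple[float, float]
    gene_overlap_median: float
    gene_overlap_ci: tuple[float, float]


def subsample_robustness(
    nodelist: NodeList,
    network: FunctionalNetwork,
    rates: Sequence[float],
    n_rep: int,
    runner: Callable[[Sequence[str]], tuple[set[tuple[str, str]], set[str]]],
    rng: np.random.Generator,
) -> list[SubsampleSummary]:
    """Stability of FTI output under candidate-list subsampling.

    ``runner(genes)`` runs the FTI pipeline and returns (edge set, gene
    set).  For each rate, ``n_rep`` random subsamples of the list are run
    and the proportion of subsample-run edges (genes) also present in the
    full-run output is summarised by median and 95% quantile CI.  A rate of
    1.0 is allowed (degenerate: overlap 1).
    """
    for r in rates:
        if not (0.0 < r <= 1.0):
            raise ValueError(f"rate {r} outside (0, 1]")
    full_edges, full_genes = runner(list(nodelist))
    out = []
    genes = list(nodelist)
    for rate in rates:
        k = max(1, int(round(rate * len(genes))))
        e_overlaps, g_overlaps = [], []
        for _ in range(n_rep):
            idx = rng.choice(len(genes), size=k, replace=False)
            sub_genes = [genes[i] for i in idx]
            edges, gset = runner(sub_genes)
            e_overlaps.append(
                len(edges & full_edges) / len(edges) if edges else 1.0
            )
            g_overlaps.append(
                len(gset & full_genes) / len(gset) if gset else 1.0
            )
        e_arr, g_arr = np.array(e_overlaps), np.array(g_overlaps)
        out.append(
            SubsampleSummary(
                rate=rate,
                edge_overlap_median=float(np.median(e_arr)),
                edge_overlap_ci=tuple(np.quantile(e_arr, [0.025, 0.975])),
                gene_overlap_median=float(np.median(g_arr)),
                gene_overlap_ci=tuple(np.quantile(g_arr, [0.025, 0.975])),
            )
        )
    return out
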