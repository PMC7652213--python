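"""Functional gene network construction from pairwise evidence.

Pairwise evidence scores (e.g., a STRING-style association score and a GO
coannotation depth) are converted per source into Bayesian bin posteriors —
the probability of pathway co-membership given the score bin, estimated on
gold-standard labelled pairs — and combined by logistic regression fitted
on class-balanced training pairs.  The fitted pair probabilities are
thresholded at the F-measure-optimal value to emit a high-confidence
weighted network.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .graph_core import FunctionalNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "EvidencePairTable",
    "IntegrationModel",
    "OntologyDag",
    "read_evidence_table",
    "deepest_coannotation",
    "bin_posteriors",
    "BinPosterior",
    "balance_training",
    "fit_integration",
    "select_threshold",
    "emit_network",
]


# ---------------------------------------------------------------------------
# Ontology


class OntologyDag:
    """Minimal is_a ontology: terms with parents, a namespace tag per term
    ('process' or 'component'), and gene -> term annotations.

    Genes are treated as leaves: annotating a gene to a term implicitly
    annotates it to every ancestor of that term.  Depth of a term is the
    longest is_a path from a root.
    """

    def __init__(self) -> None:
        self.parents: dict[str, set[str]] = {}
        self.namespace: dict[str, str] = {}
        self.annotations: dict[str, set[str]] = {}
        self._depth_cache: dict[str, int] = {}

    def add_term(self, term: str, namespace: str,
                 parents: Sequence[str] = ()) -> None:
        self.parents.setdefault(term, set()).update(parents)
        self.namespace[term] = namespace
        for p in parents:
            self.parents.setdefault(p, set())
        self._depth_cache.clear()

    def annotate(self, gene: str, term: str) -> None:
        if term not in self.parents:
            raise ValueError(f"annotation references unknown term {term!r}")
        self.annotations.setdefault(gene, set()).add(term)

    @classmethod
    def from_obo(cls, path: str | Path) -> "OntologyDag":
        """Read an OBO file, keeping id, is_a links and the namespace tag."""
        import obonet

        g = obonet.read_obo(str(path))
        dag = cls()
        for term, data in g.nodes(data=True):
            raw_ns = data.get("namespace", "process")
            ns = "component" if "component" in raw_ns else "process"
            parents = [v for _, v, key in g.out_edges(term, keys=True)
                       if key == "is_a"]
            dag.add_term(term, ns, parents)
        dag._check_acyclic()
        return dag

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str, stack: list[str]) -> None:
            state[t] = 1
            for p in self.parents.get(t, ()):  # noqa: B020
                if state.get(p) == 1:
                    raise ValueError(f"ontology cycle through {p!r}")
                if p not in state:
                    visit(p, stack)
            state[t] = 2

        for term in list(self.parents):
            if term not in state:
                visit(term, [])

    def depth(self, term: str) -> int:
        """Longest is_a path from any root to the term."""
        if term in self._depth_cache:
            return self._depth_cache[term]
        ps = self.parents.get(term)
        d = 0 if not ps else 1 + max(self.depth(p) for p in ps)
        self._depth_cache[term] = d
        return d

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.parents.get(t, ()))
        return out

    def gene_terms(self, gene: str) -> set[str]:
        """All terms annotating a gene, direct or via the is_a closure."""
        out: set[str] = set()
        for t in self.annotations.get(gene, ()):  # noqa: B020
            out |= self.ancestors(t)
        return out


def deepest_coannotation(
    dag: OntologyDag, gene_a: str, gene_b: str
) -> Optional[tuple[str, int]]:
    """Deepest term annotating both genes, or None.

    Ties are broken by process-namespace precedence over component, then
    lexicographic term id.
    """
    shared = dag.gene_terms(gene_a) & dag.gene_terms(gene_b)
    if not shared:
        return None
    best = min(
        shared,
        key=lambda t: (
            -dag.depth(t),
            0 if dag.namespace.get(t) == "process" else 1,
            t,
        ),
    )
    return best, dag.depth(best)


# ---------------------------------------------------------------------------
# Evidence table


@dataclass
class EvidencePairTable:
    """Per-pair evidence scores and optional gold-standard labels.

    ``frame`` columns: ``gene_a``, ``gene_b``, one column per evidence
    source (float, NaN for missing) and ``label`` (1.0 positive, 0.0
    negative, NaN unlabelled).  Pairs are unordered-unique.
    """

    frame: pd.DataFrame
    sources: list[str]

    def __post_init__(self) -> None:
        a = self.frame["gene_a"].astype(str)
        b = self.frame["gene_b"].astype(str)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        self.frame = self.frame.assign(gene_a=lo, gene_b=hi)
        dups = self.frame.duplicated(subset=["gene_a", "gene_b"])
        if dups.any():
            logger.info("evidence table: dropping %d duplicate pairs",
                        int(dups.sum()))
            self.frame = self.frame[~dups].reset_index(drop=True)

    def labelled(self) -> pd.DataFrame:
        return self.frame[self.frame["label"].notna()]


def read_evidence_table(path: str | Path) -> EvidencePairTable:
    """TSV with gene_a, gene_b, evidence columns, and a final 'label' column
    (``positive`` / ``negative`` / empty)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b"}
    if not required <= set(df.columns):
        raise ValueError("evidence table needs gene_a and gene_b columns")
    if "label" in df.columns:
        df["label"] = df["label"].map(
            {"positive": 1.0, "negative": 0.0, 1: 1.0, 0: 0.0}
        )
    else:
        df["label"] = np.nan
    sources = [c for c in df.columns if c not in ("gene_a", "gene_b", "label")]
    return EvidencePairTable(frame=df, sources=sources)


# ---------------------------------------------------------------------------
# Bin posteriors


@dataclass
class BinPosterior:
    """Quantile-binned posterior P(co-membership | score) for one source."""

    source: str
    edges: np.ndarray        # bin edges, len n_bins + 1
    posterior: np.ndarray    # per-bin posterior, len n_bins
    prior: float             # unconditional positive rate (for missing scores)
    interpolated: np.ndarray  # bool per bin: True where no labels were seen

    def lookup(self, score: float) -> float:
        if score is None or (isinstance(score, float) and math.isnan(score)):
            return self.prior
        idx = int(np.clip(
            np.searchsorted(self.edges, score, side="right") - 1,
            0, len(self.posterior) - 1,
        ))
        return float(self.posterior[idx])

    def transform(self, scores: pd.Series) -> np.ndarray:
        return np.array([self.lookup(s) for s in scores])


def bin_posteriors(
    table: EvidencePairTable, source: str, n_bins: int = 20
) -> BinPosterior:
    """Per-bin positive posterior with add-one smoothing.

    Bins are score quantiles over all scored pairs (monotone in score);
    a bin with no labelled rows inherits the linear interpolation of its
    labelled neighbours and is flagged.
    """
    lab = table.labelled()
    lab = lab[lab[source].notna()]
    if lab.empty:
        raise ValueError(f"no labelled rows carry a {source!r} score")
    all_scores = table.frame[source].dropna().to_numpy()
    qs = np.quantile(all_scores, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    if len(edges) < 2:
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    n_eff = len(edges) - 1
    pos = np.zeros(n_eff)
    tot = np.zeros(n_eff)
    idx = np.clip(
        np.searchsorted(edges, lab[source].to_numpy(), side="right") - 1,
        0, n_eff - 1,
    )
    for i, y in zip(idx, lab["label"].to_numpy()):
        tot[i] += 1
        pos[i] += y
    posterior = np.full(n_eff, np.nan)
    seen = tot > 0
    posterior[seen] = (pos[seen] + 1.0) / (tot[seen] + 2.0)
    interpolated = ~seen
    if interpolated.any():
        logger.info("bin_posteriors[%s]: interpolating %d label-free bins",
                    source, int(interpolated.sum()))
        known = np.nonzero(seen)[0]
        posterior = np.interp(np.arange(n_eff), known, posterior[known])
    prior = float((lab["label"].sum() + 1.0) / (len(lab) + 2.0))
    return BinPosterior(
        source=source,
        edges=edges,
        posterior=posterior,
        prior=prior,
        interpolated=interpolated,
    )


# ---------------------------------------------------------------------------
# Training, integration, thresholding


def balance_training(
    table: EvidencePairTable, rng: np.random.Generator
) -> EvidencePairTable:
    """Subsample negatives uniformly to the positive count."""
    lab = table.labelled()
    pos = lab[lab["label"] == 1.0]
    neg = lab[lab["label"] == 0.0]
    if pos.empty or neg.empty:
        raise ValueError("both classes required to balance training data")
    if len(neg) < len(pos):
        raise ValueError("fewer negatives than positives; cannot balance down")
    if len(neg) == len(pos):
        frame = lab.copy()
    else:
        keep = rng.choice(len(neg), size=len(pos), replace=False)
        frame = pd.concat([pos, neg.iloc[np.sort(keep)]], ignore_index=True)
    return EvidencePairTable(frame=frame.reset_index(drop=True),
                             sources=list(table.sources))


@dataclass
class IntegrationModel:
    """Logistic integration of per-source bin posteriors into a pair
    probability, with an F-measure-selected edge threshold."""

    bins: dict[str, BinPosterior]
    intercept: float
    coefficients: dict[str, float]
    threshold: Optional[float] = None
    ridge_fallback: bool = False

    def pair_probability(self, frame: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(frame), self.intercept)
        for src, beta in self.coefficients.items():
            eta = eta + beta * self.bins[src].transform(frame[src])
        return 1.0 / (1.0 + np.exp(-eta))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "threshold": self.threshold,
            "ridge_fallback": self.ridge_fallback,
            "bins": {
                s: {
                    "edges": b.edges.tolist(),
                    "posterior": b.posterior.tolist(),
                    "prior": b.prior,
                }
                for s, b in self.bins.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def fit_logistic(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, Optional[np.ndarray], bool]:
    """ML logistic regression of y on X (constant added).

    Returns (params, standard errors, ridge_flag).  Quasi-separation or
    non-convergence falls back to a ridge-stabilised (L2) fit, for which no
    standard errors are reported.
    """
    import warnings

    Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            with np.errstate(all="ignore"):
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        separated = any(
            "eparation" in str(w.message) or "onverge" in str(w.message)
            for w in caught
        )
        params = np.asarray(res.params)
        if (
            separated
            or not res.mle_retvals.get("converged", True)
            or not np.all(np.isfinite(params))
            or np.abs(params).max() > 1e3
        ):
            raise RuntimeError("unstable fit")
        return params, np.asarray(res.bse), False
    except Exception:  # separation / non-convergence
        logger.warning("fit_logistic: ML unstable, using ridge-stabilised fit")
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=10.0, max_iter=1000)  # default L2
        clf.fit(X, y)
        return np.concatenate([clf.intercept_, clf.coef_.ravel()]), None, True


def fit_integration(
    balanced: EvidencePairTable, n_bins: int = 20
) -> IntegrationModel:
    """Maximum-likelihood logistic regression of label on bin posteriors.

    Quasi-separation falls back to a ridge-stabilised fit with a warning;
    fitted probability remains monotone increasing in each evidence
    posterior for informative sources.
    """
    lab = balanced.labelled()
    if (lab["label"] == 1).sum() < 2 or (lab["label"] == 0).sum() < 2:
        raise ValueError("need >= 2 labelled rows per class")
    bins = {s: bin_posteriors(balanced, s, n_bins=n_bins)
            for s in balanced.sources}
    X = np.column_stack([bins[s].transform(lab[s]) for s in balanced.sources])
    y = lab["label"].to_numpy()
    params, _, ridge = fit_logistic(X, y)
    return IntegrationModel(
        bins=bins,
        intercept=float(params[0]),
        coefficients={s: float(params[i + 1])
                      for i, s in enumerate(balanced.sources)},
        ridge_fallback=ridge,
    )


def select_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, dict[str, float]]:
    """Threshold maximising the F-measure over candidate observed scores.

    Candidates are the distinct observed scores (rule: predict positive at
    score >= t); ties in F go to the higher threshold (fewer false
    positives).  Returns the threshold and the metrics achieved at it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("both classes required for threshold selection")
    cands = np.unique(scores)
    if len(cands) == 1:
        logger.warning("select_threshold: all scores identical; degenerate")
        t = float(cands[0])
        tp = float(labels.sum())
        fp = float((1 - labels).sum())
        f = 2 * tp / (2 * tp + fp) if tp else 0.0
        return t, {"f_measure": f, "tpr": 1.0, "fpr": 1.0}
    best_t, best_f, best_metrics = None, -1.0, {}
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    order = np.argsort(scores)
    s_sorted = scores[order]
    y_sorted = labels[order]
    # cumulative positives below each candidate give O(n log n) sweep
    cum_pos = np.concatenate([[0.0], np.cumsum(y_sorted)])
    for t in cands:
        i = np.searchsorted(s_sorted, t, side="left")
        tp = n_pos - cum_pos[i]
        fp = (len(labels) - i) - tp
        fn = n_pos - tp
        f = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f >= best_f:  # >= keeps the higher threshold on ties
            best_f = f
            best_t = float(t)
            best_metrics = {
                "f_measure": float(f),
                "tpr": float(tp / n_pos) if n_pos else 0.0,
                "fpr": float(fp / n_neg) if n_neg else 0.0,
            }
    return best_t, best_metrics


def emit_network(
    table: EvidencePairTable, model: IntegrationModel
) -> FunctionalNetwork:
    """All pairs with fitted probability >= the model threshold, weighted by
    that probability."""
    if model.threshold is None:
        raise ValueError("model has no threshold; run select_threshold first")
    probs = model.pair_probability(table.frame)
    net = FunctionalNetwork()
    for (a, b), p in zip(
        table.frame[["gene_a", "gene_b"]].itertuples(index=False), probs
    ):
        if p >= model.threshold:
            net.add_edge(a, b, float(min(p, 1.0)))
    return net
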