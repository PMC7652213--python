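# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Model and assumptions

The functional network *G* is an undirected graph over gene identifiers
with edge weights in [0, 1] interpreted as pathway co-membership
probabilities. The method's core assumption is that functionally related
genes in a candidate list *D* occupy densely interconnected neighbourhoods
of *G*, while neutrally bound genes fall at random positions. All
inference is therefore topological: edge weights are carried through I/O
and network construction but do not enter the coherence statistics (the
only weighting is the −ln p edge weight inside the min-cut step, which is
derived from the HMC p-values, not from *G*'s weights).

### HMC edge statistic

For an edge (i, j) of the induced subgraph *S*, the candidates are all
nodes of *S* except *i* and *j*. The 2×2 table counts candidates adjacent
to both endpoints (n₁₁), to one only (n₁₀, n₀₁), and to neither (n₀₀); the
cells sum to |S|−2. The p-value is the one-sided upper tail
P(X ≥ n₁₁) of the hypergeometric distribution with population |S|−2,
success count n₁₁+n₁₀ and draw count n₁₁+n₀₁ — i.e. endpoint degrees
within *S* excluding the (i, j) edge itself. The enrichment (one-sided)
tail is deliberate; a two-sided test would also flag *depleted* shared
neighbourhoods, which are not evidence of coherence. Zero-margin tables
return p = 1. The tail is evaluated through the log survival function and
p-values are floored at 1e-300 before any logarithm.

Because every node of *S* enters the table, HMC p-values are *not*
invariant to adding disconnected nodes to the list: isolated genes enlarge
the candidate population and sharpen the enrichment of genuinely shared
neighbourhoods. This is intentional — the same effect is present in the
resampled null, which re-induces subgraphs of identical size from *G*, so
the comparison between H₁ and H₀ remains like-for-like.

### Resampled null and positive FDR

H₀ pools HMC p-values over Y uniform node resamples of size |S| from *G*.
Resampling controls for the structure of *G* (including its degree
distribution) at the observed sample size, but deliberately not for the
degree distribution of *S* itself, which carries the signal. Y defaults to
100; 1000 is available (`--Y`) and was used for the original
transcription-factor analyses.

pFDR is estimated by stepping thresholds through the sorted distinct H₁
p-values: V = #{H₀ ≤ p_α}/Y, R = #{H₁ ≤ p_α}, pFDR = min(V/R, 1), then a
running maximum enforces monotonicity (sampling noise can otherwise make
pFDR dip at thresholds that admit new H₁ edges but no new null mass). The
cap at 1 corresponds to predicting that all edges at that level are false
positives.

### Local FDR

Nodes are summarised by pFDR_min — the smallest q over incident edges, the
level at which the node first enters a thresholded network. Nodes are
grouped by distinct pFDR_min levels (after rounding to 12 significant
digits to guard against float jitter). The first level's lcFDR equals its
pFDR; each later level k with predecessor l gets

    lcFDR_k = (n·pFDR_k − (n−X)·pFDR_l) / X,

with n the cumulative node count through level k and X the count at k.
This attributes the false positives added between consecutive global
levels to the nodes entering at the later level. Level values are left
unclipped so that the telescoping identity Σ X_k·lcFDR_k = n_total·pFDR_last
holds exactly; individual levels can exceed 1 when a sparse level absorbs
many accumulated false positives, and per-node values are clipped to
[0, 1] only when averaged into the binding estimate. Nodes isolated in *S*
never receive a pFDR and are counted as fully neutral (lcFDR 1) in the
mean — isolation in the induced subgraph is precisely the signature of no
co-membership with the rest of the list.

The calibrated functional fraction is
1 − mean_lcfdr(real) / mean_lcfdr(faux), where the faux baseline is the
mean over n_calibration uniformly resampled lists of identical size. The
normalisation pins fully neutral lists at 0% functional by construction;
the unnormalised 1 − mean_lcfdr is reported alongside, and the 95% CI
comes from quantiles of the statistic across individual faux baselines.

### FTI clustering

The subgraph of edges with q ≤ Q is cut iteratively: any connected
component with density 2m/(n(n−1)) below Z is split by a global minimum
weighted cut (Stoer–Wagner), with edge weights −ln p from H₁. Sides of a
cut re-enter the queue; singletons terminate trivially; components of
fewer than three nodes are discarded at output only. "Density" is standard
graph density, making Z ∈ (0, 1] interpretable. Determinism: components
are processed in descending size order and each component is rebuilt with
nodes inserted in sorted order before the cut, which fixes the cut
returned among equal-weight alternatives; full lexicographic tie-breaking
over all minimum cuts was rejected as needing min-cut enumeration for no
behavioural gain. The robust defaults (Q, Z) = (0.120, 0.306) are the
published operating point for inputs with unknown noise; a user-supplied
noise→(Q, Z) map (fit with `evaluation.select_parameters` on their own
benchmark) is consulted when a noise estimate is available.

### FBT mixture modelling

NFCS values are fitted with 1–9 component Gaussian mixtures (full
covariance, 10 restarts, variance floor 1e-6), selected by BIC. If the
selected model is unimodal, N(0, 0.01) noise is added to the NFCS = 0
nodes and the fit repeats (GN0 fallback) — a large non-Gaussian spike at
zero can otherwise swallow the structure. Modes with mean NFCS < 0.05 are
removed (they represent edgeless nodes); if more than one mode then
remains, the lowest-mean mode is also removed. A mode's score for
elimination is its component mean.

## Synthetic benchmark

The fixture network is a planted-partition graph: by default 8 pathway
modules of 25 genes with within-module edge probability 0.35 over 2000
background genes at cross probability 0.01, weights uniform on
[0.78, 1.0] to mimic a thresholded high-confidence network. The module
count, sizes and the 5%–80%-in-5%-steps noise grid with 100 replicates per
level mirror the gold-standard design the method was originally tuned on;
the within/between densities were chosen once so that module recovery is
non-trivial (an induced pathway subgraph is far from a clique) yet
attainable, and so a full benchmark sweep runs in minutes on one CPU.

Gold-standard datasets combine pathway genes with Synthetic Neutral Target
Genes (SNTGs) resampled uniformly from the network excluding that
dataset's pathway genes. The SNTG count is round(n_path·f/(1−f)) so that f
is the fraction of the *final* list; pathway subsets are nested prefixes
of the collection's pathway order. The CC-vs-size model is per-noise-level
OLS of mean induced global clustering coefficient (mean local CC over all
nodes, zeros included — disconnected nodes matter) on log dataset size.

What the synthetic benchmark does not emulate: scale-free degree
structure, overlapping pathways, correlated noise (neutral binding is
uniform here, whereas real neutral targets may cluster near open
chromatin), and identifier-mapping loss. Passing tests demonstrate
correctness of the machinery and recovery under the planted model, not
performance on any particular organism's data.

## Evaluation machinery

MCC uses the zero-denominator → 0 convention. AUC is the rank-based
Mann–Whitney statistic with midrank ties. Parameter selection masks the
high-performing region of the (Q, Z) grid — per-subset-normalised mean MCC
(floor 0.75, level 0.95) in noise-specified mode, or the fraction of
datasets beating 75% of their own best (threshold exposed, default 0.5) in
robust mode — and returns the centre of the largest circle inscribed in
the mask, computed by Euclidean distance transform on the grid; ties break
toward larger Q then larger Z. Datasets on which no cell scores above zero
are excluded as uninformative, and an empty admissible region raises
rather than guessing. The network-overlap test restricts both networks to
shared genes and computes the one-sided hypergeometric tail in log space,
so arbitrarily extreme enrichment yields a finite log₁₀ p.

## Evidence integration

Per-source scores are binned by quantiles (20 bins by default) and each
bin's posterior P(co-membership | bin) is estimated from labelled pairs
with add-one smoothing; label-free bins interpolate linearly between
labelled neighbours and are flagged. Missing scores fall back to the
source's unconditional prior. Training balances classes by uniform
negative subsampling, then logistic regression integrates the posteriors;
perfect separation or non-convergence (detected via statsmodels warnings
and the convergence flag) triggers a ridge-stabilised fallback (L2,
C = 10). The edge threshold maximises F-measure over observed scores,
ties resolving to the higher threshold. The published reference
coefficients (−6.75, 1.03, 1.12; threshold 0.779) are shipped as
documentation of the original instance, not asserted by tests — their
printed form has a sign inconsistency (probability would decrease with
evidence), so the model is always refit by maximum likelihood with the
standard convention.

## Degenerate inputs and numerics

- Edgeless induced subgraphs yield an empty edge-score set (warned), an
  undefined lcFDR (error), and empty FTI output (valid success).
- All-zero NFCS triggers GN0 and returns an empty functional set.
- p-value floor 1e-300 before logs; hypergeometric tails via `logsf`.
- pFDR thresholds are exactly the sorted distinct H₁ p-values.
- Duplicate network rows collapse to the maximum weight with a log entry;
  self-loops and out-of-range weights are rejected with line numbers.
- All randomness flows through explicitly passed `numpy` Generators; CLI
  runs materialise and record a seed, and outputs are byte-reproducible
  given the same config.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the 50%-noise recovery at
three pathways of 25 genes over a 700-node fixture with Y = 100 and 50
replicates (sharing one null across same-sized replicates, which is exact
since the null depends only on (G, |S|, Y)), 20-seed FBT mode-recovery
simulations at 250 nodes, exhaustive HMC verification over all 2×2 tables
with cells ≤ 6, and n = 5000 pairs for logistic recovery. These sizes were
chosen as the smallest at which each property is comfortably identifiable.

## Known limitations

- The SNTG-specified (Q, Z) parameter map of the original work is not
  redistributable; users fit their own via the evaluation module, with the
  robust pair as fallback.
- lcFDR is derived from global pFDR levels only; no parametric
  mixture-density local FDR is attempted.
- Comparisons against external clustering tools (HC-PIN, MCL, NEST) are
  out of scope; only the metrics needed to score any such tool's output
  are provided.
- Identifier mapping/orthology is out of scope: gene identifiers are
  opaque case-sensitive strings and must match between network and lists.
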