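# Methods

## Model

A cell is represented by its binary detection vector `g ∈ {0,1}^G` over a
fixed, ordered gene universe (column `i` is 1 iff gene `i` has count
strictly above the detection threshold, default 0).  The network is

    z = Σ_i w_i g_i + b          (one hidden neuron)
    h = max(z, 0)                (ReLU)
    p = softmax(v·h + c)         (two output nodes: state0, state1)

fitted by minimizing class-weighted categorical cross-entropy plus an L1
penalty `λ Σ_i |w_i|` with λ = 0.01.  Class weights are the balanced
convention `n_total / (2 n_k)`, so the minority pole is not drowned out.
The reported score of a cell is the *pre-activation*,

    score = orientation · (Σ_i w_i g_i + b),

deliberately without the ReLU: the linear form keeps the score a signed,
unbounded axis that remains informative on both sides of zero.  The ReLU
matters only inside the classifier head during training.

**Orientation.**  A single hidden neuron can converge to represent either
pole, so the raw sign of `z` is arbitrary.  After training, the mean
pre-activation of state1 training cells is compared to that of state0
cells; if state1 is lower, an `orientation = −1` flag is stored (raw
parameters untouched) so that reported scores always increase toward
state1.  Every downstream consumer (weight ranking, query construction,
evaluation) uses oriented quantities.

**Why binarization.**  Presence/absence is robust across UMI platforms and
sequencing depths, removes the need for normalization or log-transforms,
and puts all genes on one scale so weights are directly comparable.  The
cost is insensitivity to expression magnitude above the detection
threshold; for state axes defined by on/off transcriptional programs this
loss is small.

## Training procedure

Seeded mini-batch Adam (learning rate 1e-3, batch size 128, β₁ = 0.9,
β₂ = 0.999), at most 100 epochs, early stopping on a 10% stratified
validation split with patience 5 and best-epoch weight restoration.  All
of these are exposed in `TrainConfig`; the defaults were chosen as the
common library defaults for shallow classifiers of this size.  Training is
fully deterministic given `(data, seed)`: initialization, the validation
split and the per-epoch shuffles all flow from one generator.

Numerical choices:

- Initialization: `w ~ U(−0.05, 0.05)`, `b = 0.01` (a small positive bias
  avoids a dead ReLU at the start), output weights `v ~ U(−√2, √2)` (the
  fan-based uniform limit for a 1→2 dense layer), `c = 0`.  A zero start
  for `v` is *not* viable: it blocks all gradient flow into `w` while the
  L1 subgradient erases the input weights, and training stalls at the
  chance plateau (cross-entropy ln 2).
- L1 handled as a subgradient with sign(0) = 0 — adequate at this scale;
  weights are driven close to, not exactly onto, zero.
- ReLU′(0) taken as 0.
- Log-probabilities clamped at 1e-12, so the loss is never NaN.
- Validation loss includes the L1 term (what the optimizer actually
  minimizes is what early stopping monitors).

## Interpretation

Oriented weights are ranked descending with lexicographic tie-break, so
the ranking is a deterministic permutation of the universe.  "Top n"
lists take only strictly positive (resp. strictly negative) weights —
zero-weight genes belong to neither side.  Defaults follow the two use
cases: top 50 per side for enrichment readouts, top 250 per side for the
drug-search query.

Over-representation uses the one-sided hypergeometric tail
`P(X ≥ overlap)` with the model's gene universe as the background
population — the only self-consistent choice, since the query genes were
drawn from exactly that axis — and Benjamini–Hochberg adjustment across
terms.

## Gene-set scoring baselines

Three baselines reproduce the standard comparison design; they are
reimplementations in the spirit of the cited tools, not bit-compatible
ports, and are named `*_like` accordingly:

- `aucell_like(expr, set, top_fraction=0.05)` — per cell, rank genes by
  descending count; score = normalized area under the set-recovery curve
  within the top 5% of ranks, in [0, 1].
- `rank_percentile_score(expr, up, down)` — mean centered rank percentile
  `(r − (G+1)/2)/(G−1)` of the up genes minus that of the down genes;
  identical up/down lists cancel to exactly 0.
- `module_score(expr, set, n_bins=24, n_ctrl=100, seed)` — set mean count
  minus the mean of bin-matched control genes (equal-frequency bins of
  dataset-mean expression; up to `n_ctrl` controls per set gene sampled
  without replacement from the gene's bin).

Rank ties are broken by gene identifier — equivalently, by column index
after sorting genes by name — which makes all three scores deterministic
*and* invariant to gene-column permutation of the input; a plain
column-index tie-break would not survive a shuffle.

## Evaluation

Separation between the two states is quantified by the two-sample
Kolmogorov–Smirnov statistic `D = sup_x |ECDF₁ − ECDF₀|` (asymptotic
two-sided p) and the ROC AUC in its Mann–Whitney form
`P(s₁ > s₀) + ½P(tie)` (midrank ties), with a seeded stratified bootstrap
percentile 95% CI (default 2000 resamples).  Both are rank statistics,
invariant under strictly increasing transforms of the score — so the
choice of pre-activation vs any monotone remap of it cannot change them.

## Connectivity drug search

The up/down query (top ±250 oriented weights) is compared to each
perturbagen signature (per-gene signed scores over a reference universe):

- **ES**: GSEA-style running sum over the signature ranked by descending
  score; hits increment ∝ |score| (weighted) or 1/t (unweighted), misses
  decrement 1/(G−t); ES = extremum of largest magnitude, in [−1, 1].
- **WTCS** (LINCS convention): `(ES_up − ES_down)/2` when the two ES have
  opposite signs, else exactly 0.  A query side absent from the reference
  falls back to the single available ES, flagged in the output.
- **raw** (classic CMap convention): unweighted KS statistics
  `a = max_j(j/t − V(j)/G)`, `b = max_j(V(j)/G − (j−1)/t)`,
  `ks = a if a ≥ b else −b`; `raw = ks_up − ks_down` when signs differ,
  else 0; a per-search scaled score divides positive raws by the maximum
  positive raw and negative raws by |minimum|, landing in [−1, 1].

The source literature names these scores without printing their formulas;
the definitions above follow the published CMap/LINCS connectivity-scoring
papers and the signatureSearch implementation.  Ranking is ascending for
reversal searches (most negative = strongest predicted reverser) and
descending for induction, ties broken by perturbagen name.  Query genes
missing from the reference universe are dropped with the coverage fraction
reported; below 10% coverage the search refuses to rank.

## Synthetic data

The generator emulates exactly the statistical structure the model
consumes: independent per-gene Bernoulli detection.  Baseline detection
probabilities are uniform on [0.01, 0.5]; a planted 50-gene up-signature
has `p₁ = p₀ + δ` in state1 and a 50-gene down-signature `p₁ = p₀ − δ`
(δ = 0.3 by default, probabilities clamped to [0.002, 0.95]); 500 cells
per state.  δ = 0.3 makes recovery reliable but not trivial — individual
signature genes are noisy detectors; only their aggregate separates the
states cleanly.  Count mode multiplies each detection by a positive
geometric count (mean 3), drawn from an independent seed stream, so
binarizing the counts reproduces the binary field bit-for-bit.

The planted truth depends only on `seed`; `replicate` draws fresh cells
from the same truth, which is how all held-out evaluations are built.
Reference databases for drug-search tests contain i.i.d. N(0, 1)
background signatures plus a planted mimicker (+3 shift on up-signature
genes, −3 on down) and reverser (mirror image).

What the generator does *not* emulate: count-depth variation, gene–gene
correlation, doublets, batch effects, ambient RNA.  Passing tests
therefore demonstrate correctness of the machinery and recoverability
under the stated detection model, not performance on any real tissue.

## Problem sizes

The test battery and the acceptance script run the reference setting
(2000 genes, 1000 cells, 50 + 2 reference signatures); training takes well
under a second there, and the complete pipeline a few seconds.  These
sizes were chosen as the smallest at which the planted-recovery and
separation properties are stable across seeds.

## Known limitations

- Exact string matching of gene symbols; no alias or case resolution —
  mismatched nomenclature between matrix and universe silently becomes
  zero columns (the coverage fraction is reported to surface this).
- Single-feature models only; no multi-task heads or transfer learning.
- Baselines are design-compatible, not output-compatible, with the tools
  they are named after.
- No FDR/tau-percentile normalization of connectivity scores across cell
  types; ranking is per signature.
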