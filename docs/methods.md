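# Methods

## Problem and approach

Cell-type annotation by label transfer: given a reference count matrix
with curated type labels and a query matrix without them, assign each
query cell a reference type.  The package learns a metric embedding in
which cells of one type concentrate around that type's *prototype* —
the arithmetic mean expression profile of its reference cells — and
then classifies queries by k-nearest-neighbor vote among embedded
reference cells.

Contrasting cells against T prototypes instead of against other cells
reduces the pair count per step from O(B²) to O(B·T).  Because T
(tens) is orders of magnitude below B (thousands), each step is cheap
and the negative-sampling problem of instance-level contrastive
learning disappears: every cell sees every negative prototype every
step.

## Loss and aggregation

Per (cell i, prototype j) pair, with Euclidean distance D in embedding
space and margin m:

    same type:   1/2 · D²
    other type:  1/2 · max(0, m − D)²

The scalar objective is the **mean over all B·T pairs** of a
mini-batch.  Summing instead of averaging would only rescale the
learning rate; the mean keeps the loss magnitude independent of T and
batch size.  The hinge gradient at exactly D = 0 for a cross-type pair
is undefined; the subgradient 0 is used (the configuration is
measure-zero and transient).

Prototypes are computed **once, in preprocessed input space**, from the
training cells, and are **re-embedded with the current weights at every
step**; cells and prototypes share a single forward pass so batch-norm
statistics are computed over their union.  The loss depends only on
pairwise distances, hence is invariant to rigid rotations of the
embedding, and is non-decreasing in m for fixed embeddings.

## Encoder and optimization

Dense(d→256) → ReLU → Dropout(0.1) → BatchNorm →
Dense(256→64) → ReLU → Dropout(0.1) → BatchNorm → Dense(64→d′), with
d′ = 16 by default.  The layer sizes form a monotone bottleneck between
the 2,000-gene input and the 16-dimensional output; all are
configurable.  Weights use fan-in-scaled symmetric uniform
initialization, batch norm starts as the identity (γ=1, β=0, running
mean 0, running variance 1, ε = 1e-5, running-stat momentum 0.1), and
dropout is inverted (scaling by 1/(1−p) at train time).

The network and its backward pass are implemented directly in NumPy:
three dense layers with two batch-norm blocks need only a handful of
matrix products, and analytic gradients are verified against finite
differences in the test suite (relative error < 1e-4; observed ~1e-10).
Optimization is Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), batch size 512, at
most 100 epochs.  Eval-mode embedding is a deterministic, row-wise pure
function of (parameters, input): dropout off, running statistics used.

**Early stopping.** Validation loss (eval mode, full validation set vs
prototypes) is computed every 2 epochs; training stops after 5
consecutive checks that fail to strictly improve the running best.  The
returned parameters are those of the best check, not the last epoch.

## Preprocessing

Order of operations: QC → split → HVG selection → gene subset →
per-cell normalization.

- **QC** (raw counts): drop cells with mitochondrial fraction > 5%
  (mito genes = id prefix "MT-", case-insensitive, configurable), then
  cells expressing < 200 genes, then genes detected in < 3 remaining
  cells.  All comparisons strict; the gene rule counts post-cell-filter
  cells.  The filter is idempotent.
- **HVG selection**: for cell total n_c and pooled gene fraction p_g,
  the analytic Pearson residual is (x − μ)/sqrt(μ + μ²/θ) with
  μ = n_c·p_g, θ = 100, clipped to ±sqrt(n_cells); genes are ranked by
  residual variance and the top 2,000 kept.  The selection matches the
  scanpy implementation of the same estimator gene-for-gene on
  simulated data (cross-checked in the tests).  By default HVGs are
  selected on the **training fold only** so the test fold cannot
  influence the gene space; `hvg_on_full=True` selects on the whole
  dataset before splitting, which is the common order in practice when
  a single dataset is split for benchmarking.
- **Normalization**: each cell scaled to 10,000 total counts, then
  log1p.  Zeros are preserved; a zero-total cell is an error (QC
  should have removed it).

## Split protocols

- **Stratified random**: per label, a seeded shuffle followed by
  contiguous slicing into 10 folds; folds 1–8 train, 9 validation, 10
  test (8:1:1 within ±1 cell per label).  Labels with < 10 cells get a
  warning and best-effort allocation.
- **Batch split**: listed test batches become the test set whole; the
  remaining cells are split 9:1 train:validation, stratified by label.
- **Unseen type**: after a stratified split, the listed types are
  removed from train and validation only, leaving the test fold intact.
  Prediction never abstains, so unseen-type cells necessarily receive a
  wrong (known) label; their embedding geometry is the object of study.

## KNN transfer

k = 10 Euclidean nearest reference neighbors, uniform votes.  Ties are
broken by the smaller summed neighbor distance, then lexicographically —
deterministic and distance-respecting.  The vote fraction
(winner votes / k) is reported per cell; low fractions flag unreliable
calls such as unseen types.

## Evaluation metrics

Implemented from contingency tables: accuracy; macro-F1 over the union
of observed classes with F1 = 0 when P + R = 0; pair-counting ARI with
the convention ARI = 1 when the chance-corrected denominator is 0; NMI
with natural-log entropies and arithmetic-mean normalization, NMI = 1
when both entropies vanish.  In the batch protocol ARI/NMI compare
**predicted vs true labels** (not an unsupervised clustering of the
embedding).  All four are cross-checked against scikit-learn on random
instances in the tests.

## Dendrograms

Type representatives (means per type, in HVG input space or in
embedding space) are joined by single linkage on their Euclidean
distance matrix.  Single linkage makes merge heights equal minimax path
distances, checked against a brute-force O(T³) implementation.  Exact
distance ties are resolved by cluster index order, which is
lexicographic for sorted label input.  Trees are exported as Newick
with branch lengths = parent height − child height.

## Synthetic data

The simulator emulates grouped scRNA-seq counts in the style of the
Splatter family: gene base means λ_g ~ Gamma(shape 0.6, rate 0.3);
per group, each gene is differentially expressed with probability 0.1,
with log-normal factor (loc 0.3, scale 0.4) inverted to its reciprocal
with probability ½; library sizes LogNormal(log 1e4, 0.25); optional
per-batch log-normal factors (loc 0.1, scale 0.1); cell expectations
are the library size times the group/batch-weighted gene proportions;
counts are Poisson around them, so margins are gamma-Poisson
overdispersed.  Group sizes use deterministic largest-remainder
rounding and batches are assigned round-robin within groups, so tests
can assert exact counts.  A hierarchical variant places types on a
nested tree and accumulates DE factors along root-to-leaf paths, making
sibling types share ancestral DE genes.

What it does **not** emulate: zero inflation/dropout beyond Poisson
sparsity, trajectory structure, cell-cycle or depth artifacts, and
real-data label noise.  Passing tests therefore demonstrate correctness
of the machinery and recoverability under a faithful generative null,
not performance on any real atlas.

## Problem sizes in tests and the acceptance script

Unit tests run on hundreds of cells.  The end-to-end checks use
6,000-cell, 2,000-gene, 10-group simulations for the stratified and
batch protocols, 4,000 cells for the unseen-type analysis and
1,600 cells for the hierarchy analysis — large enough for stable
behavior on a single CPU in minutes, and the conditions under which
the reported numbers are computed.

## Known limitations

- Prediction always returns a known label; there is no novelty
  rejection, only the vote-fraction signal.
- Batch effects are not modeled explicitly; robustness comes from the
  label-supervised objective.  Under mild simulated batch effects raw
  log-HVG KNN can already be near-perfect, leaving the embedding no
  headroom to demonstrate an advantage.
- The margin value, hidden sizes and dropout are pragmatic defaults; no
  automatic hyperparameter selection is provided (the config surface
  supports sweeps).
- Checkpoints store dense float64 weights (.npz + JSON sidecar); for a
  2,000-gene model that is ~4 MB.
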