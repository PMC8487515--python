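# Methods

## Model

The classifier is an ensemble of *flexible neural trees* (FNTs). An FNT is a
finite tree whose internal nodes ("flexible neurons") of arity m compute
`σ(Σ_j ω_j I_j + θ)` over their m children and whose leaves emit single input
features; evaluation proceeds bottom-up, and with the logistic activation the
root output lies strictly in (0, 1). Because any child slot may hold a leaf,
inputs can connect to neurons at any depth — sparse, cross-layer wiring falls
out of the grammar rather than needing a separate mechanism. The logistic
activation is the operational default; gaussian (unit centre/width) and ReLU
variants exist behind the same enum but are exercised only at unit level.

Tree *structure* is searched by grammar-guided genetic programming over the
minimal grammar generating such trees:

    Node → +m(Node, …, Node)   for m in the function set
    Node → x_i                 for i in [0, d)

with tournament selection (size 3), subtree crossover (probability 0.4),
three mutation operators (subtree replacement, leaf retargeting, arity
change; probability 0.01), and elitism 1. Tree *parameters* (all ω and θ,
flattened pre-order) are tuned by global-best PSO: velocity update
`v ← 0.7·v + 2·r1·(pbest−x) + 2·r2·(gbest−x)` with |v| ≤ 2 and positions
clamped to ±5. Each generation the incumbent best structure receives one PSO
pass (swarm 30, 50 iterations by default) and the final incumbent a longer
pass (200 iterations), realising the alternating structure/parameter loop.
Fitness is the RMSE between the tree output and 0/1 targets; elitism plus
the gbest seed particle make the best-so-far fitness non-increasing.

An M-class problem is decomposed into B = ⌈log₂M⌉ binary tasks: class c is
assigned the B-bit binary representation of c (MSB first), one tree predicts
each bit, and decoding maps a raw output vector to the nearest *valid* code
(Euclidean distance, ties to the lowest class index). For M not a power of
two the unused codes simply never win — the minimal consistent extension of
the binary decomposition, needed for 3-class problems.

A **DFNForest** cascades B-tree forests: level ℓ consumes the original
features concatenated with the raw outputs of all ℓ−1 earlier levels (width
d + (ℓ−1)·B). Depth is chosen automatically: an 80/20 stratified
train/validation split is fixed per forest, each new level's decoded
validation accuracy is recorded, training stops on the first
non-improvement, and the model keeps the depth that maximised the trace.

The **laminar ensemble** stacks `num_layers` = 4 such layers. Layer ℓ holds
`K + (ℓ−1)` DFNForests (K = 3) under arithmetic widening — the minimal
monotone widening rule; a constant-width mode exists for ablation — with the
four grammars F1 = {2,3,4}, F2 = {2,3,5}, F3 = {2,4,5}, F4 = {3,4,5}
assigned round-robin across each layer's forests. A layer's output is the
per-bit mean over its forests. After each non-final layer, samples whose
every bit lies in the confidence region [0, 0.1] ∪ [0.9, 1] exit (set Y);
the uncertain rest (set X) flow onward, and only they train the next layer.
Deeper layers see densely augmented inputs `[X0 | out_1 | … | out_{ℓ−1}]`
(each layer contributes its averaged B columns, so width grows by B per
layer independent of widening; a per-forest augmentation variant would
multiply that by the layer width and is deliberately not the default). The
final layer classifies everyone. The combined score is
`y_f = Σ ω_i y_i` with triangular weights `ω_i = i / (N(N+1)/2)` over the
traversed layers, renormalised to sum 1 for early exits — this preserves
convexity and reduces exactly to the full-weight combination when a sample
traverses all N layers. The predicted class is the decoded `y_f`.

## Preprocessing

Samples with strictly more than 20% missing genes are removed (a sample at
exactly 20% is retained). Remaining gaps are filled by k-nearest-neighbour
imputation over samples (k = 5): distance is Euclidean over mutually
observed genes scaled by d/shared so sparsely overlapping samples are not
spuriously close, only donors observed for the target gene are eligible, and
k is clamped to the available donors. Each gene is then z-scored with the
*population* variance (divide by n), so the tests can assert exact moments.
Constant genes become all-zero columns by default (`set_zero`), keeping the
feature space stable across CV folds; a `drop_gene` policy is available.
The imputation is written directly rather than delegated because the exact
rule (gene-wise mean over the k nearest samples, uniform weights, strict
donor eligibility) is part of the contract; sklearn's KNNImputer serves as
an independent cross-check on a case where the two rules coincide.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| population size / crossover / mutation | 50 / 0.4 / 0.01 | the published GP operating point |
| c1, c2 / vmax / inertia / swarm | 2, 2 / 2 / 0.7 / 30 | published swarm factors; inertia and swarm size are this package's bounded defaults |
| parameter bound | ±5 | keeps logistic pre-activations in a trainable range |
| tree depth / node cap | 5 / 200 | bounds evolution; unbounded trees add parameters faster than d ≫ n data can support |
| num_layers / K | 4 / 3 | forced ensemble depth and first-layer width |
| confidence region | [0, 0.1] ∪ [0.9, 1], final 0.5 | early-exit rule; every bit must be confident (the strictest generalisation of the scalar rule; a max-bit mode is a config option) |
| cascade validation split | 80/20 stratified | fixed per forest by a derived seed |
| max cascade levels | 8 | safety cap on the auto-depth rule |

All randomness flows from one master seed; per-component generators are
derived deterministically from (seed, component tag, index), so training,
routing and prediction are bit-reproducible.

## Synthetic data

The generator draws class-conditional Gaussians: each class receives a
random ±effect-size pattern over `n_informative` genes (default shift 2 SD),
all other genes are N(0, 1) noise, and missing cells are injected uniformly
(default 2%). A log-normal mode produces positive raw-scale values for the
preprocessing path. Defaults emulate the target regime (continuous
expression, d ≫ n, 3–4 classes, minority informative genes). It does *not*
model gene–gene correlation, batch effects, count noise, or real subtype
biology — passing tests demonstrate the machinery recovers planted signal
under the stated noise model, not performance on real tumours.

## Evaluation

Stratified 5-fold cross-validation, optionally repeated, reporting macro
precision/recall/F1 (unweighted class means; "macro" is this package's
reading of an unqualified "average", with a weighted mode available).
Deviations are reported both across folds and across repeats, and every
summary number is recomputable from the per-fold predictions stored in the
report. Learning curves subsample stratified fractions and report train and
validation accuracy per size.

## Problem sizes and budgets

Library defaults are the full budgets above. The test suite and the
acceptance script use the package's desk-scale budget (`reduced_budget()`:
population 20, 10 generations, swarm 15 with 20/60 iterations, depth 4) on
synthetic problems of n = 120–200, d = 20–50, which a single CPU handles in
a few minutes while leaving the planted 4-class structure easily learnable
(cross-validated macro F1 ≈ 0.97–0.99 at effect size 2).

## Numerical and degenerate-input choices

- Bit decisions at exactly 0.5 round to 1; decode ties go to the lowest
  class index.
- Crossover resamples swap points on depth/size violations (10 retries, then
  returns the parents); mutation returns the original on violation.
- Degenerate bit columns (all 0 or all 1) are trained anyway with a warning.
- A layer whose uncertain set has a single class trains without
  stratification; with fewer than 10 uncertain samples the stack stops
  growing and the final gate classifies the remainder; with zero uncertain
  samples remaining layers are skipped and the model is simply shallower.
- Cascade validation splits fall back to unstratified when the split is too
  small to hold every class.

## Known limitations

- Training cost grows linearly in layers × forests × cascade levels × bits;
  the full published budgets on d ≈ 3000 inputs are hours of CPU, so the
  defaults are only sensible with offline patience.
- Whether per-layer augmentation should contribute B columns (layer mean,
  the default) or B × width columns (per forest, `augment_per_forest`-style
  variant) is genuinely ambiguous; both widths are supported by
  `dense_augment`, only the default is wired into training.
- Whether parameter tuning should touch every individual or only elites each
  generation is an open design point; tuning elites only keeps the budget
  bounded at a possible cost in search quality.
- No gene selection, batch correction, or count-model normalisation is
  included; inputs are assumed to be a cleaned expression matrix.
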