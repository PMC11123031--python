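# Methods

## Problem and model

Given a metabolite feature matrix of non-negative atom-color substructure
counts (each feature tagged with its bond-inclusion level) and a map from
pathway categories to member metabolites, the package builds a single binary
classifier over metabolite–pathway *pairs*: the input is the concatenation
of one metabolite's feature vector and one pathway category's feature
vector, and the label is whether the metabolite is annotated to that
category. One model therefore serves every category, and categories are
interchangeable at prediction time — the model is not tied to a fixed label
set.

Pathway categories are represented generatively from their members: raw
member counts are summed, then converted to proportions *within each
bond-inclusion level* so categories of very different sizes become
comparable. The proportion denominator includes the focal feature (a level
totalling 10,000 with a focal count of 1,000 normalizes to 0.1).
Metabolite vectors receive the same normalization for consistency.

Assumptions worth stating: pathway vectors are computed from **all**
metabolites, including any later held out in a test split. The pathway
representation is treated as fixed domain knowledge about the category
rather than a per-split estimate; the membership labels of test pairs are
still never seen at training time, and a pathway vector is constant across
all pairs of that pathway, so it cannot leak per-pair labels. A
`pathway_features_from` argument supports the stricter train-only variant.

## Stage-by-stage choices

**Normalization.** Zero-total (entry, level) groups map to zeros, not NaN
and not a uniform vector: an entry with no substructures at a level carries
no proportional signal, and zeros keep vectors finite and comparable.
Normalized group sums are exactly 1 (or 0), and the transform is invariant
to scaling an entry's raw counts.

**De-duplication** keys on exact (bitwise) equality of normalized column
vectors, keeping the earliest column of each class. At this stage values are
rational proportions of integer counts, so exact equality is reproducible;
no tolerance is used. Applied after normalization, to pathway columns only.

**Autoencoder.** A symmetric fully connected network (input → code → input
by default; optional mirrored hidden layers), ReLU on hidden layers
including the code layer, MSE reconstruction loss, Adam mini-batches, early
stopping on a held-out 10% of rows once ≥ 20 rows are available. It is fitted
with scikit-learn's `MLPRegressor` on targets = inputs; encoding is a manual
forward pass through the encoder half. Code width is ⌊ratio × input width⌋
(default ratio 0.1). Inputs are min–max scaled per column before training;
code outputs are min–max scaled with ranges fitted on the training rows and
clipped to [0, 1] for later inputs. Encoded features carry no bond level and
are never re-normalized. Defaults (400 epochs, learning rate 1e-3, batch
32) are package choices exposed in `EncoderSpec`, tuned for nothing more
than stable convergence at test scale.

**Pair dataset.** The cross join is kept lazy: rows are (metabolite index,
pathway index) pairs and the concatenated block is materialized on demand,
so memory is linear in the two matrices, not their product. Labels are set
from the membership map; positive count always equals the number of
(metabolite, pathway) annotations.

**Splits.** Monte-Carlo CV with independent stratified splits, stratum key =
(pathway, label) so every pathway's positives appear in every test set —
required for per-pathway reporting. Test fraction defaults to 0.2
(configurable). Per-stratum test counts are `round(f·size)`, clamped to keep
both sides non-empty, then adjusted ±1 by largest fractional remainder to
hit the global test size; a size-1 stratum is an error with a remediation
hint. Split `i` uses seed `base + i`, so iterations are order-independent
and resumable.

**Balancing.** Every positive training row is duplicated
k = ⌊n_neg/n_pos⌋ times — the largest equal whole-number duplication with a
positive proportion ≤ 50%. Equal duplication keeps all positives equally
weighted; fractional top-ups would not. Test sets are never oversampled
(duplicate test rows flatter the metrics).

**Classifiers.** Gradient-boosted trees (XGBoost, `tree_method="hist"`,
single-thread for reproducibility) and a multilayer perceptron
(scikit-learn `MLPClassifier`, ReLU, Adam, sigmoid output via its binary
mode, optional early stopping). No loss re-weighting — balance is handled
upstream. Since the network has no dropout knob in this backend, L2 `alpha`
is the regularization hyperparameter. Shipped defaults are midpoints of the
search spaces and are placeholders; `tune()` is the intended selection
mechanism.

**Metrics.** Computed from the integer confusion matrix in closed form.
MCC, precision, recall and F1 all use the zero-denominator → 0 convention
(verified against scikit-learn on random prediction vectors in the tests).

**Tuning.** Seeded random search (uniform, log-uniform or categorical per
dimension). Every trial sees the same per-step split seeds, making
intermediate values comparable across trials. The pruning rule is
median-stopping: after each CV step, a trial whose running median MCC falls
below the median of completed trials' running medians at that step is
stopped (1 warm-up step, 1 startup trial). Objective = median MCC over a
trial's iterations; even counts use the mean of the two central values.

**Importance.** XGBoost *gain* (total loss reduction from splits on the
feature) is the raw score — the informative conventional choice among
gain/weight/cover. Aggregation: drop features with zero gain in every
iteration, softmax the remaining raw scores within each iteration (so
per-iteration relative importances sum to 1), then average across
iterations and rank (ties broken by name). The softmax is applied per
iteration, before averaging. Metabolite and pathway features sharing an
atom color are cross-referenced, and their mean relative importances
correlated (Pearson + Spearman; Pearson reported as NaN when one side is
constant).

## Synthetic data

The generator emulates the data model the pipeline consumes: sparse
non-negative Poisson count matrices with features grouped into
bond-inclusion levels, plus a pathway membership map. Each pathway owns a
disjoint set of signature features (disjointness makes recovery tests
unambiguous; overlap is configurable by seeding signatures manually);
members of a pathway draw its signature features at `signal_multiplier`
times the background rate. Memberships are independent Bernoulli draws per
(metabolite, pathway) — metabolites may belong to several categories — with
a deterministic fallback so no category is empty.

Defaults: 500 metabolites, 12 categories, 60 features over bond levels
{0: 12, 1: 24, 2: 24}, 4 signature features per category, membership
probability 0.1 (≈10% positive pairs, matching the imbalance of real
pathway-annotation data), signal multiplier 5, background Poisson rate 4.
The background rate reflects that a typical metabolite carries several
matches of a common atom color (e.g. 10–20 carbons at bond level 0); note
the multiplier is relative, so very sparse backgrounds also mean weak
absolute signal. With these defaults a threshold oracle that knows the
planted signature features reaches MCC ≈ 0.97 after normalization — the
planted effect is strong and unambiguous, so classifier failures indicate
pipeline defects, not noise.

What the generator does **not** emulate: the heavy-tailed, highly
correlated count distributions of real atom colors, duplicate feature
structure at KEGG scale, or chemically coherent substructures. Passing the
recovery suite therefore demonstrates that the pipeline's machinery
(normalization, pairing, balancing, training, scoring) preserves and
recovers a planted association; it does not certify real-data accuracy.

## Problem sizes

The shipped tests run the full protocol at reduced scale as the package's
own default study sizes: recovery uses 500 metabolites × 12 categories
(6,000 pairs, width 120) over 20 CV iterations per backend, 10 iterations
per point for the signal-strength monotonicity check, and smaller grids
(≈300 × 4–6) for unit-level behavior. Benchmark-scale arithmetic
(5,683 × 12 → 68,196 pairs; widths 20,090 / 2,930; 10.6% positive) is
verified structurally with matrices of those dimensions.

## Known limitations

- The autoencoder backend has no dropout and trains full-batch epochs via
  scikit-learn; very wide inputs (10⁴+ features) train slowly compared to a
  GPU implementation, though the architecture is the same.
- `run_cv` executes iterations sequentially; the per-iteration seed scheme
  makes external parallelization safe but none is built in.
- Random search explores fixed distributions; no adaptive sampler is
  provided.
- Pathway vectors from all metabolites are the protocol default (see
  above); users wanting strict train-only pathway features must pass
  `pathway_features_from` explicitly.
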