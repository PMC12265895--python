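# Methods

`ndlsdti` predicts binary drug–target interactions (DTIs) by combining
three ingredients: graph-convolutional featurization of each entity, a
heterogeneous similarity graph connecting entities, and node-dependent
local smoothing (NDLS) of features over that graph, with a gradient
boosted tree classifier on top. This note records the model, the
defaults and why, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Entity featurization

**Drugs.** A SMILES string is parsed (RDKit) into a heavy-atom graph.
Atom *i* carries the integer feature vector

    x_i = [z_i, b_i, h_i, q_i, c_i]

— atomic number, heavy-neighbour bond count, attached hydrogens, total
valence, and a 0/1 aromaticity flag. Hydrogens are implicit (they enter
only through h_i), and bond orders are not encoded: the adjacency matrix
A is binary, because a single unweighted operator feeds the graph
convolution. Features are used as raw integers and linearly projected by
the first layer; any richer encoding (one-hot, bond features) is a
deliberate non-goal.

**Targets.** An amino-acid sequence becomes a path graph (one node per
residue, edges between consecutive positions — backbone order only; no
structural input is consumed). Each residue is coded by an index
dictionary over the 20 standard amino acids in alphabetical order
(A=1 … Y=20), with code 0 reserved for anything else. A scalar code
cannot feed a linear layer meaningfully, so codes pass through a learned
embedding lookup of width 5 (matching the drug feature width) before the
first convolution. Sequences longer than 1200 residues are truncated
with a logged warning (bounded memory).

## Graph-convolution encoder

Both entity types share the architecture

    X^(k) = σ( Â X^(k-1) W^(k-1) ),   Â = D̃^{-r} (A + I) D̃^{-(1-r)}

with r = 0.5 (the canonical symmetric normalization; r = 1 gives the
row-stochastic random-walk operator), 2 layers, hidden width 64, and a
mean-pool readout to a 128-dimensional embedding per entity. Two
departures from the formula as often written:

* the nonlinearity (ReLU) is applied between layers but not after the
  final layer — a ReLU on the output would zero half the embedding
  coordinates that the training head consumes;
* drug and target encoders do not share parameters (their inputs have
  different semantics), though they share the architecture.

Embedding width 128 is the default because it is the best-performing
width in the depth/width regime this family of models operates in;
it is configurable (32–512) for dimension sweeps.

**Training.** No published objective exists for this encoder, so the
package defines one: joint supervised link prediction. A temporary
bilinear head σ(z_d^T W_h z_t + b) scores every labelled training pair;
encoders, residue-embedding table and head are optimized together with
full-batch Adam (learning rate 0.02, 60 epochs) on binary cross-entropy.
A stratified 10 % validation slice is scored every 5 epochs and the
best-validation parameters are kept; the head is then discarded and the
frozen encoders embed every entity. Because graphs here are small, the
encoder is plain NumPy with hand-written backpropagation; everything is
bitwise reproducible from one seed. A `random` encoder mode (frozen
Glorot weights) exists for fast property tests and for isolating the
contribution of graph propagation.

## Heterogeneous graph

Nodes are all drugs and all targets; the 128-dim encoder outputs are the
node features. Three edge types:

* **dd** — Tanimoto similarity of Morgan fingerprints (radius 2,
  2048 bits; the field-standard circular fingerprint);
* **tt** — Smith–Waterman local alignment similarity. Raw SW scores are
  length-dependent, so they are normalized as
  SW(a,b) / √(SW(a,a)·SW(b,b)) ∈ [0, 1]. Scoring defaults to BLOSUM62
  with affine gaps 11/1 (standard practice); a simple match/mismatch
  scheme exists for oracle tests. Alignment is delegated to Biopython's
  `PairwiseAligner` in local mode and cross-checked in the test-suite
  against an exhaustive small-instance recursion.
* **dt** — known interactions (weight 1), taken from *training*
  positives only (see leakage control).

An unthresholded similarity graph is complete, so dd/tt edges are kept
only at similarity ≥ 0.5 and additionally capped by a *mutual* top-5
rule: an edge survives only if each endpoint ranks the other among its
five most-similar neighbours (ties broken by entity id). Mutual — rather
than union — top-k is the only reading that strictly caps every node's
degree. Thresholds, k, scoring and fingerprint settings are all
configurable; nothing downstream depends on their exact values.

Similarity edges carry their similarity as weight, but propagation
binarizes all edges by default, staying closest to the single
unweighted operator of the convolution; weighted propagation is a
config switch.

## Node-dependent local smoothing

Propagation over the heterogeneous graph is parameter-free linear
smoothing: X^(k) = Â^k X, with Â built from the union of all edge types
plus self-loops (always added: they keep isolated nodes well-defined and
break bipartiteness, so the power iteration converges on every
component). The influence of node j on node i after k steps is exactly
(Â^k)_ij, and as k → ∞ each row approaches the over-smoothing limit,
which for this operator has the closed form (self-looped degrees d̃,
component volume 2m̃)

    Ĩ_ij = d̃_i^(1-r) · d̃_j^r / (2m̃)   within a component, 0 across.

The local smoothing iteration count of node i at tolerance ε is

    K(i, ε) = min { k : ‖Ĩ_i − row_i(Â^k)‖₂ < ε },

and the smoothed embedding of node i averages its propagated features
over depths 0…K(i, ε). Well-connected nodes stabilize after few steps
(small K) and stop aggregating early; peripheral nodes keep going — this
per-node depth is what counters the over-smoothing that a fixed global
depth causes.

Numerical choices: ε defaults to 0.05 (swept over {0.2, 0.1, 0.05, 0.01}
in the ablation harness, since no canonical value exists); K is capped
at k_max = 50 with a logged warning; powers are applied as repeated
sparse matrix–vector products, never materializing Â^k (the dense
matrix-power oracle is test-only); cross-component influence is exactly
zero and isolated nodes get K = 0. The vectorized LSI computation tracks
a dense n×n power matrix, which is fine at the scales this package
targets (hundreds to a few thousand nodes). A `fixed_depth` switch
replaces adaptive depths with plain Â^K X — the non-adaptive baseline
used in depth-sweep comparisons.

## Pair scoring and evaluation

A candidate pair is the concatenation [X_drug ‖ X_target] (drug block
first; 256 coordinates under the defaults) of the smoothed embeddings,
scored by a LightGBM binary classifier: 500 trees, depth 6 (63 leaves),
learning rate 0.05, subsample 0.8, max_bin 127, single-threaded and
deterministic given its seed. No canonical hyperparameters exist for
this stage; these are ordinary GBDT settings and all are exposed.

Metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), F1 = 2·P·R/(P+R) at a fixed 0.5 threshold; AUC and AUPR are
threshold-free. Ratios with zero denominators are reported as absent
(None), never as 0. Precision is TP/(TP+FP) — with TP+FN in the
denominator it would duplicate recall and F1 would collapse to recall.

**Cross-validation and leakage control.** Evaluation is pair-level
stratified k-fold (default 10). Inside each fold the whole pipeline is
refit, and the propagation graph's dt edges are rebuilt from that fold's
training positives only — a test interaction that participates in
propagation would leak label information into the very features used to
predict it. dd/tt similarity edges use no labels and are therefore
shared across folds. The removal is switchable (`remove_test_dt=False`)
to measure the optimism that transductive leakage produces.

**Imbalance.** `make_imbalanced` keeps all positives and samples exactly
ratio × positives label-0 pairs without replacement (default 1:10,
mimicking the real-world excess of non-interacting pairs), drawing from
the set's own negatives plus, optionally, unobserved cross-product
pairs.

## Synthetic benchmark

The planted world ties interactions and similarities to the same latent
clusters: drug i and target j belong to cluster (index mod
n_clusters); a pair interacts with probability p_in within a cluster and
p_out across; drugs of one cluster decorate one core scaffold with
random alkyl substituents (so within-cluster Tanimoto is high); targets
of one cluster are ~15 %-mutated copies of one ancestral sequence (so
within-cluster alignment similarity is high — the homology regime that
motivates similarity edges in the first place). The standard conditions
are 200 drugs × 100 targets, 4 clusters, p_in = 0.5, p_out = 0.02,
balanced negatives, sequence lengths 60–100.

What the benchmark emulates: cluster-structured interactions, chemically
coherent drug families, homologous protein families, balanced and 1:10
imbalanced labelling. What it does not: realistic chemistry (the
molecules are tiny decorated scaffolds), realistic protein families or
domain architecture, cold-start entities, noisy/unlabelled negatives.
Passing tests therefore demonstrate that the implementation recovers
planted relational structure and is correctly calibrated under a null
(p_in = p_out gives AUC ≈ 0.5) — not that it attains any particular
accuracy on real interaction databases.

Because interaction density under these conditions is high (each entity
has many observed training interactions), the marginal value of dd/tt
edges over the dt edges plus encoder features is small — the full graph
beats the dt-only ablation on average, but by a narrow margin, the same
direction-but-small-effect picture the edge-type ablation shows at
benchmark scale. The 1:10 imbalanced scenario uses a sparser world
(p_in = 0.1, p_out = 0.005): a dense world simply does not contain ten
negatives per positive.

## Problem sizes and reproducibility

Default study sizes (200×100 world, ~5–6 k pairs) were chosen so a full
pipeline fit takes seconds-to-tens-of-seconds on one CPU; the
cross-validated and multi-seed experiments in the test-suite and
acceptance script use those same sizes. One global seed fans out to
per-stage seeds via `SeedSequence`, so featurization, encoder training,
splitting and boosting are independently reproducible; two runs with the
same seed agree bitwise in embeddings and scores.

## Known limitations

* The encoder's training objective is this package's construction;
  other choices (contrastive, reconstruction) are plausible.
* Binary classification only: no affinities, mechanisms or binding sites.
* Pair-level random splits; cold-drug / cold-target generalization is
  out of scope.
* Similarity thresholds/top-k defaults are field-reasonable but not
  canonical; conclusions about edge ablations should be read per
  configuration.
* Negative labels are sampled non-interactions; some may be
  undiscovered positives (label noise inherent to the task).
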