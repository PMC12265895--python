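# ndlsdti

Drug–target interaction (DTI) prediction on heterogeneous similarity
graphs with **node-dependent local smoothing** (NDLS).

Predicting which small molecules bind which proteins is a bottleneck of
early drug discovery; reliable in-silico ranking of candidate pairs
narrows the space that assays must cover. Graph-based predictors exploit
not only what a drug and a target *are* (structure, sequence) but how
they *relate* (shared chemistry, homology, known interactions). Their
standard failure mode is over-smoothing: stack enough propagation steps
and all node features collapse toward a degree-determined limit. This
package implements an adaptive remedy — each node is smoothed exactly as
many steps as its own position in the graph warrants.

## The model

1. **Featurization.** Each drug SMILES becomes a heavy-atom graph with
   per-atom features `[z, b, h, q, c]` (atomic number, heavy-neighbour
   bonds, hydrogens, valence, aromaticity); each protein sequence
   becomes a chain graph of integer residue codes.
2. **Encoding.** A two-layer graph convolution
   `X^(k) = σ(Â X^(k-1) W^(k-1))`, `Â = D̃^{-r}(A+I)D̃^{-(1-r)}`
   (r = ½), with mean-pool readout gives every entity a 128-dim
   embedding; encoders are trained jointly by link prediction on the
   training pairs.
3. **Heterogeneous graph.** Drug–drug edges from Tanimoto similarity of
   Morgan fingerprints, target–target edges from normalized
   Smith–Waterman alignment, drug–target edges from *training*
   interactions only.
4. **NDLS.** With linear propagation `X^(k) = Â^k X`, the influence of
   node *j* on node *i* is `(Â^k)_ij` and converges to a closed-form
   stationary row `Ĩ_i`. Each node gets its own depth
   `K(i, ε) = min{k : ‖Ĩ_i − (Â^k)_i‖₂ < ε}` and its smoothed feature is
   the average of `X^(0)_i … X^(K_i)_i`.
5. **Scoring.** Gradient-boosted trees (LightGBM) classify concatenated
   pair embeddings `[X_drug ‖ X_target]`; evaluation reports AUC, AUPR,
   F1, sensitivity and specificity under pair-level stratified
   cross-validation with strict leakage control (test interactions never
   enter propagation).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from ndlsdti import DTIModel, PlantedWorld, generate_world

# synthetic world: 200 drugs x 100 targets in 4 latent clusters that
# drive interactions, drug chemistry and target homology simultaneously
drugs, targets, pairs = generate_world(PlantedWorld(seed=1))
model = DTIModel(drugs, targets, pairs, seed=1)
result = model.fit(test_size=0.2)
print(result.summary())
```

```
Drug-target interaction model (NDLS heterogeneous graph + GBDT)
================================================================
nodes: 300 (200 drugs, 100 targets)
edges: dd=377  tt=108  dt=2227   [variant: full]
smoothing: adaptive, K in [3, 12], median 7
pairs: 4454 train / 1114 test
----------------------------------------------------------------
held-out metrics (threshold 0.50):
  auc           0.8696
  aupr          0.8165
  f1            0.8475
  sensitivity   0.8582
  specificity   0.8330
  precision     0.8371
```

Reading: the propagation graph mixes 377 chemical-similarity, 108
homology and 2227 training-interaction edges; adaptive depths range from
3 (hub nodes, already near their stationary influence) to 12 (peripheral
nodes). Held-out AUC 0.87 means the model recovers most of the planted
cluster structure; with `p_in = p_out` (nothing to learn) the same
pipeline scores AUC ≈ 0.5.

Ablations hang off the same model object:

```python
model.fit(test_size=0.2, graph_variant="no_both")   # dt edges only
model.fit(test_size=0.2, fixed_depth=2)             # non-adaptive GCN baseline
model.cross_validate(folds=10)                      # mean ± sd per metric
```

A CLI mirrors the pipeline (`ndlsdti simulate | featurize | train |
build-graph | ndls | predict | evaluate | run | ablate`); e.g.

```bash
ndlsdti simulate --workdir w --seed 1
ndlsdti run --workdir w --seed 1      # writes metrics.json, predictions.tsv
```

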