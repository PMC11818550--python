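# Methods

This document records the modelling assumptions, parameter choices, and
numerical decisions behind `dynheter`, and the scope of the synthetic
benchmark used for validation.

## 1. Problem setting

Input: a set of drugs (SMILES), a set of proteins (residue sequences,
optionally with residue–residue contact maps in `[0,1]`), and an affinity
table of `(drug_id, protein_id, y)` records. Output: a regressor for
continuous affinity or a classifier for binary interaction.

## 2. Dataset-level dynamic heterogeneous graph

### 2.1 Similarity edges

- **Drug–drug**: Tanimoto similarity of Morgan (ECFP) fingerprints,
  radius 2, 1024 bits (512 in the desk preset). Computed with RDKit's
  fingerprint generator; the Tanimoto ratio itself is implemented in the
  package and cross-checked against RDKit in the tests. An all-zero
  fingerprint pair scores 0 with a warning.
- **Protein–protein**: global alignment score, normalized by the geometric
  mean of self-scores, `sim(a,b) = nw(a,b) / sqrt(nw(a,a)·nw(b,b))`, clipped
  to `[0,1]`. Default scoring uses Biopython's `PairwiseAligner` with
  BLOSUM62 and affine gaps (open −10, extend −1), the field convention. A
  package-authored linear-gap Needleman–Wunsch DP (`nw_score`) is provided
  and oracle-verified against exhaustive alignment enumeration; the `simple`
  scoring mode uses it directly.

Both matrices are validated to be symmetric with unit diagonal and entries
in `[0,1]`.

### 2.2 Affinity block and leakage control

The drug×protein block `B` is filled **only from training-fold records**;
entries for validation and test pairs are exactly zero, so no held-out
affinity can leak through message passing. Regression values are min–max
scaled to `[0,1]` (classification labels are used as-is).

### 2.3 Dynamic thresholding

`φ(Â)` applies `ReLU(S − w)` to the two similarity blocks only; `B` is never
thresholded. `w1` (drugs) and `w2` (proteins) are scalar `Tensor`s
initialized at 0.1 and updated by Adam together with all network weights.
The subgradient of `ReLU(S − w)` w.r.t. `w` is `−1` on surviving edges, so
the thresholds receive well-defined gradients; a finite-difference check at
tolerance 1e-4 is part of the acceptance suite. Sparsification is monotone:
raising `w` never adds edges.

### 2.4 Node features and propagation

`ψ(H) = [D | binarize(φ(Â))]`, where `D` stacks per-node content embeddings
and `binarize` is the 0/1 edge-indicator treated as a constant under
differentiation (stop-gradient). Its discontinuity is measure-zero in `w`;
gradients still flow into `w` through the edge *weights* in `φ(Â)`.
Propagation is the standard renormalized GCN rule with self-loops added
**after** thresholding:
`H' = ReLU(D̂^{-1/2}(φ(Â)+I)D̂^{-1/2} H W)`, two layers, followed by a
two-layer MLP per entity type.

## 3. Per-molecule encoders

### 3.1 Drug atom graphs

Atoms become nodes with 78-dim features (44-symbol one-hot, degree, total
hydrogens, implicit valence, aromaticity — the convention established by
GraphDTA-family models); bonds become undirected edges. Two GAT layers with
2 concatenated heads each; attention uses
`e_ij = LeakyReLU(a·[Wv_i || Wv_j])` normalized by a numerically stable
segment softmax over each receiver's neighborhood, with self-loops added
inside the layer. The drug vector concatenates the heterogeneous-branch
embedding, the GAT global average pool, and an FC projection of the ECFP
fingerprint.

### 3.2 Protein residue graphs

Residues become nodes with 29-dim features (25-symbol one-hot plus
normalized position, hydrophobicity class, charge class, polarity). Edges:
contact-map entries ≥ 0.5, or a `|i−j| ≤ 3` sequence-window fallback when no
map is given. Three GIN layers (`MLP((1+ε)v + Σ_{neighbors})`, learnable ε),
then self-attention top-k pooling: node scores come from a single-channel
symmetrically normalized graph convolution, the top `k = ⌈ratio·N⌉` nodes
are kept (ratio 0.5; 961 residues → 481), and kept features are gated by
`tanh(score)` so the scoring path receives gradients. Global average
pooling produces the graph vector, concatenated with the
heterogeneous-branch embedding.

### 3.3 Head

The concatenated pair vector passes through three FC layers
(1024 → 512 → 1 at full size; 256 → 128 → 1 in the desk preset) with ReLU
between layers; sigmoid output in classification mode. Inverted dropout is
applied during training only.

## 4. Training protocol

- Split: `⌊n/6⌋` records held out as the test set, the rest divided into 5
  CV folds; all seeded and reproducible (`make_splits`).
- Optimizer: Adam, lr 5e-4, batch size 512, MSE loss (binary cross-entropy
  with ε=1e-12 clamping for classification), default 200 epochs in the desk
  preset (the full-size configuration defaults to 4000).
- Early stopping on validation loss with patience 50 and restoration of the
  best checkpoint; training aborts with a `RuntimeError` on divergence.
- The trajectory of `(w1, w2)` is logged per epoch.
- Ablations: `no_hetero_gin` removes the heterogeneous branch;
  `no_hetero_gcn` additionally replaces GIN + pooling with plain GCN layers.
- Seeds: one integer seed expands via `np.random.SeedSequence` spawning into
  independent streams for initialization, batching, and dropout.

## 5. Metrics

- **MSE** on raw targets.
- **Concordance index** with the standard step function
  (1 / 0.5 / 0 for concordant / tied / discordant), normalized by the number
  of pairs with distinct true affinities; vectorized O(n²), oracle-verified.
- **rm²** in the Roy form `r²(1 − √(r² − r₀²))`, where `r₀²` is the
  through-origin determination coefficient (clamped to `[0, r²]` to keep the
  root real under finite precision). A variant without the square root is
  available as `formula="paper"`, since part of the DTA literature prints
  the expression that way; the Roy form is the default because it is the
  originally published statistic.
- **AUROC / AUPR** via scikit-learn in classification mode.
- Outlier analysis flags pairs with absolute error strictly above the 95th
  percentile and aggregates them by drug and by protein.

## 6. Synthetic benchmark

`generate_dataset(SyntheticSpec())` produces 20 drugs × 30 proteins
(generator seed 42). Drugs are drawn from a 55-molecule curated SMILES
library (padded with substituted variants if oversampled, with a warning).
Proteins are random sequences of length 30–60 with banded contact maps
(band 2) plus sparse long-range contacts (p = 0.05). Affinities follow a
planted similarity rule,

```
y(d, p) = 5·tanimoto(d, d_ref) + 3·nw_sim(p, p_ref) + N(0, 0.1²),
```

so a model can only fit the data by actually exploiting chemical and
sequence similarity — which is precisely what the heterogeneous branch adds.
An alternative `affinity_rule="random"` produces structure-free Gaussian
targets for null experiments.

**Scope and limits.** The generator validates the learning machinery, not
chemistry: sequences are not real proteins, contact maps are synthetic, and
the planted rule is far simpler than binding physics. Results on it
demonstrate correctness of information flow (and the ablation gap
demonstrates the value of the heterogeneous branch on similarity-structured
data), not expected performance on Davis/KIBA-scale benchmarks.

## 7. Numerical and sizing choices

- All computation is float64 NumPy via a package-authored reverse-mode
  autodiff engine (tape-based, iterative topological backward); no
  deep-learning framework is required. Gradients of every primitive are
  tested against central finite differences.
- The segment softmax subtracts per-segment maxima before exponentiation for
  stability; GCN propagation checks for non-finite values.
- The vectorized Needleman–Wunsch DP processes whole rows using a
  prefix-maximum identity for linear gap penalties.
- **Desk preset** (`ModelConfig.desk()`): embedding widths (64, 128, 32),
  FC head (256, 128, 1), 512-bit fingerprints, 200 epochs — sized by this
  package so a full training run takes ~40 s on one CPU core. The full-size
  configuration (256/1024/128 embeddings, 1024/512/1 head, 1024-bit
  fingerprints, 4000 epochs) remains available through `ModelConfig`
  defaults but is not exercised in CI.

## 8. Known limitations

- Dense adjacency throughout: fine for hundreds of entities, not for
  Davis/KIBA-scale heterogeneous graphs without sparse refactoring.
- Thresholds are global scalars; per-edge-type or per-entity thresholds are
  not implemented.
- The sequence-window fallback for proteins without contact maps encodes
  only local structure.
- CPU-only; no minibatching of the heterogeneous graph (it is recomputed
  per step, which is cheap at these sizes).
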