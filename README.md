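# dynheter

Drug–target binding-affinity prediction with a **dynamic heterogeneous
graph**: per-molecule graph neural encoders are coupled to a dataset-level
graph whose drug–drug and protein–protein similarity edges are pruned by
*learnable* thresholds trained jointly with the predictor.

## Scientific problem

Given a drug described by its SMILES string and a protein described by its
residue sequence (optionally with a contact map), predict the continuous
binding affinity `y(d, t)` (e.g. pKd) or, in classification mode, whether the
pair binds. Accurate affinity prediction narrows the experimental search
space in early-stage drug discovery.

Most graph-based predictors encode each molecule in isolation. This package
additionally models *relations between molecules*: chemically similar drugs
and homologous proteins tend to share binding behaviour, so a dataset-level
graph over all drugs and proteins lets information flow between related
entities. Because a fixed similarity cutoff is a brittle hyperparameter, the
cutoffs here are continuous parameters learned by gradient descent.

## Model

Let `S_d ∈ [0,1]^{N_d×N_d}` be Tanimoto similarities of Morgan fingerprints,
`S_p ∈ [0,1]^{N_p×N_p}` normalized Needleman–Wunsch similarities, and `B`
the (train-fold-only, min–max-scaled) affinity block. The heterogeneous
adjacency and its dynamic sparsification are

```
Â = [ S_d  B ]        φ(Â) = [ ReLU(S_d − w1)   B               ]
    [ Bᵀ  S_p ]               [ Bᵀ               ReLU(S_p − w2) ]
```

with `w1, w2` scalar parameters updated by backpropagation (the affinity
block is never thresholded). Node features are `ψ = [D | 1{φ(Â) > 0}]`
where `D` stacks each drug's ECFP fingerprint embedding and each protein's
sequence-composition embedding, and the indicator is treated as a constant
during differentiation. Two GCN layers propagate
`H' = ReLU(D̂^{-1/2}(φ(Â)+I)D̂^{-1/2} H W)`.

Per-molecule encoders:

- **Drugs** — 2-layer, 2-head GAT over the atom graph (78-dim atom
  features), global average pooling, concatenated with an ECFP projection
  and the MLP-transformed heterogeneous embedding.
- **Proteins** — 3-layer GIN over the residue graph (contact-map edges, or a
  sequence-window fallback), followed by self-attention top-k pooling that
  keeps `⌈ratio·N⌉` residues (ratio 0.5: a 961-residue graph keeps 481),
  global average pooling, concatenated with the MLP-transformed
  heterogeneous embedding.

The fused pair vector passes through a 3-layer fully connected head (linear
output for regression, sigmoid for classification). Everything — including
`w1`, `w2` — is trained end to end with Adam on MSE (or cross-entropy).

No deep-learning framework is required: the package ships a small NumPy
reverse-mode autodiff engine (`dynheter.autodiff`) whose gradients are
verified against finite differences in the test suite.

## Worked example

Generate the built-in synthetic benchmark (20 drugs × 30 proteins with
affinities planted from true chemical/sequence similarity), build similarity
matrices, and train:

```bash
dynheter synth --seed 42 --out data/
dynheter build-sim --data data/ --out data/sim/
dynheter train --data data/ --seed 0 --epochs 200 --out runs/full/
dynheter train --data data/ --seed 0 --epochs 200 --ablation no_hetero_gcn \
    --out runs/ablated/
dynheter report --metrics runs/full/metrics.json
```

Typical held-out test metrics (100 pairs, desk-sized configuration, ~40 s
per run on one CPU core):

| model            | seed | test MSE | test CI | rm²   |
|------------------|------|----------|---------|-------|
| full             | 0    | 0.0157   | 0.864   | 0.983 |
| full             | 1    | 0.0124   | 0.866   | 0.973 |
| full             | 2    | 0.0188   | 0.875   | 0.984 |
| no_hetero_gcn    | 0    | 0.0210   | 0.859   | 0.956 |
| no_hetero_gcn    | 1    | 0.0246   | 0.844   | 0.981 |
| no_hetero_gcn    | 2    | 0.0199   | 0.856   | 0.964 |

The full model beats the plain-GCN ablation (no heterogeneous branch, GIN +
pooling replaced by GCN layers) at every seed: median test MSE 0.0157 vs
0.0210.

The same workflow is available from Python:

```python
from dynheter import (SyntheticSpec, generate_dataset, drug_similarity_matrix,
                      protein_similarity_matrix, make_splits, ModelConfig, train)

drugs, proteins, table = generate_dataset(SyntheticSpec())
Sd = drug_similarity_matrix(drugs)
Sp = protein_similarity_matrix(proteins)
splits = make_splits(table, seed=42)
result = train(ModelConfig.desk(epochs=200, seed=0),
               drugs, proteins, Sd, Sp, table, splits)
print(result.report.as_dict())   # {'mse': 0.0157, 'ci': 0.864, 'rm2': 0.983, ...}
```

## Layout

- `src/dynheter/autodiff.py` — NumPy reverse-mode autodiff + Adam
- `src/dynheter/data_io.py` — records, affinity tables, splits, TSV/JSON IO
- `src/dynheter/similarity.py` — Morgan/Tanimoto, Needleman–Wunsch (own DP
  plus Biopython BLOSUM62 scoring)
- `src/dynheter/molecular_graphs.py` — atom/residue graph construction
- `src/dynheter/hetero_graph.py` — dynamic thresholding φ, features ψ, GCN
- `src/dynheter/encoders.py` — GAT, GIN, self-attention top-k pooling
- `src/dynheter/pipeline.py` — fusion, prediction head, training loop,
  outlier analysis
- `src/dynheter/synthetic.py` — synthetic dataset generator
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
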