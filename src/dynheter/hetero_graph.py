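"""Dataset-level dynamic heterogeneous drug-protein graph.

Nodes are all drugs followed by all proteins.  The assembled adjacency is
the block matrix ``[[Sd, B], [B^T, Sp]]`` where ``Sd``/``Sp`` are the
drug-drug / protein-protein similarity blocks and ``B`` holds known
drug-protein affinities.  Two learnable scalars ``w1`` and ``w2`` prune the
similarity blocks during training,

    phi(A) = [[ReLU(Sd - w1), B], [B^T, ReLU(Sp - w2)]],

so the retained edge structure is itself optimized by backpropagation; the
affinity block is never thresholded.  Node features are the type one-hot
``D`` (drug = (1,0), protein = (0,1)) concatenated with the binarized
thresholded adjacency, and propagation is the symmetric-normalized graph
convolution ``H' = ReLU(Dhat^{-1/2} (phi(A)+I) Dhat^{-1/2} H W)``.

Leakage control: ``B`` is populated from *training* records only; entries
of held-out pairs stay exactly zero unless the literal (leaky) variant is
explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat, stop_gradient
from .data_io import AffinityTable

__all__ = [
    "HeteroGraph",
    "assemble_adjacency",
    "dynamic_threshold",
    "binarize",
    "feature_matrix",
    "gcn_propagate",
    "build_affinity_block",
]


@dataclass
class HeteroGraph:
    Sd: np.ndarray       # dr x dr, entries in [0, 1]
    Sp: np.ndarray       # dp x dp, entries in [0, 1]
    B: np.ndarray        # dr x dp, nonnegative
    drug_ids: list[str]
    protein_ids: list[str]
    w1: Tensor = None  # learnable drug-block threshold
    w2: Tensor = None  # learnable protein-block threshold

    def __post_init__(self):
        dr, dp = len(self.drug_ids), len(self.protein_ids)
        self.Sd = np.asarray(self.Sd, dtype=float)
        self.Sp = np.asarray(self.Sp, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.Sd.shape != (dr, dr) or self.Sp.shape != (dp, dp) or self.B.shape != (dr, dp):
            raise ValueError("block shapes inconsistent with id lists")
        if self.Sd.min() < 0 or self.Sd.max() > 1 or self.Sp.min() < 0 or self.Sp.max() > 1:
            raise ValueError("similarity blocks must lie in [0, 1]")
        if self.B.min() < 0:
            raise ValueError("affinity block must be nonnegative")
        if self.w1 is None:
            self.w1 = Tensor(0.1, requires_grad=True)
        if self.w2 is None:
            self.w2 = Tensor(0.1, requires_grad=True)

    @property
    def dr(self) -> int:
        return len(self.drug_ids)

    @property
    def dp(self) -> int:
        return len(self.protein_ids)

    @property
    def n_nodes(self) -> int:
        return self.dr + self.dp

    def type_onehot(self) -> np.ndarray:
        """(dr+dp) x 2 indicator: drug rows (1,0), protein rows (0,1)."""
        D = np.zeros((self.n_nodes, 2))
        D[: self.dr, 0] = 1.0
        D[self.dr:, 1] = 1.0
        return D


def assemble_adjacency(Sd, B, Sp) -> Tensor:
    """Block adjacency [[Sd, B], [B^T, Sp]]."""
    Sd, B, Sp = as_tensor(Sd), as_tensor(B), as_tensor(Sp)
    dr1, dr2 = Sd.shape
    dp1, dp2 = Sp.shape
    if dr1 != dr2 or dp1 != dp2 or B.shape != (dr1, dp1):
        raise ValueError(
            f"incompatible block shapes Sd={Sd.shape}, B={B.shape}, Sp={Sp.shape}"
        )
    top = concat([Sd, B], axis=1)
    bottom = concat([B.T, Sp], axis=1)
    return concat([top, bottom], axis=0)


def dynamic_threshold(hg: HeteroGraph) -> Tensor:
    """Learnable pruning of the similarity blocks; B passes through unchanged."""
    Sd_thr = (as_tensor(hg.Sd) - hg.w1).relu()
    Sp_thr = (as_tensor(hg.Sp) - hg.w2).relu()
    return assemble_adjacency(Sd_thr, Tensor(hg.B), Sp_thr)


def binarize(phi_A: Tensor | np.ndarray) -> Tensor:
    """Indicator of nonzero entries (constant: no gradient flows through it)."""
    data = phi_A.data if isinstance(phi_A, Tensor) else np.asarray(phi_A, dtype=float)
    return Tensor((data != 0).astype(np.float64))


def feature_matrix(hg: HeteroGraph, phi_A1: Tensor | np.ndarray) -> Tensor:
    """Node features psi(H) = [D | binarized adjacency]."""
    phi_A1 = as_tensor(phi_A1)
    n = hg.n_nodes
    if phi_A1.shape != (n, n):
        raise ValueError(f"binarized adjacency shape {phi_A1.shape} != ({n}, {n})")
    return concat([Tensor(hg.type_onehot()), phi_A1], axis=1)


def gcn_propagate(H, A, W, activation: str = "relu") -> Tensor:
    """One symmetric-normalized graph-convolution layer.

    Self-loops are added internally (``A + I``) and the degree matrix is
    taken from the self-looped weighted adjacency, so every node has
    positive degree for any threshold setting.
    """
    H, A, W = as_tensor(H), as_tensor(A), as_tensor(W)
    if np.isnan(A.data).any():
        raise ValueError("adjacency contains NaN")
    n = A.shape[0]
    A_hat = A + Tensor(np.eye(n))
    deg = A_hat.sum(axis=1, keepdims=True)          # (n, 1), > 0 after self-loops
    d_inv_sqrt = deg ** -0.5
    A_norm = A_hat * d_inv_sqrt * d_inv_sqrt.T      # D^-1/2 (A+I) D^-1/2
    out = A_norm @ H @ W
    if activation == "relu":
        return out.relu()
    if activation == "none":
        return out
    raise ValueError(f"unknown activation {activation!r}")


def build_affinity_block(
    table: AffinityTable,
    drug_ids: list[str],
    protein_ids: list[str],
    train_indices: np.ndarray | None = None,
    scale: str = "minmax",
) -> np.ndarray:
    """Affinity block B from the (training subset of the) affinity table.

    ``scale="minmax"`` maps training values to [0, 1] so B is on the same
    bounded scale as the similarity blocks; ``scale="binary"`` marks known
    pairs with 1 (the classification-mode convention); ``scale="raw"``
    keeps values untouched (requires nonnegative affinities).  Pairs outside
    ``train_indices`` are left at exactly zero to avoid target leakage.
    """
    d_index = {d: i for i, d in enumerate(drug_ids)}
    p_index = {p: i for i, p in enumerate(protein_ids)}
    B = np.zeros((len(drug_ids), len(protein_ids)))
    if train_indices is None:
        train_indices = np.arange(table.n)
    subset = [table.records[i] for i in np.asarray(train_indices, dtype=int)]
    if not subset:
        return B
    vals = np.array([v for _, _, v in subset], dtype=float)
    if scale == "minmax":
        lo, hi = vals.min(), vals.max()
        span = hi - lo
        scaled = np.ones_like(vals) if span == 0 else (vals - lo) / span
    elif scale == "binary":
        scaled = np.ones_like(vals)
    elif scale == "raw":
        if vals.min() < 0:
            raise ValueError("raw scaling requires nonnegative affinities")
        scaled = vals
    else:
        raise ValueError(f"unknown scale {scale!r}")
    for (did, pid, _), v in zip(subset, scaled):
        B[d_index[did], p_index[pid]] = v
    return B
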