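"""Per-molecule graph encoders.

Drug atom graphs are encoded with graph attention (GAT) layers: each edge
(j -> i) receives a score ``e_ij = LeakyReLU(a^T [W v_i || W v_j])``,
scores are softmax-normalized over each node's neighborhood, and node
features are updated by the attention-weighted sum of transformed
neighbors, with multi-head outputs concatenated.  Isolated nodes attend to
themselves (self-loops are added inside the layer).

Protein residue graphs are encoded with graph isomorphism (GIN) layers,
``v_p' = MLP((1 + eps) v_p + sum_{q in N(p)} v_q)``, followed by
self-attention top-k pooling: a single graph convolution scores every node,
the ``ceil(ratio * N)`` best-scoring nodes are kept, their features are
gated by ``tanh(score)``, and the adjacency is restricted to the induced
submatrix.  Global average pooling turns node features into one embedding
per graph.

All encoders operate on batched disjoint unions of graphs: ``edge_index``
is a (2, E) directed index array and ``batch`` maps each node to its graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (Tensor, as_tensor, concat, gather_rows, glorot,
                       segment_softmax, segment_sum)

__all__ = [
    "GATLayerParams",
    "GINLayerParams",
    "SAGPoolParams",
    "PoolResult",
    "gat_attention",
    "gat_normalize",
    "gat_update",
    "gin_update",
    "sag_pool",
    "sag_pool_batched",
    "global_average_pool",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class GATLayerParams:
    W: list[Tensor]        # per head: (F_in, F_out)
    a_src: list[Tensor]    # per head: (F_out, 1), applied to the sender
    a_dst: list[Tensor]    # per head: (F_out, 1), applied to the receiver
    n_heads: int
    leaky_slope: float = 0.2

    @classmethod
    def init(cls, rng: np.random.Generator, f_in: int, f_out: int,
             n_heads: int = 2, leaky_slope: float = 0.2) -> "GATLayerParams":
        return cls(
            W=[glorot(rng, f_in, f_out) for _ in range(n_heads)],
            a_src=[glorot(rng, f_out, 1) for _ in range(n_heads)],
            a_dst=[glorot(rng, f_out, 1) for _ in range(n_heads)],
            n_heads=n_heads,
            leaky_slope=leaky_slope,
        )

    def parameters(self) -> list[Tensor]:
        return [*self.W, *self.a_src, *self.a_dst]


@dataclass
class GINLayerParams:
    epsilon: Tensor        # learnable scalar
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, f_in: int, f_out: int) -> "GINLayerParams":
        return cls(
            epsilon=Tensor(0.0, requires_grad=True),
            W1=glorot(rng, f_in, f_out),
            b1=Tensor(np.zeros((1, f_out)), requires_grad=True),
            W2=glorot(rng, f_out, f_out),
            b2=Tensor(np.zeros((1, f_out)), requires_grad=True),
        )

    @classmethod
    def identity(cls, dim: int) -> "GINLayerParams":
        """eps = 0 and identity MLP; used by exactness tests and oracles."""
        eye = np.eye(dim)
        zero = np.zeros((1, dim))
        return cls(Tensor(0.0), Tensor(eye), Tensor(zero), Tensor(eye), Tensor(zero))

    def mlp(self, x: Tensor) -> Tensor:
        return (x @ self.W1 + self.b1).relu() @ self.W2 + self.b2

    def parameters(self) -> list[Tensor]:
        return [self.epsilon, self.W1, self.b1, self.W2, self.b2]


@dataclass
class SAGPoolParams:
    w_score: Tensor        # (F, 1) score-convolution weight

    @classmethod
    def init(cls, rng: np.random.Generator, f_in: int) -> "SAGPoolParams":
        return cls(w_score=glorot(rng, f_in, 1))

    def parameters(self) -> list[Tensor]:
        return [self.w_score]


@dataclass
class PoolResult:
    scores: np.ndarray         # per-node importance, length N
    kept_indices: np.ndarray   # top-k node indices
    X_new: Tensor              # gated features of retained nodes
    A_new: np.ndarray          # induced adjacency submatrix
    ratio: float
    k: int


# ---------------------------------------------------------------------------
# graph attention


def gat_attention(vi, vj, W: Tensor, a: Tensor, leaky_slope: float = 0.2) -> Tensor:
    """Unnormalized attention score of neighbor j for node i.

    ``a`` has shape (2*F_out, 1); its top half weights the receiver's
    transformed features, the bottom half the sender's.
    """
    vi, vj = as_tensor(vi).reshape(1, -1), as_tensor(vj).reshape(1, -1)
    hi, hj = vi @ W, vj @ W
    return (concat([hi, hj], axis=1) @ a).leaky_relu(leaky_slope)


def gat_normalize(scores) -> Tensor:
    """Softmax over a node's neighborhood scores (vector in, vector out)."""
    scores = as_tensor(scores).reshape(-1, 1)
    shifted = scores - Tensor(np.max(scores.data))
    z = shifted.exp()
    return (z / z.sum()).reshape(-1)


def gat_update(X, edge_index: np.ndarray, params: GATLayerParams,
               activation: str = "relu") -> Tensor:
    """One multi-head GAT layer over a (batched) graph.

    ``edge_index`` holds directed (src, dst) pairs; self-loops are added
    here so isolated nodes fall back to pure self-attention.
    """
    X = as_tensor(X)
    n = X.shape[0]
    src = np.concatenate([edge_index[0], np.arange(n)])
    dst = np.concatenate([edge_index[1], np.arange(n)])
    head_outputs = []
    for h in range(params.n_heads):
        Hh = X @ params.W[h]                       # (N, F_out)
        h_src = gather_rows(Hh, src)
        h_dst = gather_rows(Hh, dst)
        e = (h_dst @ params.a_dst[h] + h_src @ params.a_src[h]).leaky_relu(params.leaky_slope)
        alpha = segment_softmax(e, dst, n)         # normalize over each receiver
        out = segment_sum(h_src * alpha, dst, n)
        head_outputs.append(out)
    out = concat(head_outputs, axis=1) if len(head_outputs) > 1 else head_outputs[0]
    return out.relu() if activation == "relu" else out


# ---------------------------------------------------------------------------
# graph isomorphism


def gin_update(X, edge_index: np.ndarray, params: GINLayerParams,
               activation: str = "relu") -> Tensor:
    """One GIN layer: MLP((1 + eps) * v + sum of neighbor features)."""
    X = as_tensor(X)
    n = X.shape[0]
    agg = segment_sum(gather_rows(X, edge_index[0]), edge_index[1], n)
    pre = X * (params.epsilon + 1.0) + agg
    out = params.mlp(pre)
    return out.relu() if activation == "relu" else out


# ---------------------------------------------------------------------------
# self-attention pooling


def _score_convolution(X: Tensor, edge_index: np.ndarray, w_score: Tensor,
                       n: int) -> Tensor:
    """Symmetric-normalized one-channel graph convolution used for scoring."""
    src = np.concatenate([edge_index[0], np.arange(n)])
    dst = np.concatenate([edge_index[1], np.arange(n)])
    deg = np.bincount(dst, minlength=n).astype(float)
    norm = 1.0 / np.sqrt(deg[src] * deg[dst])
    s_in = X @ w_score                              # (N, 1)
    return segment_sum(gather_rows(s_in, src) * Tensor(norm[:, None]), dst, n)


def sag_pool(X, A, ratio: float, params: SAGPoolParams) -> PoolResult:
    """Self-attention top-k pooling of a single graph.

    ``k = ceil(ratio * N)`` nodes with the highest score-convolution output
    are retained; their features are gated by ``tanh(score)`` and the
    adjacency is cut down to the induced submatrix ``A[kept][:, kept]``.
    Ties and equal scores resolve to the lowest node index (stable sort).
    """
    X = as_tensor(X)
    A = np.asarray(A.data if isinstance(A, Tensor) else A, dtype=float)
    n = X.shape[0]
    if n < 1 or not (0 < ratio <= 1):
        raise ValueError("need N >= 1 and 0 < ratio <= 1")
    iu, ju = np.nonzero(np.triu(A, k=1))
    edge_index = np.array([np.concatenate([iu, ju]), np.concatenate([ju, iu])],
                          dtype=np.intp).reshape(2, -1)
    s = _score_convolution(X, edge_index, params.w_score, n)
    k = int(np.ceil(ratio * n))
    order = np.argsort(-s.data[:, 0], kind="stable")
    kept = np.sort(order[:k])
    X_new = gather_rows(X, kept) * gather_rows(s, kept).tanh()
    return PoolResult(scores=s.data[:, 0].copy(), kept_indices=kept, X_new=X_new,
                      A_new=A[np.ix_(kept, kept)], ratio=ratio, k=k)


def sag_pool_batched(X, edge_index: np.ndarray, batch: np.ndarray, n_graphs: int,
                     ratio: float, params: SAGPoolParams) -> tuple[Tensor, np.ndarray]:
    """Top-k pooling applied independently within each graph of a batch.

    Returns the gated features of all retained nodes and their graph
    membership vector.
    """
    X = as_tensor(X)
    n = X.shape[0]
    s = _score_convolution(X, edge_index, params.w_score, n)
    kept_all = []
    for g in range(n_graphs):
        nodes = np.nonzero(batch == g)[0]
        k = int(np.ceil(ratio * len(nodes)))
        order = np.argsort(-s.data[nodes, 0], kind="stable")
        kept_all.append(np.sort(nodes[order[:k]]))
    kept = np.concatenate(kept_all)
    X_new = gather_rows(X, kept) * gather_rows(s, kept).tanh()
    return X_new, batch[kept]


def global_average_pool(X, batch: np.ndarray, n_graphs: int) -> Tensor:
    """Per-graph mean of node features; every graph must be non-empty."""
    X = as_tensor(X)
    counts = np.bincount(batch, minlength=n_graphs).astype(float)
    if np.any(counts == 0):
        raise ValueError("empty graph in batch")
    sums = segment_sum(X, batch, n_graphs)
    return sums * Tensor(1.0 / counts[:, None])
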