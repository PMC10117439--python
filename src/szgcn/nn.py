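"""NumPy primitives for the hierarchical graph network.

The three building blocks of each stage, with exact forward definitions:

* graph convolution  H' = ReLU(D~^{-1/2} (A + I) D~^{-1/2} H W)
* TopK pooling       y = H p / ||p||_2 ; keep the k = ceil(ratio N)
  highest-scoring nodes, gate their features by tanh(y), induce the
  subgraph adjacency
* readout            concat(columnwise max, columnwise mean)

The functional entry points (:func:`graph_conv`, :func:`topk_pool`,
:func:`readout`) are inference-only; the cached forward/backward pair
used in training lives in :mod:`szgcn.gcn`.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "normalized_adjacency",
    "graph_conv",
    "topk_pool",
    "topk_indices",
    "readout",
    "pool_size",
]


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetrically normalised adjacency with self-loops.

    S = D~^{-1/2} (A + I) D~^{-1/2}, D~_ii = sum_j (A + I)_ij.  S is
    symmetric with spectral radius at most 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a_tilde = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def graph_conv(H: np.ndarray, A: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One spectral graph-convolution layer with ReLU activation."""
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"feature dim {H.shape[1]} != weight rows {W.shape[0]}")
    if A.shape[0] != H.shape[0]:
        raise ValueError("adjacency/feature node counts differ")
    return np.maximum(normalized_adjacency(A) @ H @ W, 0.0)


def pool_size(n_nodes: int, ratio: float) -> int:
    """Survivor count k = ceil(ratio * N), clipped to [1, N]."""
    return min(max(int(math.ceil(ratio * n_nodes)), 1), n_nodes)


def topk_indices(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, descending; ties broken by
    ascending node index (deterministic)."""
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((np.arange(scores.size), -scores))
    return order[:k]


def topk_pool(
    H: np.ndarray, A: np.ndarray, p: np.ndarray, ratio: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """TopK node-selection pooling.

    Scores y = H p / ||p||_2; the k = ceil(ratio N) top-scoring nodes are
    retained (descending score, index tie-break), their feature rows gated
    by tanh(y), and the subgraph adjacency induced.

    Returns ``(H_pooled, A_pooled, selected_indices, scores)`` where
    ``scores`` is the full length-N score vector.
    """
    H = np.asarray(H, dtype=float)
    p = np.asarray(p, dtype=float)
    norm = np.linalg.norm(p)
    if norm == 0:
        raise ValueError("projection vector must be non-zero")
    y = H @ (p / norm)
    k = pool_size(H.shape[0], ratio)
    idx = topk_indices(y, k)
    h_pooled = H[idx] * np.tanh(y[idx])[:, None]
    a_pooled = np.asarray(A, dtype=float)[np.ix_(idx, idx)]
    return h_pooled, a_pooled, idx, y


def readout(H: np.ndarray) -> np.ndarray:
    """Fixed-size graph summary: columnwise max concatenated with mean."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("readout needs a non-empty node-feature matrix")
    return np.concatenate([H.max(axis=0), H.mean(axis=0)])
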