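"""Slow, explicit reference forward pass for the graph attention model.

Evaluates the attention equations node by node and pair by pair with plain
Python loops — no segment tricks, no batching — and exists solely for
validation: on small graphs the vectorised implementation in :mod:`.gat` must
reproduce these numbers to numerical precision.
"""

from __future__ import annotations

import numpy as np

from .gat import GATConfig, elu, _softmax


def _leaky(x: float, slope: float) -> float:
    return x if x > 0 else slope * x


def dense_layer(h: np.ndarray, W: np.ndarray, a: np.ndarray,
                neighbors: list[list[int]], slope: float, mode: str):
    """One attention layer on a single graph, fully looped.

    Returns the pre-activation output and ``{(head, i, j): alpha_ij}``.
    """
    K, Fin, Fh = W.shape
    N = h.shape[0]
    alphas: dict[tuple[int, int, int], float] = {}
    head_outs = []
    for k in range(K):
        hp = [h[i] @ W[k] for i in range(N)]
        out_k = np.zeros((N, Fh))
        for i in range(N):
            logits = []
            for j in neighbors[i]:
                concat = np.concatenate([hp[i], hp[j]])
                logits.append(_leaky(float(a[k] @ concat), slope))
            logits = np.array(logits)
            weights = np.exp(logits - logits.max())
            weights = weights / weights.sum()
            for j, w in zip(neighbors[i], weights):
                alphas[(k, i, j)] = float(w)
                out_k[i] += w * hp[j]
        head_outs.append(out_k)
    if mode == "concat":
        Z = np.concatenate(head_outs, axis=1)
    else:
        Z = np.mean(head_outs, axis=0)
    return Z, alphas


def dense_forward(X: np.ndarray, params: dict[str, np.ndarray],
                  config: GATConfig, undirected_edges: list[tuple[int, int]]):
    """Full forward pass on one graph [n_nodes, n_features].

    Neighborhoods include the node itself (self-loops). Returns class
    probabilities and the per-layer attention dictionaries.
    """
    N = X.shape[0]
    neighbors: list[list[int]] = [[i] for i in range(N)]
    for u, v in undirected_edges:
        neighbors[u].append(v)
        neighbors[v].append(u)
    neighbors = [sorted(set(ns)) for ns in neighbors]

    Z1, alpha1 = dense_layer(X, params["W1"], params["a1"], neighbors,
                             config.leaky_slope, "concat")
    H1 = elu(Z1)
    Z2, alpha2 = dense_layer(H1, params["W2"], params["a2"], neighbors,
                             config.leaky_slope, "average")
    H2 = elu(Z2)
    pooled = H2.mean(axis=0)
    logits = pooled @ params["Wout"] + params["bout"]
    probs = _softmax(logits[None, :])[0]
    return probs, [alpha1, alpha2]
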