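"""Scaled dot-product and multi-head attention as plain NumPy functions.

These are the mathematical reference for the encoder: ``weights =
softmax(Q K^T / sqrt(d_k))`` and ``output = weights V``; multi-head runs the
same computation per head on learned projections and concatenates.  The
trainable model in :mod:`smirtd.model` implements the identical arithmetic on
autodiff tensors; a parity test pins the two together.
"""

from __future__ import annotations

import numpy as np

__all__ = ["scaled_dot_attention", "multi_head_attention"]


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(output, weights)`` with ``weights`` row-stochastic.

    ``Q``: (Lq, d_k); ``K``: (Lk, d_k); ``V``: (Lk, d_v).
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"key width mismatch: Q has {Q.shape[-1]}, K has {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError(f"length mismatch: K has {K.shape[-2]} rows, V has {V.shape[-2]}")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(Q.shape[-1])
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ V, weights


def multi_head_attention(x: np.ndarray, params: dict[str, np.ndarray]) -> np.ndarray:
    """Multi-head self-attention on a single sequence.

    ``x``: (L, d_model).  ``params`` holds per-head projections ``Wq``, ``Wk``,
    ``Wv`` of shape (h, d_model, d_head) and the output projection ``Wo`` of
    shape (h * d_head, d_model).
    """
    x = np.asarray(x, dtype=float)
    Wq, Wk, Wv, Wo = (np.asarray(params[k], dtype=float) for k in ("Wq", "Wk", "Wv", "Wo"))
    h = Wq.shape[0]
    heads = []
    for i in range(h):
        out, _ = scaled_dot_attention(x @ Wq[i], x @ Wk[i], x @ Wv[i])
        heads.append(out)
    return np.concatenate(heads, axis=-1) @ Wo
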