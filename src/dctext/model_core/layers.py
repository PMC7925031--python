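"""Differentiable layers built from the autograd primitives.

All functions here operate on batched tensors: sequences are
(batch, time, features). The trainable network and the single-example
functional API both route through these.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .autograd import Tensor, concat, conv1d, softmax


def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """x @ W^T + b, with W stored as (out_dim, in_dim)."""
    return x @ W.T + b


def lstm_cell(x_t: Tensor, h: Tensor, c: Tensor, p: Dict[str, Tensor]) -> Tuple[Tensor, Tensor]:
    """One LSTM step on a batch. x_t: (B, e); h, c: (B, d).

    Gates read the concatenation [h_{t-1}, x_t]; candidate gate is tanh,
    the other three are sigmoid; c_t = f*c_{t-1} + i*q; h_t = o*tanh(c_t).
    """
    z = concat([h, x_t], axis=1)
    i = linear(z, p["W_i"], p["b_i"]).sigmoid()
    f = linear(z, p["W_f"], p["b_f"]).sigmoid()
    q = linear(z, p["W_q"], p["b_q"]).tanh()
    o = linear(z, p["W_o"], p["b_o"]).sigmoid()
    c_t = f * c + i * q
    h_t = o * c_t.tanh()
    return h_t, c_t


def lstm_scan(X: Tensor, p: Dict[str, Tensor], h0: Tensor | None = None,
              c0: Tensor | None = None) -> Tuple[Tensor, Tensor]:
    """Run the cell over time. X: (B, T, e) -> H, C each (B, T, d)."""
    B, T, _ = X.shape
    d = p["W_i"].shape[0]
    h = h0 if h0 is not None else Tensor(np.zeros((B, d)))
    c = c0 if c0 is not None else Tensor(np.zeros((B, d)))
    hs, cs = [], []
    for t in range(T):
        h, c = lstm_cell(X[:, t, :], h, c, p)
        hs.append(h.reshape(B, 1, d))
        cs.append(c.reshape(B, 1, d))
    return concat(hs, axis=1), concat(cs, axis=1)


def gru_cell(x_t: Tensor, h: Tensor, p: Dict[str, Tensor]) -> Tensor:
    """Standard update/reset-gate cell (baseline comparator only)."""
    z = concat([h, x_t], axis=1)
    r = linear(z, p["W_r"], p["b_r"]).sigmoid()
    u = linear(z, p["W_u"], p["b_u"]).sigmoid()
    zn = concat([r * h, x_t], axis=1)
    n = linear(zn, p["W_n"], p["b_n"]).tanh()
    return (1.0 - u) * n + u * h


def gru_scan(X: Tensor, p: Dict[str, Tensor]) -> Tensor:
    B, T, _ = X.shape
    d = p["W_r"].shape[0]
    h = Tensor(np.zeros((B, d)))
    for t in range(T):
        h = gru_cell(X[:, t, :], h, p)
    return h


def attention_pool(H: Tensor, C: Tensor, p: Dict[str, Tensor]) -> Tuple[Tensor, Tensor]:
    """Hybrid attention over an LSTM run.

    Keys are the concatenations [h_t; c_t] (shape (B, T, 2d)); scores are
    v_a^T tanh(W_a k + b); the context is the softmax-weighted sum of the
    same concatenated vectors. Returns (context (B, 2d), weights (B, T)).
    """
    B, T, d = H.shape
    keys = concat([H, C], axis=2)  # (B, T, 2d)
    hidden = (keys @ p["W_a"].T + p["b"]).tanh()  # (B, T, a)
    a = p["v_a"].shape[0]
    scores = (hidden @ p["v_a"].reshape(a, 1)).reshape(B, T)
    weights = softmax(scores, axis=1)
    context = (weights.reshape(B, T, 1) * keys).sum(axis=1)  # (B, 2d)
    return context, weights


def conv_branch(X: Tensor, kernels: Dict[int, Tensor], biases: Dict[int, Tensor],
                stride: int = 1, padding: int = 0) -> Tensor:
    """Multi-width convolution + ReLU + max-over-time, concatenated.

    X: (B, T, e) -> (B, n_maps * n_widths).
    """
    pooled = []
    for f in sorted(kernels):
        fm = conv1d(X, kernels[f], biases[f], stride=stride, padding=padding)
        pooled.append(fm.relu().max(axis=2))  # (B, n_maps)
    return concat(pooled, axis=1)


def conv_sequence(X: Tensor, kernels: Dict[int, Tensor], biases: Dict[int, Tensor]) -> Tensor:
    """Length-preserving ('same'-padded) convolution producing a feature
    sequence for series CNN->LSTM models. Widths must be odd.

    X: (B, T, e) -> (B, T, n_maps * n_widths).
    """
    seqs = []
    for f in sorted(kernels):
        if f % 2 == 0:
            raise ValueError("series conv->LSTM requires odd filter widths")
        fm = conv1d(X, kernels[f], biases[f], stride=1, padding=(f - 1) // 2)
        seqs.append(fm.relu())
    return concat(seqs, axis=1).transpose((0, 2, 1))  # (B, T, M*n_widths)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not train or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout needs a random generator")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)
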