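"""Single-example layer operations and analytic-gradient helpers.

Each operation runs the batched differentiable layers with a batch of
one and returns plain numpy, so the exact code path that training uses
is also the one exercised against the loop oracles in the test suite.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np

from . import layers
from .autograd import Tensor, concat
from .params import (
    AttentionOutput,
    AttentionParams,
    ChannelParams,
    ChannelOutput,
    ConvParams,
    GeometryError,
    HeadParams,
    LSTMParams,
    LSTMState,
    ModelOutput,
    PoolConfig,
    conv_output_length,
)

__all__ = [
    "conv_output_length",
    "convolve",
    "pool",
    "lstm_step",
    "lstm_sequence",
    "hybrid_attention",
    "channel_forward",
    "dc_forward",
    "lstm_step_grads",
    "hybrid_attention_grads",
]


def _lstm_tensors(params: LSTMParams, requires_grad: bool = False) -> Dict[str, Tensor]:
    return {name: Tensor(getattr(params, name), requires_grad=requires_grad)
            for name in ("W_i", "W_f", "W_q", "W_o", "b_i", "b_f", "b_q", "b_o")}


def _attn_tensors(params: AttentionParams, requires_grad: bool = False) -> Dict[str, Tensor]:
    return {name: Tensor(getattr(params, name), requires_grad=requires_grad)
            for name in ("W_a", "v_a", "b")}


def convolve(x: np.ndarray, params: ConvParams) -> Dict[int, np.ndarray]:
    """Multi-width 1-d convolution of an (L, K) input.

    Returns one (n_maps, L_out) feature-map bank per configured width,
    where L_out follows the closed-form output length.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("input must be an (L, K) matrix")
    L, K = x.shape
    if K != params.in_channels:
        raise ValueError(f"input has {K} channels but kernels expect {params.in_channels}")
    out: Dict[int, np.ndarray] = {}
    for f in params.widths:
        conv_output_length(L, f, params.padding, params.stride)  # validates geometry
        fm = layers.conv1d(
            Tensor(x[None]), Tensor(params.kernels[f]), Tensor(params.biases[f]),
            stride=params.stride, padding=params.padding,
        )
        out[f] = fm.data[0]
    return out


def pool(row: np.ndarray, config: PoolConfig) -> np.ndarray:
    """Windowed pooling of a 1-d feature-map row.

    Finite-exponent p-norm pooling requires non-negative inputs (apply it
    after rectification); ``max_over_time`` collapses the row to its
    single maximum.
    """
    row = np.asarray(row, dtype=float)
    n = row.shape[0]
    if n == 0:
        raise GeometryError("cannot pool an empty row")
    if config.mode == "max_over_time":
        return np.array([row.max()])
    if config.window > n:
        raise GeometryError(f"pooling window {config.window} exceeds row length {n}")
    starts = np.arange(0, n - config.window + 1, config.stride)
    windows = np.stack([row[s:s + config.window] for s in starts])
    if config.mode == "average":
        return windows.mean(axis=1)
    if config.mode == "max" or math.isinf(config.exponent):
        return windows.max(axis=1)
    if np.any(windows < 0):
        raise ValueError("finite-exponent p-norm pooling requires non-negative inputs")
    p = config.exponent
    return (windows ** p).sum(axis=1) ** (1.0 / p)


def lstm_step(x_t: np.ndarray, state: LSTMState, params: LSTMParams) -> LSTMState:
    """One LSTM cell update for a single example."""
    x_t = np.asarray(x_t, dtype=float)
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(state.h)) and np.all(np.isfinite(state.c))):
        raise FloatingPointError("non-finite LSTM inputs")
    h, c = layers.lstm_cell(
        Tensor(x_t[None]), Tensor(state.h[None]), Tensor(state.c[None]),
        _lstm_tensors(params),
    )
    return LSTMState(h=h.data[0], c=c.data[0])


def lstm_sequence(X: np.ndarray, params: LSTMParams,
                  h0: np.ndarray | None = None,
                  c0: np.ndarray | None = None) -> Tuple[np.ndarray, np.ndarray]:
    """Unrolled LSTM over a (T, e) sequence; returns full (T, d) H and C."""
    X = np.asarray(X, dtype=float)
    d = params.hidden_dim
    if X.shape[0] == 0:
        return np.zeros((0, d)), np.zeros((0, d))
    h0_t = None if h0 is None else Tensor(np.asarray(h0, dtype=float)[None])
    c0_t = None if c0 is None else Tensor(np.asarray(c0, dtype=float)[None])
    H, C = layers.lstm_scan(Tensor(X[None]), _lstm_tensors(params), h0_t, c0_t)
    return H.data[0], C.data[0]


def hybrid_attention(H: np.ndarray, C: np.ndarray,
                     params: AttentionParams) -> AttentionOutput:
    """Attention over concatenated hidden/cell states of one sequence."""
    H = np.asarray(H, dtype=float)
    C = np.asarray(C, dtype=float)
    if H.shape[0] == 0:
        raise ValueError("attention over an empty sequence is undefined")
    if H.shape != C.shape:
        raise ValueError("H and C must have congruent shapes")
    p = _attn_tensors(params)
    context, weights = layers.attention_pool(Tensor(H[None]), Tensor(C[None]), p)
    keys = np.concatenate([H, C], axis=1)
    scores = np.tanh(keys @ params.W_a.T + params.b) @ params.v_a
    return AttentionOutput(scores=scores, weights=weights.data[0], context=context.data[0])


def channel_forward(embedded: np.ndarray, params: ChannelParams) -> ChannelOutput:
    """One channel: parallel conv branch and attention-pooled LSTM branch.

    conv branch = convolve -> ReLU -> max-over-time per map, widths
    concatenated; recurrent branch = LSTM -> hybrid-attention context;
    the two parts are concatenated into the fused channel output.
    """
    embedded = np.asarray(embedded, dtype=float)
    T = embedded.shape[0]
    if T < max(params.conv.widths):
        raise GeometryError(f"sequence length {T} shorter than widest filter")
    maps = convolve(embedded, params.conv)
    conv_part = np.concatenate([
        np.array([pool(np.maximum(maps[f][m], 0.0), PoolConfig(mode="max_over_time"))[0]
                  for m in range(maps[f].shape[0])])
        for f in params.conv.widths
    ])
    H, C = lstm_sequence(embedded, params.lstm)
    att = hybrid_attention(H, C, params.attn)
    return ChannelOutput(conv_part=conv_part, recurrent_part=att.context)


def dc_forward(word_ids: np.ndarray, char_ids: np.ndarray,
               word_matrix: np.ndarray, char_matrix: np.ndarray,
               word_params: ChannelParams, char_params: ChannelParams,
               head: HeadParams) -> ModelOutput:
    """Double-channel forward pass for a single encoded example.

    The char-channel output is concatenated before the word-channel
    output, the fused vector passes through a rectified dense layer and
    a softmax class head. Inference only — dropout never applies here.
    """
    word_ids = np.asarray(word_ids, dtype=np.int64)
    char_ids = np.asarray(char_ids, dtype=np.int64)
    if word_ids.size == 0 or char_ids.size == 0:
        raise ValueError("both id sequences must be non-empty")
    c_out = channel_forward(char_matrix[char_ids], char_params).fused
    w_out = channel_forward(word_matrix[word_ids], word_params).fused
    hidden = np.concatenate([c_out, w_out])
    if head.out_W.shape[0] != head.out_b.shape[0]:
        raise ValueError("class head weight/bias disagree on class count")
    dense = np.maximum(head.dense_W @ hidden + head.dense_b, 0.0)
    logits = head.out_W @ dense + head.out_b
    shifted = logits - logits.max()
    e = np.exp(shifted)
    return ModelOutput(hidden=hidden, dense=dense, probs=e / e.sum())


# -- analytic gradients (used by the finite-difference contract) -------

def lstm_step_grads(x_t: np.ndarray, state: LSTMState, params: LSTMParams,
                    d_h: np.ndarray, d_c: np.ndarray) -> Dict[str, np.ndarray]:
    """Gradients of <d_h, h_t> + <d_c, c_t> w.r.t. every cell parameter."""
    p = _lstm_tensors(params, requires_grad=True)
    h, c = layers.lstm_cell(
        Tensor(np.asarray(x_t, dtype=float)[None]),
        Tensor(np.asarray(state.h, dtype=float)[None]),
        Tensor(np.asarray(state.c, dtype=float)[None]), p)
    obj = (h * Tensor(np.asarray(d_h)[None])).sum() + (c * Tensor(np.asarray(d_c)[None])).sum()
    obj.backward()
    return {name: t.grad for name, t in p.items()}


def hybrid_attention_grads(H: np.ndarray, C: np.ndarray, params: AttentionParams,
                           d_context: np.ndarray) -> Dict[str, np.ndarray]:
    """Gradients of <d_context, context> w.r.t. W_a, v_a, b."""
    p = _attn_tensors(params, requires_grad=True)
    context, _ = layers.attention_pool(
        Tensor(np.asarray(H, dtype=float)[None]),
        Tensor(np.asarray(C, dtype=float)[None]), p)
    obj = (context * Tensor(np.asarray(d_context)[None])).sum()
    obj.backward()
    return {name: t.grad for name, t in p.items()}
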