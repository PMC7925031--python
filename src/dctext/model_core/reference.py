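"""Explicit-loop reference implementations of every layer.

These deliberately avoid vectorization, shared code with the production
path, and the autograd engine: each function transcribes its defining
formula with plain Python loops over scalars so the two routes can be
compared in tests. They are far too slow for training and exist only as
oracles.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np

from .params import (
    AttentionOutput,
    AttentionParams,
    ChannelParams,
    ConvParams,
    HeadParams,
    LSTMParams,
    LSTMState,
    ModelOutput,
    PoolConfig,
)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def convolve_ref(x: np.ndarray, params: ConvParams) -> Dict[int, np.ndarray]:
    """Nested-loop convolution: out[m, j] = sum_k sum_y x[s0*j + y, k] * w[m, y, k] + b[m]."""
    L, K = x.shape
    s0, p = params.stride, params.padding
    padded = np.zeros((L + 2 * p, K))
    padded[p:p + L] = x
    out: Dict[int, np.ndarray] = {}
    for f in params.widths:
        w = params.kernels[f]
        b = params.biases[f]
        M = w.shape[0]
        L_out = (L + 2 * p - f) // s0 + 1
        fm = np.zeros((M, L_out))
        for m in range(M):
            for j in range(L_out):
                acc = 0.0
                for y in range(f):
                    for k in range(K):
                        acc += padded[s0 * j + y, k] * w[m, y, k]
                fm[m, j] = acc + b[m]
        out[f] = fm
    return out


def pool_ref(row: np.ndarray, config: PoolConfig) -> np.ndarray:
    """Windowed pooling by direct evaluation of the p-norm / mean / max."""
    row = np.asarray(row, dtype=float)
    n = row.shape[0]
    if config.mode == "max_over_time":
        best = row[0]
        for v in row[1:]:
            if v > best:
                best = v
        return np.array([best])
    f, s0 = config.window, config.stride
    n_out = (n - f) // s0 + 1
    out = np.zeros(n_out)
    for j in range(n_out):
        window = row[s0 * j:s0 * j + f]
        if config.mode == "average":
            out[j] = sum(window) / f
        elif config.mode == "max" or (config.mode == "pnorm" and math.isinf(config.exponent)):
            out[j] = max(window)
        else:
            out[j] = sum(v ** config.exponent for v in window) ** (1.0 / config.exponent)
    return out


def lstm_step_ref(x_t: np.ndarray, state: LSTMState, params: LSTMParams) -> LSTMState:
    """Coordinate-by-coordinate LSTM step."""
    d = params.hidden_dim
    z = np.concatenate([state.h, x_t])
    h_new = np.zeros(d)
    c_new = np.zeros(d)
    for k in range(d):
        i_k = _sigmoid(float(np.dot(params.W_i[k], z)) + params.b_i[k])
        f_k = _sigmoid(float(np.dot(params.W_f[k], z)) + params.b_f[k])
        q_k = math.tanh(float(np.dot(params.W_q[k], z)) + params.b_q[k])
        o_k = _sigmoid(float(np.dot(params.W_o[k], z)) + params.b_o[k])
        c_new[k] = f_k * state.c[k] + i_k * q_k
        h_new[k] = o_k * math.tanh(c_new[k])
    return LSTMState(h=h_new, c=c_new)


def lstm_sequence_ref(X: np.ndarray, params: LSTMParams,
                      h0: np.ndarray | None = None,
                      c0: np.ndarray | None = None) -> Tuple[np.ndarray, np.ndarray]:
    d = params.hidden_dim
    state = LSTMState(
        h=np.zeros(d) if h0 is None else np.array(h0, dtype=float),
        c=np.zeros(d) if c0 is None else np.array(c0, dtype=float),
    )
    H, C = [], []
    for t in range(X.shape[0]):
        state = lstm_step_ref(X[t], state, params)
        H.append(state.h.copy())
        C.append(state.c.copy())
    if not H:
        return np.zeros((0, d)), np.zeros((0, d))
    return np.stack(H), np.stack(C)


def hybrid_attention_ref(H: np.ndarray, C: np.ndarray,
                         params: AttentionParams) -> AttentionOutput:
    """Loop transcription of score, softmax and weighted sum."""
    T = H.shape[0]
    a = params.v_a.shape[0]
    scores = np.zeros(T)
    for i in range(T):
        key = np.concatenate([H[i], C[i]])
        acc = 0.0
        for r in range(a):
            acc += params.v_a[r] * math.tanh(float(np.dot(params.W_a[r], key)) + params.b[r])
        scores[i] = acc
    m = max(scores)
    exps = [math.exp(s - m) for s in scores]
    total = sum(exps)
    weights = np.array([e / total for e in exps])
    context = np.zeros(2 * H.shape[1])
    for j in range(T):
        context += weights[j] * np.concatenate([H[j], C[j]])
    return AttentionOutput(scores=scores, weights=weights, context=context)


def channel_forward_ref(embedded: np.ndarray, params: ChannelParams):
    conv_maps = convolve_ref(embedded, params.conv)
    pooled = []
    for f in params.conv.widths:
        fm = np.maximum(conv_maps[f], 0.0)
        for m in range(fm.shape[0]):
            pooled.append(pool_ref(fm[m], PoolConfig(mode="max_over_time"))[0])
    conv_part = np.array(pooled)
    H, C = lstm_sequence_ref(embedded, params.lstm)
    att = hybrid_attention_ref(H, C, params.attn)
    return np.concatenate([conv_part, att.context])


def _softmax_ref(v: np.ndarray) -> np.ndarray:
    m = max(v)
    e = np.array([math.exp(x - m) for x in v])
    return e / e.sum()


def dc_forward_ref(word_ids: np.ndarray, char_ids: np.ndarray,
                   word_matrix: np.ndarray, char_matrix: np.ndarray,
                   word_params: ChannelParams, char_params: ChannelParams,
                   head: HeadParams) -> ModelOutput:
    """Full forward composition through the reference layers (no dropout)."""
    word_emb = np.stack([word_matrix[i] for i in word_ids])
    char_emb = np.stack([char_matrix[i] for i in char_ids])
    c_out = channel_forward_ref(char_emb, char_params)
    w_out = channel_forward_ref(word_emb, word_params)
    hidden = np.concatenate([c_out, w_out])
    dense = np.maximum(head.dense_W @ hidden + head.dense_b, 0.0)
    logits = head.out_W @ dense + head.out_b
    return ModelOutput(hidden=hidden, dense=dense, probs=_softmax_ref(logits))
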