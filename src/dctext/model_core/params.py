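"""Parameter containers and configuration for the classifier layers."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

ARCHITECTURES = (
    "dc_lstm",
    "cnn",
    "lstm",
    "cnn_lstm",
    "gru",
    "word_only_dc",
    "char_only_dc",
)


class GeometryError(ValueError):
    """Raised when a convolution/pooling geometry is unsatisfiable."""


def conv_output_length(L: int, f: int, p: int, s0: int) -> int:
    """Closed-form length of a strided, padded 1-d convolution output.

    Returns floor((L + 2p - f)/s0) + 1 and rejects geometries where the
    kernel does not fit even once.
    """
    if L < 1 or f < 1 or s0 < 1 or p < 0:
        raise GeometryError(f"invalid geometry L={L}, f={f}, p={p}, s0={s0}")
    if L + 2 * p < f:
        raise GeometryError(f"kernel width {f} exceeds padded length {L + 2 * p}")
    return (L + 2 * p - f) // s0 + 1


@dataclass
class ConvParams:
    """One kernel bank per filter width, plus shared stride/padding."""

    kernels: Dict[int, np.ndarray]  # width -> (n_maps, width, in_channels)
    biases: Dict[int, np.ndarray]  # width -> (n_maps,)
    stride: int = 1
    padding: int = 0

    @property
    def widths(self) -> Tuple[int, ...]:
        return tuple(sorted(self.kernels))

    @property
    def n_maps(self) -> int:
        return next(iter(self.kernels.values())).shape[0]

    @property
    def in_channels(self) -> int:
        return next(iter(self.kernels.values())).shape[2]

    def __post_init__(self):
        for f, k in self.kernels.items():
            if k.shape[1] != f:
                raise ValueError(f"kernel registered under width {f} has width {k.shape[1]}")
            if self.biases[f].shape != (k.shape[0],):
                raise ValueError(f"bias for width {f} must have one entry per map")


@dataclass
class PoolConfig:
    """Pooling mode: p-norm over windows, average, max, or max-over-time."""

    mode: str = "max_over_time"  # pnorm | average | max | max_over_time
    window: int = 2
    stride: int = 2
    exponent: float = math.inf

    def __post_init__(self):
        if self.mode not in ("pnorm", "average", "max", "max_over_time"):
            raise ValueError(f"unknown pooling mode {self.mode!r}")
        if self.mode == "pnorm" and not (self.exponent >= 1):
            raise ValueError("p-norm pooling requires exponent >= 1")


@dataclass
class LSTMParams:
    """Gate weights applied to the concatenation [h_{t-1}, x_t]."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_q: np.ndarray
    W_o: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_q: np.ndarray
    b_o: np.ndarray

    @property
    def hidden_dim(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_i.shape[1] - self.W_i.shape[0]

    def __post_init__(self):
        shape = self.W_i.shape
        for name in ("W_f", "W_q", "W_o"):
            if getattr(self, name).shape != shape:
                raise ValueError("all four gate matrices must share one shape")
        for name in ("b_i", "b_f", "b_q", "b_o"):
            if getattr(self, name).shape != (shape[0],):
                raise ValueError("gate biases must have length d")


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray


@dataclass
class AttentionParams:
    """Score parameters: e_i = v_a^T tanh(W_a h_i + b) over h_i = [h'_i; c_i]."""

    W_a: np.ndarray  # (a, 2d)
    v_a: np.ndarray  # (a,)
    b: np.ndarray  # (a,)

    def __post_init__(self):
        a = self.W_a.shape[0]
        if self.v_a.shape != (a,) or self.b.shape != (a,):
            raise ValueError("v_a and b must have length equal to W_a's row count")


@dataclass
class AttentionOutput:
    scores: np.ndarray  # (T,)
    weights: np.ndarray  # (T,), non-negative, sums to 1
    context: np.ndarray  # (2d,) convex combination of [h'_t; c_t]


@dataclass
class ChannelOutput:
    conv_part: np.ndarray
    recurrent_part: np.ndarray

    @property
    def fused(self) -> np.ndarray:
        return np.concatenate([self.conv_part, self.recurrent_part])


@dataclass
class HeadParams:
    """Fully connected layer followed by the class-logit layer."""

    dense_W: np.ndarray  # (dense_dim, in_dim)
    dense_b: np.ndarray
    out_W: np.ndarray  # (n_classes, dense_dim)
    out_b: np.ndarray


@dataclass
class ChannelParams:
    conv: ConvParams
    pool: PoolConfig
    lstm: LSTMParams
    attn: AttentionParams


@dataclass
class ModelOutput:
    hidden: np.ndarray  # fused channel outputs
    dense: np.ndarray  # post-activation dense layer
    probs: np.ndarray  # softmax class probabilities


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the published configuration."""

    arch: str = "dc_lstm"
    n_classes: int = 2
    word_vocab_size: int = 2
    char_vocab_size: int = 2
    embed_dim: int = 300
    widths: Tuple[int, ...] = (3, 5, 7)
    n_maps: int = 150
    lstm_dim: int = 128
    attn_dim: Optional[int] = None  # defaults to lstm_dim
    dense_dim: int = 200
    dropout: float = 0.25
    max_word_len: int = 64
    max_char_len: int = 128
    embeddings_trainable: bool = True

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.arch!r}; choose from {ARCHITECTURES}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def attention_dim(self) -> int:
        return self.attn_dim if self.attn_dim is not None else self.lstm_dim

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["widths"] = list(self.widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "widths" in d:
            d["widths"] = tuple(d["widths"])
        return cls(**d)
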