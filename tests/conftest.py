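"""Shared fixtures: random parameter factories for the layer tests."""

import numpy as np
import pytest

from dctext.model_core import (
    AttentionParams,
    ChannelParams,
    ConvParams,
    HeadParams,
    LSTMParams,
    LSTMState,
    PoolConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_conv_params(rng, widths=(2, 3), n_maps=2, in_channels=3,
                     stride=1, padding=0) -> ConvParams:
    return ConvParams(
        kernels={f: rng.normal(size=(n_maps, f, in_channels)) for f in widths},
        biases={f: rng.normal(size=n_maps) for f in widths},
        stride=stride, padding=padding,
    )


def make_lstm_params(rng, d=3, e=4) -> LSTMParams:
    return LSTMParams(
        W_i=rng.normal(size=(d, d + e)), W_f=rng.normal(size=(d, d + e)),
        W_q=rng.normal(size=(d, d + e)), W_o=rng.normal(size=(d, d + e)),
        b_i=rng.normal(size=d), b_f=rng.normal(size=d),
        b_q=rng.normal(size=d), b_o=rng.normal(size=d),
    )


def make_attn_params(rng, d=3, a=None) -> AttentionParams:
    a = a if a is not None else d
    return AttentionParams(W_a=rng.normal(size=(a, 2 * d)),
                           v_a=rng.normal(size=a), b=rng.normal(size=a))


def make_channel_params(rng, e=4, d=3, widths=(2, 3), n_maps=2) -> ChannelParams:
    return ChannelParams(
        conv=make_conv_params(rng, widths=widths, n_maps=n_maps, in_channels=e),
        pool=PoolConfig(mode="max_over_time"),
        lstm=make_lstm_params(rng, d=d, e=e),
        attn=make_attn_params(rng, d=d),
    )


def make_head_params(rng, in_dim, dense_dim=5, n_classes=3) -> HeadParams:
    return HeadParams(
        dense_W=rng.normal(size=(dense_dim, in_dim)), dense_b=rng.normal(size=dense_dim),
        out_W=rng.normal(size=(n_classes, dense_dim)), out_b=rng.normal(size=n_classes),
    )


@pytest.fixture
def lstm_params(rng):
    return make_lstm_params(rng)


@pytest.fixture
def attn_params(rng):
    return make_attn_params(rng)
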