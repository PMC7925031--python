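"""Layer-operation contracts, loop-oracle equivalence and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    make_attn_params,
    make_channel_params,
    make_conv_params,
    make_head_params,
    make_lstm_params,
)
from dctext.model_core import (
    AttentionParams,
    ConvParams,
    GeometryError,
    LSTMParams,
    LSTMState,
    ModelConfig,
    PoolConfig,
    TextClassifier,
    channel_forward,
    conv_output_length,
    convolve,
    dc_forward,
    hybrid_attention,
    lstm_sequence,
    lstm_step,
    pool,
)
from dctext.model_core import reference as ref
from dctext.model_core.params import ChannelParams


class TestConvOutputLength:
    @pytest.mark.parametrize("args,expected", [
        ((10, 3, 0, 1), 8),
        ((5, 1, 0, 1), 5),
        ((17, 1, 0, 1), 17),
        ((7, 3, 1, 2), 4),
    ])
    def test_examples(self, args, expected):
        assert conv_output_length(*args) == expected

    def test_invalid_geometry(self):
        with pytest.raises(GeometryError):
            conv_output_length(2, 5, 0, 1)

    def test_geometry_grid_matches_realized_length(self, rng):
        """Realized convolution lengths equal the closed form on the grid."""
        for L in range(3, 21):
            for f in (1, 3, 5, 7):
                for p in (0, 1, 2):
                    for s0 in (1, 2):
                        if L + 2 * p < f:
                            continue
                        params = make_conv_params(rng, widths=(f,), n_maps=1,
                                                  in_channels=2, stride=s0, padding=p)
                        out = convolve(rng.normal(size=(L, 2)), params)
                        assert out[f].shape[1] == conv_output_length(L, f, p, s0)


class TestConvolve:
    def test_all_ones_width2_kernel(self):
        params = ConvParams(kernels={2: np.ones((1, 2, 1))}, biases={2: np.zeros(1)})
        out = convolve(np.ones((4, 1)), params)
        np.testing.assert_allclose(out[2], [[2.0, 2.0, 2.0]])

    def test_zero_kernel_bias_five(self, rng):
        params = ConvParams(kernels={3: np.zeros((2, 3, 2))},
                            biases={3: np.full(2, 5.0)})
        out = convolve(rng.normal(size=(6, 2)), params)
        np.testing.assert_allclose(out[3], 5.0)

    def test_matches_nested_loop_oracle(self, rng):
        params = make_conv_params(rng, widths=(3,), n_maps=2, in_channels=3)
        x = rng.normal(size=(8, 3))
        got = convolve(x, params)
        want = ref.convolve_ref(x, params)
        np.testing.assert_allclose(got[3], want[3], atol=1e-10)

    def test_channel_mismatch_raises(self, rng):
        params = make_conv_params(rng, in_channels=3)
        with pytest.raises(ValueError):
            convolve(rng.normal(size=(6, 2)), params)


class TestPool:
    def test_max_over_time(self):
        np.testing.assert_allclose(
            pool(np.array([1.0, 3.0, 2.0, 8.0]), PoolConfig(mode="max_over_time")), [8.0])

    def test_average_window(self):
        cfg = PoolConfig(mode="average", window=2, stride=2)
        np.testing.assert_allclose(pool(np.array([2.0, 2.0, 2.0, 2.0]), cfg), [2.0, 2.0])

    def test_large_exponent_approaches_max(self):
        cfg = PoolConfig(mode="pnorm", window=4, stride=4, exponent=64)
        got = pool(np.array([1.0, 2.0, 3.0, 4.0]), cfg)
        # direct evaluation of the p-norm formula
        want = (1.0 + 2.0 ** 64 + 3.0 ** 64 + 4.0 ** 64) ** (1 / 64)
        np.testing.assert_allclose(got, [want])
        assert abs(got[0] - 4.0) < 1e-3

    def test_infinite_exponent_is_plain_max(self):
        cfg = PoolConfig(mode="pnorm", window=2, stride=1, exponent=math.inf)
        np.testing.assert_allclose(pool(np.array([1.0, 5.0, 2.0]), cfg), [5.0, 5.0])

    def test_finite_exponent_rejects_negative_input(self):
        cfg = PoolConfig(mode="pnorm", window=2, stride=1, exponent=2)
        with pytest.raises(ValueError):
            pool(np.array([1.0, -1.0]), cfg)

    def test_window_too_large(self):
        with pytest.raises(GeometryError):
            pool(np.array([1.0, 2.0]), PoolConfig(mode="max", window=3, stride=1))

    def test_matches_loop_oracle(self, rng):
        row = np.abs(rng.normal(size=9))
        for cfg in (PoolConfig(mode="pnorm", window=3, stride=2, exponent=2.5),
                    PoolConfig(mode="average", window=2, stride=1),
                    PoolConfig(mode="max", window=4, stride=3),
                    PoolConfig(mode="max_over_time")):
            np.testing.assert_allclose(pool(row, cfg), ref.pool_ref(row, cfg), atol=1e-10)


class TestLSTMStep:
    def zeros_params(self, d=3, e=2):
        z = np.zeros((d, d + e))
        return LSTMParams(W_i=z.copy(), W_f=z.copy(), W_q=z.copy(), W_o=z.copy(),
                          b_i=np.zeros(d), b_f=np.zeros(d), b_q=np.zeros(d),
                          b_o=np.zeros(d))

    def test_all_zero_weights(self):
        p = self.zeros_params()
        s = lstm_step(np.zeros(2), LSTMState(h=np.zeros(3), c=np.zeros(3)), p)
        # sigmoid(0)=0.5, tanh(0)=0 -> candidate 0 -> c_t = h_t = 0
        np.testing.assert_allclose(s.c, 0.0)
        np.testing.assert_allclose(s.h, 0.0)

    def test_saturated_gates_preserve_memory(self):
        p = self.zeros_params()
        p.b_f[:] = 50.0  # forget gate ~1
        p.b_i[:] = -50.0  # input gate ~0
        c_prev = np.array([0.3, -0.7, 0.1])
        s = lstm_step(np.zeros(2), LSTMState(h=np.zeros(3), c=c_prev), p)
        np.testing.assert_allclose(s.c, c_prev, atol=1e-10)

    def test_matches_scalar_loop_oracle(self, rng, lstm_params):
        x = rng.normal(size=4)
        state = LSTMState(h=rng.normal(size=3), c=rng.normal(size=3))
        got = lstm_step(x, state, lstm_params)
        want = ref.lstm_step_ref(x, state, lstm_params)
        np.testing.assert_allclose(got.h, want.h, atol=1e-6)
        np.testing.assert_allclose(got.c, want.c, atol=1e-6)

    def test_non_finite_input_raises(self, lstm_params):
        with pytest.raises(FloatingPointError):
            lstm_step(np.array([np.nan, 0, 0, 0]),
                      LSTMState(h=np.zeros(3), c=np.zeros(3)), lstm_params)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_hidden_state_bounded_by_one(self, seed):
        r = np.random.default_rng(seed)
        p = make_lstm_params(r, d=3, e=4)
        # scale params/inputs up: boundedness must hold regardless
        state = LSTMState(h=np.clip(r.normal(size=3), -1, 1), c=r.normal(size=3) * 10)
        s = lstm_step(r.normal(size=4) * 10, state, p)
        assert np.all(np.abs(s.h) <= 1.0)


class TestLSTMSequence:
    def test_single_step_equivalence(self, rng, lstm_params):
        x = rng.normal(size=(1, 4))
        H, C = lstm_sequence(x, lstm_params)
        s = lstm_step(x[0], LSTMState(h=np.zeros(3), c=np.zeros(3)), lstm_params)
        np.testing.assert_allclose(H[0], s.h)
        np.testing.assert_allclose(C[0], s.c)

    def test_zero_input_zero_weights(self):
        p = TestLSTMStep().zeros_params()
        H, C = lstm_sequence(np.zeros((4, 2)), p)
        np.testing.assert_allclose(H, 0.0)

    def test_empty_sequence(self, lstm_params):
        H, C = lstm_sequence(np.zeros((0, 4)), lstm_params)
        assert H.shape == (0, 3) and C.shape == (0, 3)

    def test_equals_chained_steps(self, rng, lstm_params):
        X = rng.normal(size=(5, 4))
        H, C = lstm_sequence(X, lstm_params)
        state = LSTMState(h=np.zeros(3), c=np.zeros(3))
        for t in range(5):
            state = lstm_step(X[t], state, lstm_params)
            np.testing.assert_allclose(H[t], state.h, atol=1e-10)
            np.testing.assert_allclose(C[t], state.c, atol=1e-10)

    def test_initial_state_respected(self, rng, lstm_params):
        X = rng.normal(size=(2, 4))
        h0, c0 = rng.normal(size=3), rng.normal(size=3)
        H, _ = lstm_sequence(X, lstm_params, h0=h0, c0=c0)
        s = lstm_step(X[0], LSTMState(h=h0, c=c0), lstm_params)
        np.testing.assert_allclose(H[0], s.h)


class TestHybridAttention:
    def test_singleton_sequence(self, rng, attn_params):
        H = rng.normal(size=(1, 3))
        C = rng.normal(size=(1, 3))
        out = hybrid_attention(H, C, attn_params)
        np.testing.assert_allclose(out.weights, [1.0])
        np.testing.assert_allclose(out.context, np.concatenate([H[0], C[0]]))

    def test_zero_scores_give_uniform_weights(self, rng):
        d = 3
        p = AttentionParams(W_a=np.zeros((d, 2 * d)), v_a=np.ones(d), b=np.zeros(d))
        H = rng.normal(size=(4, d))
        C = rng.normal(size=(4, d))
        out = hybrid_attention(H, C, p)
        np.testing.assert_allclose(out.weights, 0.25)
        keys = np.concatenate([H, C], axis=1)
        np.testing.assert_allclose(out.context, keys.mean(axis=0))

    def test_matches_loop_oracle(self, rng, attn_params, lstm_params):
        X = rng.normal(size=(4, 4))
        H, C = lstm_sequence(X, lstm_params)
        got = hybrid_attention(H, C, attn_params)
        want = ref.hybrid_attention_ref(H, C, attn_params)
        np.testing.assert_allclose(got.weights, want.weights, atol=1e-9)
        np.testing.assert_allclose(got.context, want.context, atol=1e-9)

    def test_empty_sequence_raises(self, attn_params):
        with pytest.raises(ValueError):
            hybrid_attention(np.zeros((0, 3)), np.zeros((0, 3)), attn_params)

    def test_shape_mismatch_raises(self, attn_params):
        with pytest.raises(ValueError):
            hybrid_attention(np.zeros((3, 3)), np.zeros((2, 3)), attn_params)

    @given(st.integers(0, 2 ** 32 - 1), st.integers(1, 7))
    @settings(max_examples=60, deadline=None)
    def test_weights_on_simplex_and_context_in_hull(self, seed, T):
        r = np.random.default_rng(seed)
        p = make_attn_params(r, d=3)
        H = r.normal(size=(T, 3)) * 3
        C = r.normal(size=(T, 3)) * 3
        out = hybrid_attention(H, C, p)
        assert np.all(out.weights >= 0)
        assert abs(out.weights.sum() - 1.0) <= 1e-9
        keys = np.concatenate([H, C], axis=1)
        assert np.all(out.context >= keys.min(axis=0) - 1e-12)
        assert np.all(out.context <= keys.max(axis=0) + 1e-12)


class TestChannelForward:
    def test_hand_set_toy(self, rng):
        """widths={2}, n_maps=1, d=2: compose the three layer oracles."""
        e, d = 3, 2
        params = ChannelParams(
            conv=make_conv_params(rng, widths=(2,), n_maps=1, in_channels=e),
            pool=PoolConfig(mode="max_over_time"),
            lstm=make_lstm_params(rng, d=d, e=e),
            attn=make_attn_params(rng, d=d),
        )
        emb = rng.normal(size=(5, e))
        out = channel_forward(emb, params)
        assert out.fused.shape == (1 + 2 * d,)
        np.testing.assert_allclose(out.fused, ref.channel_forward_ref(emb, params),
                                   atol=1e-9)

    def test_zero_embeddings_zero_biases_give_zero(self):
        e, d = 2, 2
        z = np.zeros((d, d + e))
        params = ChannelParams(
            conv=ConvParams(kernels={2: np.zeros((1, 2, e))}, biases={2: np.zeros(1)}),
            pool=PoolConfig(mode="max_over_time"),
            lstm=LSTMParams(W_i=z.copy(), W_f=z.copy(), W_q=z.copy(), W_o=z.copy(),
                            b_i=np.zeros(d), b_f=np.zeros(d), b_q=np.zeros(d),
                            b_o=np.zeros(d)),
            attn=AttentionParams(W_a=np.zeros((d, 2 * d)), v_a=np.zeros(d),
                                 b=np.zeros(d)),
        )
        out = channel_forward(np.zeros((4, e)), params)
        np.testing.assert_allclose(out.fused, 0.0)

    def test_doubling_maps_doubles_conv_part_only(self, rng):
        p1 = make_channel_params(rng, e=4, d=3, widths=(2,), n_maps=2)
        p2 = make_channel_params(rng, e=4, d=3, widths=(2,), n_maps=4)
        emb = rng.normal(size=(6, 4))
        o1, o2 = channel_forward(emb, p1), channel_forward(emb, p2)
        assert len(o2.conv_part) == 2 * len(o1.conv_part)
        assert len(o2.recurrent_part) == len(o1.recurrent_part)
        assert len(o1.fused) == len(o1.conv_part) + len(o1.recurrent_part)

    def test_sequence_shorter_than_widest_filter(self, rng):
        params = make_channel_params(rng, e=4, widths=(5,))
        with pytest.raises(GeometryError):
            channel_forward(rng.normal(size=(3, 4)), params)


class TestDCForward:
    def build(self, rng, e=4, d=3, n_maps=2, widths=(2,), n_classes=2):
        wp = make_channel_params(rng, e=e, d=d, widths=widths, n_maps=n_maps)
        cp = make_channel_params(rng, e=e, d=d, widths=widths, n_maps=n_maps)
        fused = n_maps * len(widths) + 2 * d
        head = make_head_params(rng, in_dim=2 * fused, dense_dim=4, n_classes=n_classes)
        wm = rng.normal(size=(9, e))
        cm = rng.normal(size=(7, e))
        return wm, cm, wp, cp, head

    def test_probabilities_sum_to_one(self, rng):
        wm, cm, wp, cp, head = self.build(rng)
        out = dc_forward([1, 2, 3], [1, 2, 3, 4], wm, cm, wp, cp, head)
        assert abs(out.probs.sum() - 1.0) <= 1e-9
        assert np.all(out.probs > 0)

    def test_deterministic(self, rng):
        wm, cm, wp, cp, head = self.build(rng)
        a = dc_forward([1, 2, 3], [1, 2, 3], wm, cm, wp, cp, head)
        b = dc_forward([1, 2, 3], [1, 2, 3], wm, cm, wp, cp, head)
        assert np.array_equal(a.probs, b.probs)

    def test_matches_composed_oracle(self, rng):
        wm, cm, wp, cp, head = self.build(rng)
        wid = rng.integers(0, 9, size=5)
        cid = rng.integers(0, 7, size=6)
        got = dc_forward(wid, cid, wm, cm, wp, cp, head)
        want = ref.dc_forward_ref(wid, cid, wm, cm, wp, cp, head)
        np.testing.assert_allclose(got.probs, want.probs, atol=1e-6)
        np.testing.assert_allclose(got.hidden, want.hidden, atol=1e-6)

    def test_empty_ids_rejected(self, rng):
        wm, cm, wp, cp, head = self.build(rng)
        with pytest.raises(ValueError):
            dc_forward([], [1], wm, cm, wp, cp, head)


class TestCheckpoint:
    def test_save_load_bit_exact(self, tmp_path, rng):
        cfg = ModelConfig(arch="dc_lstm", n_classes=3, word_vocab_size=11,
                          char_vocab_size=7, embed_dim=6, widths=(2, 3), n_maps=2,
                          lstm_dim=4, dense_dim=5, max_word_len=5, max_char_len=8)
        model = TextClassifier(cfg, rng=rng)
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded, _ = TextClassifier.load(path)
        assert loaded.config == cfg
        for k, t in model.params.items():
            assert np.array_equal(t.data, loaded.params[k].data), k
        w = np.array([[1, 2, 3, 0, 0]])
        c = np.array([[1, 2, 3, 4, 0, 0, 0, 0]])
        assert np.array_equal(model.predict_proba(w, c), loaded.predict_proba(w, c))

    def test_canonical_parameter_names(self, rng):
        cfg = ModelConfig(arch="dc_lstm", n_classes=2, word_vocab_size=5,
                          char_vocab_size=5, embed_dim=4, widths=(3,), n_maps=2,
                          lstm_dim=3)
        model = TextClassifier(cfg, rng=rng)
        names = set(model.params)
        for expected in ("word_embed", "char_embed", "word.conv.3.kernel",
                         "char.conv.3.bias", "word.lstm.W_i", "char.lstm.b_o",
                         "word.attn.W_a", "char.attn.v_a", "dense.W", "out.b"):
            assert expected in names
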