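"""The trainable classifier: parameter initialization, forward pass for
every supported architecture, and bit-exact checkpointing.

Architectures share one head and one preprocessing contract:

* ``dc_lstm`` — word + char channels, each conv-branch ⊕ attention-LSTM;
* ``word_only_dc`` / ``char_only_dc`` — single-channel ablations;
* ``cnn`` — word conv branch only;
* ``lstm`` / ``gru`` — word recurrent branch only, final hidden state;
* ``cnn_lstm`` — series: same-padded conv features fed to an LSTM.
"""

from __future__ import annotations

import json
from typing import Dict, Optional

import numpy as np

from . import layers
from .autograd import Tensor, concat, embedding
from .params import ModelConfig

_LSTM_GATES = ("W_i", "W_f", "W_q", "W_o", "b_i", "b_f", "b_q", "b_o")
_GRU_GATES = ("W_r", "W_u", "W_n", "b_r", "b_u", "b_n")
_ATTN = ("W_a", "v_a", "b")


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


class TextClassifier:
    """Holds the parameter tensors and runs the batched forward pass."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | int = 0,
                 word_matrix: np.ndarray | None = None,
                 char_matrix: np.ndarray | None = None):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.config = config
        self.params: Dict[str, Tensor] = {}
        c = config

        if self._uses_words:
            wm = word_matrix if word_matrix is not None else self._random_embed(
                rng, c.word_vocab_size, c.embed_dim)
            self.params["word_embed"] = Tensor(wm, requires_grad=c.embeddings_trainable)
        if self._uses_chars:
            cm = char_matrix if char_matrix is not None else self._random_embed(
                rng, c.char_vocab_size, c.embed_dim)
            self.params["char_embed"] = Tensor(cm, requires_grad=c.embeddings_trainable)

        for chan in self._channels:
            if self._has_conv(chan):
                for f in c.widths:
                    k = _glorot(rng, (c.n_maps, f, c.embed_dim),
                                f * c.embed_dim, c.n_maps)
                    self.params[f"{chan}.conv.{f}.kernel"] = Tensor(k, requires_grad=True)
                    self.params[f"{chan}.conv.{f}.bias"] = Tensor(
                        np.zeros(c.n_maps), requires_grad=True)
            if self._has_lstm(chan):
                e_in = self._lstm_input_dim
                d = c.lstm_dim
                for g in ("i", "f", "q", "o"):
                    W = _glorot(rng, (d, d + e_in), d + e_in, d)
                    self.params[f"{chan}.lstm.W_{g}"] = Tensor(W, requires_grad=True)
                    # forget-gate bias starts at 1 so early training retains memory
                    b0 = np.ones(d) if g == "f" else np.zeros(d)
                    self.params[f"{chan}.lstm.b_{g}"] = Tensor(b0, requires_grad=True)
            if self._has_gru(chan):
                e_in = c.embed_dim
                d = c.lstm_dim
                for g in ("r", "u", "n"):
                    W = _glorot(rng, (d, d + e_in), d + e_in, d)
                    self.params[f"{chan}.gru.W_{g}"] = Tensor(W, requires_grad=True)
                    self.params[f"{chan}.gru.b_{g}"] = Tensor(np.zeros(d), requires_grad=True)
            if self._has_attention(chan):
                a, d2 = c.attention_dim, 2 * c.lstm_dim
                self.params[f"{chan}.attn.W_a"] = Tensor(
                    _glorot(rng, (a, d2), d2, a), requires_grad=True)
                self.params[f"{chan}.attn.v_a"] = Tensor(
                    _glorot(rng, (a,), a, 1), requires_grad=True)
                self.params[f"{chan}.attn.b"] = Tensor(np.zeros(a), requires_grad=True)

        h_dim = self.hidden_dim
        self.params["dense.W"] = Tensor(
            _glorot(rng, (c.dense_dim, h_dim), h_dim, c.dense_dim), requires_grad=True)
        self.params["dense.b"] = Tensor(np.zeros(c.dense_dim), requires_grad=True)
        self.params["out.W"] = Tensor(
            _glorot(rng, (c.n_classes, c.dense_dim), c.dense_dim, c.n_classes),
            requires_grad=True)
        self.params["out.b"] = Tensor(np.zeros(c.n_classes), requires_grad=True)

    # -- structure -----------------------------------------------------
    @staticmethod
    def _random_embed(rng: np.random.Generator, size: int, dim: int) -> np.ndarray:
        m = rng.uniform(-0.25, 0.25, size=(size, dim))
        m[0] = 0.0  # padding row stays zero
        return m

    @property
    def _uses_words(self) -> bool:
        return self.config.arch != "char_only_dc"

    @property
    def _uses_chars(self) -> bool:
        return self.config.arch in ("dc_lstm", "char_only_dc")

    @property
    def _channels(self):
        arch = self.config.arch
        if arch == "dc_lstm":
            return ("word", "char")
        if arch == "char_only_dc":
            return ("char",)
        return ("word",)

    def _has_conv(self, chan: str) -> bool:
        return self.config.arch in ("dc_lstm", "word_only_dc", "char_only_dc",
                                    "cnn", "cnn_lstm")

    def _has_lstm(self, chan: str) -> bool:
        return self.config.arch in ("dc_lstm", "word_only_dc", "char_only_dc",
                                    "lstm", "cnn_lstm")

    def _has_gru(self, chan: str) -> bool:
        return self.config.arch == "gru"

    def _has_attention(self, chan: str) -> bool:
        return self.config.arch in ("dc_lstm", "word_only_dc", "char_only_dc")

    @property
    def _lstm_input_dim(self) -> int:
        c = self.config
        if c.arch == "cnn_lstm":
            return c.n_maps * len(c.widths)
        return c.embed_dim

    @property
    def channel_dim(self) -> int:
        c = self.config
        conv_dim = c.n_maps * len(c.widths)
        rec_dim = 2 * c.lstm_dim
        return {
            "dc_lstm": conv_dim + rec_dim,
            "word_only_dc": conv_dim + rec_dim,
            "char_only_dc": conv_dim + rec_dim,
            "cnn": conv_dim,
            "lstm": c.lstm_dim,
            "gru": c.lstm_dim,
            "cnn_lstm": c.lstm_dim,
        }[c.arch]

    @property
    def hidden_dim(self) -> int:
        return self.channel_dim * (2 if self.config.arch == "dc_lstm" else 1)

    def _gate_dict(self, chan: str, kind: str) -> Dict[str, Tensor]:
        names = _LSTM_GATES if kind == "lstm" else _GRU_GATES if kind == "gru" else _ATTN
        return {n: self.params[f"{chan}.{kind}.{n}"] for n in names}

    # -- forward -------------------------------------------------------
    def _channel(self, chan: str, ids: np.ndarray) -> Tensor:
        c = self.config
        X = embedding(self.params[f"{chan}_embed"], ids)
        arch = c.arch
        if arch in ("dc_lstm", "word_only_dc", "char_only_dc"):
            kernels = {f: self.params[f"{chan}.conv.{f}.kernel"] for f in c.widths}
            biases = {f: self.params[f"{chan}.conv.{f}.bias"] for f in c.widths}
            conv_out = layers.conv_branch(X, kernels, biases)
            H, C = layers.lstm_scan(X, self._gate_dict(chan, "lstm"))
            context, _ = layers.attention_pool(H, C, self._gate_dict(chan, "attn"))
            return concat([conv_out, context], axis=1)
        if arch == "cnn":
            kernels = {f: self.params[f"{chan}.conv.{f}.kernel"] for f in c.widths}
            biases = {f: self.params[f"{chan}.conv.{f}.bias"] for f in c.widths}
            return layers.conv_branch(X, kernels, biases)
        if arch == "lstm":
            H, _ = layers.lstm_scan(X, self._gate_dict(chan, "lstm"))
            return H[:, -1, :]
        if arch == "gru":
            return layers.gru_scan(X, self._gate_dict(chan, "gru"))
        if arch == "cnn_lstm":
            kernels = {f: self.params[f"{chan}.conv.{f}.kernel"] for f in c.widths}
            biases = {f: self.params[f"{chan}.conv.{f}.bias"] for f in c.widths}
            seq = layers.conv_sequence(X, kernels, biases)
            H, _ = layers.lstm_scan(seq, self._gate_dict(chan, "lstm"))
            return H[:, -1, :]
        raise AssertionError(arch)

    def forward(self, word_ids: Optional[np.ndarray], char_ids: Optional[np.ndarray],
                train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        """Batched logits. word_ids/char_ids: (B, T) int arrays (either may
        be None when the architecture ignores that granularity)."""
        parts = []
        if self._uses_chars:
            parts.append(self._channel("char", np.asarray(char_ids)))
        if self._uses_words:
            parts.append(self._channel("word", np.asarray(word_ids)))
        hidden = parts[0] if len(parts) == 1 else concat(parts, axis=1)
        hidden = layers.dropout(hidden, self.config.dropout, rng, train)
        dense = layers.linear(hidden, self.params["dense.W"], self.params["dense.b"]).relu()
        return layers.linear(dense, self.params["out.W"], self.params["out.b"])

    def predict_proba(self, word_ids, char_ids, batch_size: int = 256) -> np.ndarray:
        """Inference-mode class probabilities, batched internally."""
        n = len(word_ids) if word_ids is not None else len(char_ids)
        outs = []
        for lo in range(0, n, batch_size):
            hi = lo + batch_size
            w = None if word_ids is None else np.asarray(word_ids)[lo:hi]
            ch = None if char_ids is None else np.asarray(char_ids)[lo:hi]
            logits = self.forward(w, ch, train=False).data
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            outs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(outs, axis=0)

    # -- optimization support ------------------------------------------
    def trainable(self) -> Dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if v.requires_grad}

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()

    def mask_padding_grads(self) -> None:
        """The padding row of each embedding matrix never updates."""
        for name in ("word_embed", "char_embed"):
            t = self.params.get(name)
            if t is not None and t.grad is not None:
                t.grad[0] = 0.0

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k!r}")
            if state[k].shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            t.data = np.array(state[k], dtype=np.float64)

    # -- persistence ---------------------------------------------------
    def save(self, path, word_vocab=None, char_vocab=None, class_names=None) -> None:
        """Single-archive checkpoint: parameters + config (+ vocabularies
        and ordered class names), sufficient for bit-exact reload."""
        payload = {k: v.data for k, v in self.params.items()}
        payload["__config__"] = np.array(json.dumps(self.config.to_dict()))
        if word_vocab is not None:
            payload["__word_vocab__"] = np.array(json.dumps(word_vocab.to_dict()))
        if char_vocab is not None:
            payload["__char_vocab__"] = np.array(json.dumps(char_vocab.to_dict()))
        if class_names is not None:
            payload["__classes__"] = np.array(json.dumps(list(class_names)))
        np.savez(path, **payload)

    @classmethod
    def load(cls, path):
        """Returns (model, extras) where extras holds optional vocabulary
        dicts and class names stored alongside the parameters."""
        with np.load(path, allow_pickle=False) as z:
            config = ModelConfig.from_dict(json.loads(str(z["__config__"])))
            model = cls(config, rng=0)
            model.load_state_dict({k: z[k] for k in z.files if not k.startswith("__")})
            extras = {}
            for key, name in (("__word_vocab__", "word_vocab"),
                              ("__char_vocab__", "char_vocab"),
                              ("__classes__", "classes")):
                if key in z.files:
                    extras[name] = json.loads(str(z[key]))
        return model, extras
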