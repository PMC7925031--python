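# dctext

A dual-granularity neural text classifier in pure numpy. Every document
is read twice — as a sequence of word tokens and as a sequence of
characters — and each granularity feeds its own channel: a
multi-width convolution branch (ReLU + max-over-time pooling) running
in parallel with an LSTM branch whose per-timestep hidden *and* cell
states are pooled by an attention mechanism. The channel outputs are
concatenated and classified through a dense + softmax head.

The package includes:

- `dctext.preprocessing` — tokenization (whitespace or pluggable
  segmenter), frequency vocabularies with fixed pad/unk slots,
  fixed-length encoding, word2vec-text embedding loading, and readers
  for two CSV dialects (`department,title,ask` with header; headerless
  6-field polarity CSV).
- `dctext.model_core` — a minimal reverse-mode autodiff engine over
  numpy, the differentiable layers, single-example functional ops
  (`convolve`, `pool`, `lstm_step`, `lstm_sequence`, `hybrid_attention`,
  `channel_forward`, `dc_forward`), explicit-loop reference
  implementations used as test oracles, and the trainable
  `TextClassifier` with single-archive checkpointing.
- `dctext.training` — mini-batch training (Adam or Adadelta,
  categorical or binary cross-entropy), one-vs-rest confusion counts,
  precision/recall/F1/accuracy, midrank ROC-AUC, and baseline
  architectures (`cnn`, `lstm`, `cnn_lstm`, `gru`, `word_only_dc`,
  `char_only_dc`) sharing the same head and training stack.
- `dctext.synthetic_data` — deterministic toy corpora with plantable
  word-level and/or char-level class signal, used to verify each
  channel's contribution without external downloads.
- `dctext.cli` — `generate` / `train` / `evaluate` / `predict`.

There is no deep-learning framework dependency; gradients come from the
bundled autodiff engine and are finite-difference-checked in the tests.

## CLI quick start

```
# synthetic dataset with one decisive marker token per class
dctext generate --n-classes 3 --n-per-class 50 --signal-mode word \
    --signal-strength 1.0 --seed 1 --out-dir data/toy

# train a small double-channel model
dctext train --train data/toy/train.csv --test data/toy/test.csv \
    --model dc_lstm --epochs 10 --batch-size 32 --learning-rate 0.005 \
    --out-dir runs/toy

dctext evaluate --checkpoint runs/toy/checkpoint.npz --data data/toy/test.csv
dctext predict  --checkpoint runs/toy/checkpoint.npz --text "bado kizu miro"
```

`dctext train` also accepts `--config config.json` (flat key/value
document; flags override file values) and writes a merged config
snapshot, a `history.jsonl` training log, a metrics report and a
reloadable checkpoint into the output directory.

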