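"""Mini-batch training, losses, evaluation metrics and baseline configs."""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .model_core.autograd import Tensor, log_softmax, pick, softmax
from .model_core.network import TextClassifier
from .model_core.params import ARCHITECTURES, ModelConfig
from .preprocessing import (
    EncodedDataset,
    Vocabulary,
    build_vocab,
    encode_dataset,
    tokenize_chars,
    tokenize_words,
)

_PROB_FLOOR = 1e-12


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    batch_size: int = 256
    optimizer: str = "adam"  # adam | adadelta
    learning_rate: float = 1e-3
    epochs: int = 10
    seed: int = 0
    loss: str = "categorical_ce"  # categorical_ce | binary_ce

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("adam", "adadelta"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in ("categorical_ce", "binary_ce"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# -- losses ------------------------------------------------------------

def loss(probs: np.ndarray, label: int, kind: str = "categorical_ce") -> float:
    """Loss of one predicted probability vector against an integer label.

    Zero probabilities are clamped at 1e-12 with a warning rather than
    raising.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any(probs <= 0.0) or np.any(probs >= 1.0):
        if probs[label] <= 0.0 or (kind == "binary_ce" and np.any(probs >= 1.0)):
            warnings.warn("probability hit 0/1; clamping for the log", RuntimeWarning)
    p = np.clip(probs, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    if kind == "categorical_ce":
        return float(-np.log(p[label]))
    if kind == "binary_ce":
        y = np.zeros_like(p)
        y[label] = 1.0
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    raise ValueError(f"unknown loss kind {kind!r}")


def _batch_loss(logits: Tensor, labels: np.ndarray, kind: str) -> Tensor:
    if kind == "categorical_ce":
        return -pick(log_softmax(logits, axis=1), labels).mean()
    # binary: mean per-class Bernoulli CE against the one-hot target
    p = softmax(logits, axis=1)
    n, c = logits.shape
    y = np.zeros((n, c))
    y[np.arange(n), labels] = 1.0
    eps = 1e-9
    safe = p * (1.0 - 2.0 * eps) + eps  # keep both logs finite
    ll = Tensor(y) * safe.log() + Tensor(1.0 - y) * (1.0 - safe).log()
    return -ll.mean(axis=1).mean()


# -- optimizers --------------------------------------------------------

class _Adam:
    def __init__(self, params: Dict[str, Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.lr, self.b1, self.b2, self.eps = params, lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _Adadelta:
    def __init__(self, params: Dict[str, Tensor], lr: float = 1.0,
                 rho: float = 0.95, eps: float = 1e-6):
        self.params, self.lr, self.rho, self.eps = params, lr, rho, eps
        self.eg = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.ed = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self):
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.eg[k] = self.rho * self.eg[k] + (1 - self.rho) * g * g
            delta = np.sqrt(self.ed[k] + self.eps) / np.sqrt(self.eg[k] + self.eps) * g
            self.ed[k] = self.rho * self.ed[k] + (1 - self.rho) * delta * delta
            p.data -= self.lr * delta


# -- training loop -----------------------------------------------------

@dataclass
class History:
    records: List[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_state: Optional[Dict[str, np.ndarray]] = None


def evaluate(model: TextClassifier, data: EncodedDataset,
             loss_kind: str = "categorical_ce",
             batch_size: int = 256) -> Tuple[float, float, np.ndarray]:
    """(mean loss, accuracy, (N, n_classes) probabilities) on a dataset."""
    probs = model.predict_proba(data.word_ids, data.char_ids, batch_size=batch_size)
    losses = [loss(probs[i], int(data.labels[i]), loss_kind) for i in range(len(data))]
    preds = probs.argmax(axis=1)
    acc = float((preds == data.labels).mean())
    return float(np.mean(losses)), acc, probs


def train(model: TextClassifier, train_data: EncodedDataset, config: TrainConfig,
          val_data: Optional[EncodedDataset] = None) -> History:
    """Shuffled mini-batch training, deterministic under ``config.seed``.

    Records one history line per epoch and split; retains the parameter
    state of the best-validation epoch (training split stands in when no
    validation set is given).
    """
    if len(train_data) == 0:
        raise ValueError("empty training set")
    if int(train_data.labels.max()) >= model.config.n_classes:
        raise ValueError("label out of range for the configured class count")
    rng = np.random.default_rng(config.seed)
    trainable = model.trainable()
    opt = (_Adam(trainable, config.learning_rate) if config.optimizer == "adam"
           else _Adadelta(trainable, config.learning_rate))
    history = History()
    best_key = None
    n = len(train_data)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            model.zero_grad()
            logits = model.forward(train_data.word_ids[idx], train_data.char_ids[idx],
                                   train=True, rng=rng)
            batch_loss = _batch_loss(logits, train_data.labels[idx], config.loss)
            if not np.isfinite(batch_loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch offset {lo}")
            batch_loss.backward()
            model.mask_padding_grads()
            opt.step()
        tr_loss, tr_acc, _ = evaluate(model, train_data, config.loss, config.batch_size)
        history.records.append({"epoch": epoch, "split": "train",
                                "loss": tr_loss, "accuracy": tr_acc})
        if val_data is not None:
            va_loss, va_acc, _ = evaluate(model, val_data, config.loss, config.batch_size)
            history.records.append({"epoch": epoch, "split": "val",
                                    "loss": va_loss, "accuracy": va_acc})
            key = (va_acc, -va_loss)
        else:
            key = (tr_acc, -tr_loss)
        if best_key is None or key > best_key:
            best_key = key
            history.best_epoch = epoch
            history.best_state = model.state_dict()
    if history.best_state is not None:
        model.load_state_dict(history.best_state)
    return history


# -- evaluation metrics ------------------------------------------------

@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(predicted: Sequence[int], true: Sequence[int],
              n_classes: int) -> List[ConfusionCounts]:
    """One-vs-rest TP/FP/TN/FN per class."""
    predicted = np.asarray(predicted, dtype=np.int64)
    true = np.asarray(true, dtype=np.int64)
    if predicted.shape != true.shape:
        raise ValueError("prediction and label sequences differ in length")
    if predicted.size and (predicted.min() < 0 or predicted.max() >= n_classes
                           or true.min() < 0 or true.max() >= n_classes):
        raise ValueError("label outside [0, n_classes)")
    out = []
    for c in range(n_classes):
        tp = int(np.sum((predicted == c) & (true == c)))
        fp = int(np.sum((predicted == c) & (true != c)))
        fn = int(np.sum((predicted != c) & (true == c)))
        tn = int(np.sum((predicted != c) & (true != c)))
        out.append(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
    return out


@dataclass
class Metrics:
    accuracy: float
    precision: List[float]
    recall: List[float]
    f1: List[float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    undefined: List[str] = field(default_factory=list)  # which ratios were 0/0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _safe_ratio(num: int, den: int, tag: str, flags: List[str]) -> float:
    if den == 0:
        flags.append(tag)
        return 0.0
    return num / den


def metrics(counts: Sequence[ConfusionCounts]) -> Metrics:
    """Precision/recall/F1 per class plus pooled accuracy and macro means.

    Accuracy is the fraction of examples whose predicted class is
    correct (the one-vs-rest TPs summed over classes, divided by the
    example count). Undefined 0/0 ratios are reported as 0 and flagged.
    """
    flags: List[str] = []
    n = counts[0].total
    for c in counts:
        if c.total != n:
            raise ValueError("inconsistent confusion counts")
    precision = [_safe_ratio(c.TP, c.TP + c.FP, f"precision[{i}]", flags)
                 for i, c in enumerate(counts)]
    recall = [_safe_ratio(c.TP, c.TP + c.FN, f"recall[{i}]", flags)
              for i, c in enumerate(counts)]
    f1 = []
    for i, (p, r) in enumerate(zip(precision, recall)):
        if p + r == 0:
            flags.append(f"f1[{i}]")
            f1.append(0.0)
        else:
            f1.append(2 * p * r / (p + r))
    accuracy = sum(c.TP for c in counts) / n if n else 0.0
    k = len(counts)
    return Metrics(accuracy=accuracy, precision=precision, recall=recall, f1=f1,
                   macro_precision=sum(precision) / k, macro_recall=sum(recall) / k,
                   macro_f1=sum(f1) / k, undefined=flags)


def roc_auc(scores: np.ndarray, labels: Sequence[int], class_id: int) -> float:
    """One-vs-rest AUC by the midrank statistic.

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    s = scores[:, class_id] if scores.ndim == 2 else scores
    pos = labels == class_id
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined without both positives and negatives")
    ranks = rankdata(s)  # midranks
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def per_class_auc(probs: np.ndarray, labels: Sequence[int]) -> List[float]:
    return [roc_auc(probs, labels, c) for c in range(probs.shape[1])]


# -- baselines ---------------------------------------------------------

def build_baseline(kind: str, config: ModelConfig) -> ModelConfig:
    """A comparator config sharing every hyperparameter but the wiring."""
    if kind not in ARCHITECTURES:
        raise ValueError(f"unknown baseline kind {kind!r}; choose from {ARCHITECTURES}")
    d = config.to_dict()
    d["arch"] = kind
    return ModelConfig.from_dict(d)


# -- end-to-end convenience --------------------------------------------

@dataclass
class PipelineResult:
    model: TextClassifier
    word_vocab: Vocabulary
    char_vocab: Vocabulary
    history: History
    test_metrics: Optional[Metrics]
    test_probs: Optional[np.ndarray]
    test_accuracy: Optional[float]


def run_pipeline(train_texts: Sequence[str], train_labels: Sequence[int],
                 model_config: ModelConfig, train_config: TrainConfig,
                 test_texts: Optional[Sequence[str]] = None,
                 test_labels: Optional[Sequence[int]] = None,
                 min_freq: int = 1, max_vocab: Optional[int] = None,
                 word_matrix: Optional[np.ndarray] = None,
                 char_matrix: Optional[np.ndarray] = None) -> PipelineResult:
    """Vocabulary building, encoding, training and test evaluation in one go."""
    word_vocab = build_vocab((tokenize_words(t) for t in train_texts),
                             min_freq=min_freq, max_size=max_vocab, granularity="word")
    char_vocab = build_vocab((tokenize_chars(t) for t in train_texts),
                             min_freq=1, max_size=max_vocab, granularity="char")
    cfg = build_baseline(model_config.arch, model_config)  # copy
    cfg.word_vocab_size = len(word_vocab)
    cfg.char_vocab_size = len(char_vocab)
    train_set = encode_dataset(train_texts, train_labels, word_vocab, char_vocab,
                               cfg.max_word_len, cfg.max_char_len)
    model = TextClassifier(cfg, rng=np.random.default_rng(train_config.seed),
                           word_matrix=word_matrix, char_matrix=char_matrix)
    history = train(model, train_set, train_config)
    test_metrics = test_probs = test_acc = None
    if test_texts is not None and test_labels is not None:
        test_set = encode_dataset(test_texts, test_labels, word_vocab, char_vocab,
                                  cfg.max_word_len, cfg.max_char_len)
        _, test_acc, test_probs = evaluate(model, test_set, train_config.loss,
                                           train_config.batch_size)
        preds = test_probs.argmax(axis=1)
        test_metrics = metrics(confusion(preds, test_set.labels, cfg.n_classes))
    return PipelineResult(model=model, word_vocab=word_vocab, char_vocab=char_vocab,
                          history=history, test_metrics=test_metrics,
                          test_probs=test_probs, test_accuracy=test_acc)
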