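"""Tokenization, vocabularies, sequence encoding and embedding loading.

Raw labeled text is turned into two parallel integer views — word ids
and character ids — each with its own vocabulary and embedding matrix,
so the two granularities can feed independent channels.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

PAD_INDEX = 0
UNK_INDEX = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


class ConfigurationError(ValueError):
    pass


class EmbeddingFormatError(ValueError):
    pass


def tokenize_words(text: str, mode: str = "whitespace",
                   segmenter: Optional[Callable[[str], Sequence[str]]] = None) -> List[str]:
    """Split text into word tokens.

    ``whitespace`` lowercases and splits on runs of whitespace (suits
    English and pre-segmented Chinese). ``segmenter`` delegates to a
    caller-supplied segmentation callback for unsegmented text.
    """
    if mode == "whitespace":
        return text.lower().split()
    if mode == "segmenter":
        if segmenter is None:
            raise ConfigurationError("segmenter mode requires a segmentation callback")
        return list(segmenter(text))
    raise ConfigurationError(f"unknown tokenization mode {mode!r}")


def tokenize_chars(text: str) -> List[str]:
    """Unicode code points with whitespace removed."""
    return [ch for ch in text if not ch.isspace()]


@dataclass
class Vocabulary:
    """Bidirectional token<->index map with fixed pad=0 and unk=1 slots."""

    granularity: str  # "word" | "char"
    index_to_token: List[str]
    token_to_index: dict = field(init=False)

    def __post_init__(self):
        if self.index_to_token[:2] != [PAD_TOKEN, UNK_TOKEN]:
            raise ValueError("indices 0 and 1 are reserved for pad and unk")
        self.token_to_index = {t: i for i, t in enumerate(self.index_to_token)}
        if len(self.token_to_index) != len(self.index_to_token):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.index_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    @property
    def pad_index(self) -> int:
        return PAD_INDEX

    @property
    def unk_index(self) -> int:
        return UNK_INDEX

    def lookup(self, token: str) -> int:
        return self.token_to_index.get(token, UNK_INDEX)

    def to_dict(self) -> dict:
        return {"granularity": self.granularity, "tokens": list(self.index_to_token)}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(granularity=d["granularity"], index_to_token=list(d["tokens"]))


def build_vocab(token_sequences: Iterable[Sequence[str]], min_freq: int = 1,
                max_size: Optional[int] = None, granularity: str = "word") -> Vocabulary:
    """Frequency vocabulary over tokenized documents.

    Tokens are ranked by (frequency desc, token asc) — the lexicographic
    tie-break is part of the contract — pruned below ``min_freq`` and
    truncated to ``max_size`` entries including the two reserved slots.
    """
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    if max_size is not None and max_size < 2:
        raise ValueError("max_size must leave room for pad and unk")
    counts = Counter()
    for seq in token_sequences:
        counts.update(seq)
    ranked = sorted((t for t, c in counts.items() if c >= min_freq),
                    key=lambda t: (-counts[t], t))
    if max_size is not None:
        ranked = ranked[:max_size - 2]
    return Vocabulary(granularity=granularity,
                      index_to_token=[PAD_TOKEN, UNK_TOKEN] + ranked)


def encode(tokens: Sequence[str], vocab: Vocabulary, max_len: int) -> List[int]:
    """Fixed-length encoding: unknowns -> unk, tail-truncate, right-pad."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    ids = [vocab.lookup(t) for t in tokens[:max_len]]
    return ids + [PAD_INDEX] * (max_len - len(ids))


def decode(ids: Sequence[int], vocab: Vocabulary) -> List[str]:
    """Inverse of encode on the non-padding prefix."""
    out = []
    for i in ids:
        if i == PAD_INDEX:
            break
        out.append(vocab.index_to_token[i])
    return out


@dataclass
class EmbeddingMatrix:
    matrix: np.ndarray  # (|V|, dim); row 0 is all-zero padding
    trainable: bool = True

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite entries")
        if np.any(self.matrix[PAD_INDEX] != 0.0):
            raise ValueError("padding row must be zero")


def random_embeddings(vocab: Vocabulary, dim: int, seed: int,
                      trainable: bool = True) -> EmbeddingMatrix:
    """Uniform(-0.25, 0.25) initialization with a zero padding row."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(-0.25, 0.25, size=(len(vocab), dim))
    m[PAD_INDEX] = 0.0
    return EmbeddingMatrix(matrix=m, trainable=trainable)


def load_embeddings(path, vocab: Vocabulary, dim: int, seed: int,
                    trainable: bool = True) -> Tuple[EmbeddingMatrix, float]:
    """Load word2vec-text vectors for a vocabulary.

    In-vocabulary tokens found in the file keep their file vectors;
    everything else (including unk) is drawn uniform(-0.25, 0.25) under
    ``seed``; the padding row is zeroed. Returns the matrix and the
    fraction of real (non-reserved) tokens covered by the file.
    """
    vectors = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if lineno == 1 and len(parts) == 2 and all(p.isdigit() for p in parts):
                continue  # optional "count dim" header
            if len(parts) < 2:
                continue
            token, values = parts[0], parts[1:]
            if token not in vocab:
                continue
            if len(values) != dim:
                raise EmbeddingFormatError(
                    f"line {lineno}: expected {dim} values for {token!r}, got {len(values)}")
            vectors[token] = np.array([float(v) for v in values])
    rng = np.random.default_rng(seed)
    m = rng.uniform(-0.25, 0.25, size=(len(vocab), dim))
    covered = 0
    for token, vec in sorted(vectors.items()):
        m[vocab.token_to_index[token]] = vec
        covered += 1
    m[PAD_INDEX] = 0.0
    n_real = max(1, len(vocab) - 2)
    return EmbeddingMatrix(matrix=m, trainable=trainable), covered / n_real


@dataclass
class EncodedDataset:
    """Parallel fixed-length id views of a labeled corpus."""

    word_ids: np.ndarray  # (N, T_w) int
    char_ids: np.ndarray  # (N, T_c) int
    labels: np.ndarray  # (N,) int

    def __len__(self) -> int:
        return len(self.labels)


def encode_dataset(texts: Sequence[str], labels: Sequence[int],
                   word_vocab: Vocabulary, char_vocab: Vocabulary,
                   max_word_len: int, max_char_len: int) -> EncodedDataset:
    word_ids = np.array([encode(tokenize_words(t), word_vocab, max_word_len)
                         for t in texts], dtype=np.int64)
    char_ids = np.array([encode(tokenize_chars(t), char_vocab, max_char_len)
                         for t in texts], dtype=np.int64)
    return EncodedDataset(word_ids=word_ids, char_ids=char_ids,
                          labels=np.asarray(labels, dtype=np.int64))


# -- dataset readers ---------------------------------------------------

def read_cmedqa(path) -> Tuple[List[str], List[str]]:
    """CSV with header department,title,ask; text = title + " " + ask.

    Returns (texts, raw_labels) with labels as the department strings.
    """
    texts, labels = [], []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"department", "title", "ask"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected columns department,title,ask")
        for row in reader:
            title, ask = row["title"], row["ask"]
            texts.append(f"{title} {ask}" if ask else title)
            labels.append(row["department"])
    return texts, labels


def read_sentiment140(path) -> Tuple[List[str], List[str]]:
    """Headerless 6-field CSV (polarity,id,date,query,user,text)."""
    texts, labels = [], []
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if len(row) != 6:
                raise ValueError(f"{path}: row {i} has {len(row)} fields, expected 6")
            labels.append(row[0])
            texts.append(row[5])
    return texts, labels


def read_dataset(path, dialect: str) -> Tuple[List[str], List[str]]:
    if dialect == "cmedqa":
        return read_cmedqa(path)
    if dialect == "sentiment140":
        return read_sentiment140(path)
    raise ValueError(f"unknown dataset dialect {dialect!r}")


def label_encoder(raw_labels: Sequence[str]) -> dict:
    """Stable raw-label -> class-id map (sorted unique order)."""
    return {lab: i for i, lab in enumerate(sorted(set(raw_labels)))}
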