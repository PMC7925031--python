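"""Synthetic labeled corpora with plantable word- and char-level signal.

Background tokens are pronounceable consonant+vowel syllable strings.
Class signal is injected in one of four modes:

* ``word`` — each class owns a pool of ``n_markers_per_class`` marker
  tokens (background-style syllable strings, disjoint across classes
  and from the background vocabulary); with probability
  ``signal_strength`` one pool member is inserted at a random position.
  A pool of 1 gives a single decisive token per class; a large pool
  keeps the signal trivial for token-identity features while making it
  sample-inefficient to recover from character patterns, because each
  individual surface string is seen only a handful of times.
* ``char`` — each class owns a marker character (drawn from an alphabet
  disjoint from the syllable letters) embedded word-internally in a
  freshly sampled carrier string per document. Carriers are effectively
  unique, so frequency pruning (min_freq >= 2) evicts them from the
  word vocabulary and the word channel sees only <unk> there.
* ``split`` — the first half of the classes gets word signal, the second
  half char signal.
* ``none`` — no signal; chance is the ceiling.
"""

from __future__ import annotations

import csv
import itertools
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]
_MARKER_CHARS = "QXWJYHZCVK"  # disjoint from the syllable alphabet

SIGNAL_MODES = ("word", "char", "split", "none")


class CorpusConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CorpusSpec:
    n_classes: int = 3
    n_per_class: int = 50
    vocab_size: int = 120
    doc_length: Tuple[int, int] = (4, 8)
    signal_mode: str = "word"
    signal_strength: float = 0.9
    n_markers_per_class: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise CorpusConfigError("n_classes must be >= 2")
        if self.signal_mode not in SIGNAL_MODES:
            raise CorpusConfigError(f"signal_mode must be one of {SIGNAL_MODES}")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise CorpusConfigError("signal_strength must lie in [0, 1]")
        if self.doc_length[0] < 1 or self.doc_length[1] < self.doc_length[0]:
            raise CorpusConfigError("doc_length must be a valid (lo, hi) pair")
        if self.n_markers_per_class < 1:
            raise CorpusConfigError("n_markers_per_class must be >= 1")
        if self.vocab_size < 4 * self.n_classes:
            raise CorpusConfigError(
                f"vocab_size {self.vocab_size} too small to host {self.n_classes} "
                "distinct class markers on top of background tokens")

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "n_per_class": self.n_per_class,
            "vocab_size": self.vocab_size,
            "doc_length": list(self.doc_length),
            "signal_mode": self.signal_mode,
            "signal_strength": self.signal_strength,
            "n_markers_per_class": self.n_markers_per_class,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorpusSpec":
        d = dict(d)
        d["doc_length"] = tuple(d["doc_length"])
        return cls(**d)


@dataclass
class Document:
    label: int
    text: str


@dataclass
class Corpus:
    spec: CorpusSpec
    docs: List[Document]
    word_markers: Dict[int, List[str]] = field(default_factory=dict)
    char_markers: Dict[int, str] = field(default_factory=dict)

    def texts(self) -> List[str]:
        return [d.text for d in self.docs]

    def labels(self) -> List[int]:
        return [d.label for d in self.docs]


def _background_vocab(rng: np.random.Generator, size: int) -> List[str]:
    """Distinct 2-3 syllable strings, deterministic under the rng."""
    pool = ["".join(p) for p in itertools.product(_SYLLABLES, repeat=2)]
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in idx]


def _word_markers(rng: np.random.Generator, classes: Sequence[int],
                  n_per_class: int) -> Dict[int, List[str]]:
    """Disjoint marker pools of 3-syllable tokens (background is 2-syllable,
    so markers never collide with background strings)."""
    n_total = len(classes) * n_per_class
    space = len(_SYLLABLES) ** 3
    if n_total > space:
        raise CorpusConfigError("too many classes/markers for distinct word markers")
    flat_ids = rng.choice(space, size=n_total, replace=False)
    tokens = []
    for fid in flat_ids:
        a, rem = divmod(int(fid), len(_SYLLABLES) ** 2)
        b, c = divmod(rem, len(_SYLLABLES))
        tokens.append(_SYLLABLES[a] + _SYLLABLES[b] + _SYLLABLES[c])
    return {cls: tokens[j * n_per_class:(j + 1) * n_per_class]
            for j, cls in enumerate(classes)}


def _char_markers(classes: Sequence[int]) -> Dict[int, str]:
    if len(classes) > len(_MARKER_CHARS):
        raise CorpusConfigError("too many classes for distinct char markers")
    return {c: _MARKER_CHARS[i] for i, c in enumerate(classes)}


def _signal_classes(spec: CorpusSpec) -> Tuple[List[int], List[int]]:
    """(word-signal classes, char-signal classes) for a spec."""
    all_classes = list(range(spec.n_classes))
    if spec.signal_mode == "word":
        return all_classes, []
    if spec.signal_mode == "char":
        return [], all_classes
    if spec.signal_mode == "split":
        half = (spec.n_classes + 1) // 2
        return all_classes[:half], all_classes[half:]
    return [], []


def _carrier(rng: np.random.Generator, marker_char: str) -> str:
    """A fresh carrier token: random syllables around the marker char."""
    syl = [_SYLLABLES[i] for i in rng.choice(len(_SYLLABLES), size=4)]
    return syl[0] + syl[1] + marker_char + syl[2] + syl[3]


def generate_corpus(spec: CorpusSpec, subset: str = "train") -> Corpus:
    """Deterministic corpus for a spec.

    Marker assignment depends only on ``spec.seed``; document sampling
    additionally depends on ``subset``, so train/test splits share the
    same planted signal but not the same documents.
    """
    marker_rng = np.random.default_rng(spec.seed)
    vocab = _background_vocab(marker_rng, spec.vocab_size)
    word_classes, char_classes = _signal_classes(spec)
    word_markers = (_word_markers(marker_rng, word_classes, spec.n_markers_per_class)
                    if word_classes else {})
    char_markers = _char_markers(char_classes) if char_classes else {}

    # zlib.crc32 is stable across processes (str hash() is not)
    doc_rng = np.random.default_rng([spec.seed, zlib.crc32(subset.encode("utf-8"))])
    lo, hi = spec.doc_length
    docs: List[Document] = []
    for label in range(spec.n_classes):
        for _ in range(spec.n_per_class):
            length = int(doc_rng.integers(lo, hi + 1))
            tokens = [vocab[i] for i in doc_rng.integers(0, len(vocab), size=length)]
            if doc_rng.random() < spec.signal_strength:
                if label in word_markers:
                    pos = int(doc_rng.integers(0, length + 1))
                    pool = word_markers[label]
                    tokens.insert(pos, pool[int(doc_rng.integers(0, len(pool)))])
                elif label in char_markers:
                    pos = int(doc_rng.integers(0, length + 1))
                    tokens.insert(pos, _carrier(doc_rng, char_markers[label]))
            docs.append(Document(label=label, text=" ".join(tokens)))
    return Corpus(spec=spec, docs=docs,
                  word_markers=word_markers, char_markers=char_markers)


def generate_train_test(spec: CorpusSpec, n_test_per_class: Optional[int] = None
                        ) -> Tuple[Corpus, Corpus]:
    """Train and test corpora sharing the same planted markers."""
    train = generate_corpus(spec, subset="train")
    if n_test_per_class is None:
        n_test_per_class = max(1, spec.n_per_class // 4)
    test_spec = CorpusSpec(**{**spec.to_dict(), "n_per_class": n_test_per_class,
                              "doc_length": spec.doc_length})
    test = generate_corpus(test_spec, subset="test")
    return train, test


# -- rule-based probes -------------------------------------------------

def marker_rule_predict(texts: Sequence[str], markers, level: str,
                        n_classes: int, seed: int = 0) -> np.ndarray:
    """Predict by marker presence; fall back to a seeded uniform guess.

    ``level='word'`` matches whole tokens against each class's marker
    pool; ``level='char'`` matches marker characters anywhere in the
    text. Used to certify that planted signal is decodable by
    construction.
    """
    rng = np.random.default_rng(seed)
    preds = np.empty(len(texts), dtype=np.int64)
    for i, text in enumerate(texts):
        hits = []
        for cls, marker in markers.items():
            if level == "word":
                tokens = set(text.split())
                found = any(m in tokens for m in marker)
            else:
                found = marker in text
            if found:
                hits.append(cls)
        preds[i] = hits[0] if len(hits) == 1 else int(rng.integers(0, n_classes))
    return preds


# -- CSV emission ------------------------------------------------------

def write_dataset(corpus: Corpus, path, dialect: str = "cmedqa") -> None:
    """Emit the corpus in one of the supported reader dialects."""
    if not corpus.docs:
        raise ValueError("refusing to write an empty corpus")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "cmedqa":
            writer.writerow(["department", "title", "ask"])
            for doc in corpus.docs:
                tokens = doc.text.split()
                title, ask = tokens[0], " ".join(tokens[1:])
                writer.writerow([str(doc.label), title, ask])
        elif dialect == "sentiment140":
            for i, doc in enumerate(corpus.docs):
                writer.writerow([str(doc.label), str(i), "Mon Jan 01 00:00:00 UTC 2024",
                                 "NO_QUERY", f"user{i}", doc.text])
        else:
            raise ValueError(f"unknown dataset dialect {dialect!r}")
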