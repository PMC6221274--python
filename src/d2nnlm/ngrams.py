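"""Order-n vocabulary spaces and sparse document--n-gram matrices.

Each transcript is represented as one vector over the vocabulary of distinct
word n-grams (default binary presence; raw counts optional).  N-grams are
contiguous within-sentence word sequences; they never cross sentence
boundaries and no start/end padding is used.  For the higher orders of
interest here (n = 4, 5) the resulting document-term matrix is large and
sparse — the "deep language space" that is subsequently rank-reduced by SVD.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import LABELS, Transcript

NGram = tuple[str, ...]


def extract_ngrams(tokens: Sequence[str], n: int) -> list[NGram]:
    """All contiguous n-grams of one sentence, in order.

    A sentence of length L yields max(0, L - n + 1) n-grams.
    """
    if n < 1:
        raise ValueError(f"n-gram order must be >= 1, got {n}")
    return [tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1)]


def transcript_ngrams(transcript: Transcript, n: int) -> Counter:
    """Multiset of n-grams of one transcript (per-sentence, concatenated)."""
    c: Counter = Counter()
    for sent in transcript.sentences:
        c.update(extract_ngrams(sent, n))
    return c


@dataclass
class NGramVocabulary:
    """The order-n vocabulary space with per-class accounting.

    ``per_group_counts[label]`` is the number of *distinct* n-grams observed
    in that class; ``total_count`` is their sum over classes (a shared
    n-gram is counted once per class in which it occurs), and
    ``unique_count`` is the number of distinct n-grams pooled over classes,
    so ``unique_count <= total_count``.
    """

    order: int
    entries: list[NGram]
    per_group_counts: dict[str, int]
    index: dict[NGram, int] = field(repr=False, default_factory=dict)
    entry_classes: dict[NGram, tuple[str, ...]] = field(repr=False,
                                                        default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {g: i for i, g in enumerate(self.entries)}
        if len(self.index) != len(self.entries):
            raise ValueError("duplicate n-gram entries")
        for g in self.entries:
            if len(g) != self.order:
                raise ValueError(f"entry {g} is not an order-{self.order} n-gram")

    @property
    def unique_count(self) -> int:
        return len(self.entries)

    @property
    def total_count(self) -> int:
        return sum(self.per_group_counts.values())

    def to_tsv(self, path: str | Path) -> None:
        """Export as TSV: index, space-joined n-gram, classes it occurs in."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("index\tngram\tclasses\n")
            for i, g in enumerate(self.entries):
                classes = ",".join(self.entry_classes.get(g, ()))
                fh.write(f"{i}\t{' '.join(g)}\t{classes}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, order: int) -> "NGramVocabulary":
        entries, entry_classes = [], {}
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                _, gram, classes = line.rstrip("\n").split("\t")
                g = tuple(gram.split(" "))
                entries.append(g)
                if classes:
                    entry_classes[g] = tuple(classes.split(","))
        per_group: dict[str, int] = {}
        for cls_tuple in entry_classes.values():
            for lab in cls_tuple:
                per_group[lab] = per_group.get(lab, 0) + 1
        return cls(order=order, entries=entries, per_group_counts=per_group,
                   entry_classes=entry_classes)


def build_vocabulary(transcripts: Sequence[Transcript], n: int) -> NGramVocabulary:
    """Build the order-n vocabulary over a labeled transcript collection.

    Entry order is deterministic: first occurrence over transcripts in the
    given sequence, sentences in order.  Distinct-n-gram counts are kept per
    class (type-level, not token-level).
    """
    if n < 1:
        raise ValueError(f"n-gram order must be >= 1, got {n}")
    if not transcripts:
        raise ValueError("at least one transcript required")
    entries: list[NGram] = []
    index: dict[NGram, int] = {}
    per_class: dict[str, set[NGram]] = {lab: set() for lab in LABELS}
    for t in transcripts:
        for sent in t.sentences:
            for g in extract_ngrams(sent, n):
                if g not in index:
                    index[g] = len(entries)
                    entries.append(g)
                per_class[t.label].add(g)
    counts = {lab: len(s) for lab, s in per_class.items() if s}
    entry_classes = {
        g: tuple(lab for lab in LABELS if g in per_class[lab]) for g in entries}
    return NGramVocabulary(order=n, entries=entries, per_group_counts=counts,
                           index=index, entry_classes=entry_classes)


def vectorize(
    transcripts: Sequence[Transcript],
    vocab: NGramVocabulary,
    mode: str = "binary",
) -> sp.csr_matrix:
    """Document--n-gram matrix: one row per transcript, one column per entry.

    ``mode="binary"`` stores presence (0/1); ``mode="count"`` raw
    occurrence counts.  N-grams absent from the vocabulary are ignored
    (zero contribution) — this is how out-of-vocabulary material in held-out
    transcripts is handled.
    """
    if mode not in ("binary", "count"):
        raise ValueError(f"unsupported mode: {mode!r}")
    rows, cols, vals = [], [], []
    for i, t in enumerate(transcripts):
        for g, c in transcript_ngrams(t, vocab.order).items():
            j = vocab.index.get(g)
            if j is None:
                continue
            rows.append(i)
            cols.append(j)
            vals.append(1 if mode == "binary" else c)
    mat = sp.csr_matrix(
        (np.asarray(vals, dtype=np.float64), (rows, cols)),
        shape=(len(transcripts), vocab.unique_count),
    )
    return mat


def export_matrix(matrix: sp.spmatrix, transcripts: Sequence[Transcript],
                  vocab: NGramVocabulary, prefix: str | Path) -> None:
    """Write a document-term matrix as Matrix Market plus id sidecars."""
    prefix = Path(prefix)
    from scipy.io import mmwrite

    mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(matrix))
    prefix.with_suffix(".rows.txt").write_text(
        "".join(t.id + "\n" for t in transcripts), encoding="utf-8")
    prefix.with_suffix(".cols.txt").write_text(
        "".join(" ".join(g) + "\n" for g in vocab.entries), encoding="utf-8")


class NGramVectorizer(BaseEstimator, TransformerMixin):
    """Transcripts -> sparse document--n-gram matrix (sklearn transformer).

    ``fit`` builds the order-``n`` vocabulary from the training transcripts;
    ``transform`` maps any transcript list onto that fixed vocabulary,
    dropping out-of-vocabulary n-grams.

    Parameters
    ----------
    n : n-gram order (4 and 5 are the orders of interest).
    mode : "binary" presence indicators (default) or raw "count"s.
    """

    def __init__(self, n: int = 4, mode: str = "binary"):
        self.n = n
        self.mode = mode

    def fit(self, X: Sequence[Transcript], y=None) -> "NGramVectorizer":
        self.vocabulary_ = build_vocabulary(list(X), self.n)
        return self

    def transform(self, X: Sequence[Transcript]) -> sp.csr_matrix:
        if not hasattr(self, "vocabulary_"):
            raise RuntimeError("NGramVectorizer is not fitted")
        return vectorize(list(X), self.vocabulary_, mode=self.mode)

    def get_feature_names_out(self, input_features=None):
        return np.asarray([" ".join(g) for g in self.vocabulary_.entries],
                          dtype=object)
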