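"""Conventional class-conditional n-gram language-model classifier.

The non-neural baseline: one add-one-smoothed n-gram model per class, fit
on that class's training transcripts over the pooled unique-n-gram
vocabulary.  A test transcript is scored under each class by the mean
per-n-gram log2 probability, predicted by likelihood ratio (ties go to
control), and the confidence used for ranking/AUC is
score(positive) - score(control).

Unseen n-grams at test time map to a single smoothed unseen bucket, which
by default is counted as one extra vocabulary outcome so that each class's
smoothed distribution (vocabulary entries plus the bucket) sums exactly
to 1; ``unseen_bucket=False`` gives plain add-one over the vocabulary only.
"""

from __future__ import annotations

import math
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .corpus import CONTROL, LABELS, POSITIVE, Transcript
from .ngrams import NGram, transcript_ngrams


class NGramLMClassifier(BaseEstimator, ClassifierMixin):
    """Likelihood-ratio classifier over per-class smoothed n-gram models.

    Parameters
    ----------
    n : n-gram order (the classic baseline uses n = 4).
    alpha : additive smoothing constant (1.0 = add-one / Laplace).
    unseen_bucket : include one extra outcome for unseen n-grams so each
        class distribution normalizes exactly (default True).
    """

    def __init__(self, n: int = 4, alpha: float = 1.0, unseen_bucket: bool = True):
        self.n = n
        self.alpha = alpha
        self.unseen_bucket = unseen_bucket

    def fit(self, X: Sequence[Transcript], y=None) -> "NGramLMClassifier":
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        labels = list(y) if y is not None else [t.label for t in X]
        if len(labels) != len(X):
            raise ValueError("X and y differ in length")
        counts: dict[str, Counter] = {lab: Counter() for lab in LABELS}
        for t, lab in zip(X, labels):
            if lab not in counts:
                raise ValueError(f"unknown label {lab!r}")
            counts[lab].update(transcript_ngrams(t, self.n))
        for lab in LABELS:
            if not counts[lab]:
                raise ValueError(f"no order-{self.n} n-grams in class {lab!r}")
        vocab: set[NGram] = set()
        for c in counts.values():
            vocab.update(c)
        self.classes_ = np.asarray(sorted(LABELS))
        self.counts_ = counts
        self.totals_ = {lab: sum(c.values()) for lab, c in counts.items()}
        self.vocabulary_ = vocab
        self.n_outcomes_ = len(vocab) + (1 if self.unseen_bucket else 0)
        return self

    # -- probabilities ------------------------------------------------------------

    def ngram_log2_prob(self, gram: NGram, label: str) -> float:
        """Smoothed log2 P(gram | class); unseen grams use the bucket count 0."""
        if not hasattr(self, "counts_"):
            raise RuntimeError("NGramLMClassifier is not fitted")
        count = self.counts_[label].get(gram, 0)
        denom = self.totals_[label] + self.alpha * self.n_outcomes_
        return math.log2((count + self.alpha) / denom)

    def score_transcript(self, transcript: Transcript, label: str) -> float:
        """Mean per-n-gram log2 probability of the transcript under a class."""
        grams = transcript_ngrams(transcript, self.n)
        total = sum(grams.values())
        if total == 0:
            raise ValueError(
                f"transcript {transcript.id!r} has no n-grams of order {self.n}")
        logp = sum(c * self.ngram_log2_prob(g, label) for g, c in grams.items())
        return logp / total

    # -- sklearn API --------------------------------------------------------------

    def decision_function(self, X: Sequence[Transcript]) -> np.ndarray:
        """Confidence per transcript: score(positive) - score(control)."""
        return np.asarray([
            self.score_transcript(t, POSITIVE) - self.score_transcript(t, CONTROL)
            for t in X])

    def predict(self, X: Sequence[Transcript]) -> np.ndarray:
        conf = self.decision_function(X)
        # strict inequality: ties predict control
        return np.where(conf > 0, POSITIVE, CONTROL)

    def confidence(self, X: Sequence[Transcript], positive_label=POSITIVE) -> np.ndarray:
        d = self.decision_function(X)
        return d if positive_label == POSITIVE else -d

    def export_counts(self, path_prefix: str | Path) -> None:
        """Write per-class n-gram count tables as TSV."""
        for lab in LABELS:
            rows = [{"ngram": " ".join(g), "count": c}
                    for g, c in sorted(self.counts_[lab].items())]
            pd.DataFrame(rows, columns=["ngram", "count"]).to_csv(
                f"{path_prefix}.{lab}.tsv", sep="\t", index=False)


def fit_ngram_lm(transcripts: Sequence[Transcript], n: int = 4,
                 alpha: float = 1.0, unseen_bucket: bool = True) -> NGramLMClassifier:
    """Fit the class-conditional n-gram LM on labeled transcripts."""
    return NGramLMClassifier(n=n, alpha=alpha, unseen_bucket=unseen_bucket).fit(
        list(transcripts))


def classify_by_likelihood(model: NGramLMClassifier, transcript: Transcript):
    """Per-class scores, confidence, and predicted label for one transcript."""
    scores = {lab: model.score_transcript(transcript, lab) for lab in LABELS}
    conf = scores[POSITIVE] - scores[CONTROL]
    label = POSITIVE if conf > 0 else CONTROL
    return scores, conf, label
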