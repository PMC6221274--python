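"""Percent error, perplexity, and leave-pair-out cross-validated AUC.

Leave-pair-out cross-validation (LPOCV) holds out every (positive, control)
pair once, fits the model on the remaining transcripts, and scores the held
pair.  The pairwise comparisons give the Wilcoxon-Mann-Whitney estimate of
the AUC,

    AUC = (1 / |P||N|) * sum_{p in P} sum_{n in N} c(p, n),

with c(p, n) = 1 when the positive member outscores the control member and
0 otherwise (ties score 0 by default; a conventional 0.5-tie mode is
available).  The AUC variance uses the Hanley & McNeil (1982) closed form
with Q1 = A/(2-A) and Q2 = 2A^2/(1+A); standard errors, normal-theory
confidence intervals, and a two-sided z-test of A against the chance value
0.5 follow from it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import json
import math
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def percent_error(predicted, truth) -> float:
    """Misclassification rate as a percentage: 100 * #wrong / #examples."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and true labels differ in length")
    if predicted.size == 0:
        raise ValueError("empty input")
    return float(100.0 * np.mean(predicted != truth))


def squared_error_percent(prob_true, truth_indicator=None) -> float:
    """Mean squared error of the true-class probability, as a percentage.

    Alternative reading of "percentage MSE": 100 * mean((1 - q)^2) where q
    is the probability assigned to the true class.
    """
    q = np.asarray(prob_true, dtype=float)
    if q.size == 0:
        raise ValueError("empty input")
    return float(100.0 * np.mean((1.0 - q) ** 2))


def perplexity(true_class_probabilities, base: float = 2.0) -> float:
    """base ** cross-entropy of the probabilities assigned to true outcomes.

    B(q) = -(1/N) sum_i log_base q(x_i); returns base ** B(q).  For proper
    binary probabilities this is 1 for a perfect predictor and 2 for an
    uninformative one.
    """
    q = np.asarray(true_class_probabilities, dtype=float)
    if q.size == 0:
        raise ValueError("at least one probability required")
    if np.any(q <= 0) or np.any(q > 1):
        raise ValueError("probabilities must lie in (0, 1]")
    b = -np.mean(np.log(q) / np.log(base))
    return float(base ** b)


def lpocv_pairs(positive_ids: Sequence, negative_ids: Sequence
                ) -> Iterator[tuple[tuple, list]]:
    """All |P| x |N| (test pair, training remainder) rounds.

    Yields ``((p, n), remainder)`` where the remainder lists every id except
    the held pair, positives first, in input order.
    """
    P, N = list(positive_ids), list(negative_ids)
    if len(P) < 2 or len(N) < 2:
        raise ValueError("LPOCV requires at least 2 ids per class")
    if set(P) & set(N):
        raise ValueError("positive and negative id sets overlap")
    for p in P:
        for n in N:
            remainder = [x for x in P if x != p] + [x for x in N if x != n]
            yield (p, n), remainder


def pairwise_auc(pos_scores, neg_scores, tie_value: float = 0.0) -> float:
    """AUC by direct pairwise counting over two score sets."""
    pos = np.asarray(pos_scores, dtype=float)[:, None]
    neg = np.asarray(neg_scores, dtype=float)[None, :]
    wins = (pos > neg).sum() + tie_value * (pos == neg).sum()
    return float(wins / (pos.size * neg.size))


@dataclass
class EvalReport:
    """All evaluation quantities for one model on one dataset."""

    percent_error: float | None = None
    perplexity: float | None = None
    auc: float | None = None
    sd: float | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n_pos: int | None = None
    n_neg: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=1, sort_keys=True) + "\n",
            encoding="utf-8")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([asdict(self)]).to_csv(path, sep="\t", index=False)


def lpocv_auc(
    trainer: Callable,
    positives: Sequence,
    negatives: Sequence,
    score_fn: Callable | None = None,
    tie_value: float = 0.0,
    seed: int = 0,
    max_rounds: int | None = None,
    record: list | None = None,
) -> EvalReport:
    """Leave-pair-out cross-validated AUC with variance and significance.

    Parameters
    ----------
    trainer:
        ``trainer(train_positives, train_negatives, seed) -> model`` where
        the model has a ``confidence``-style callable supplied as
        ``score_fn(model, example) -> float``.  Per-round seeds are derived
        deterministically from ``seed`` and the round index.
    positives, negatives:
        The two labeled example collections (any objects the trainer
        understands).
    tie_value:
        Contribution of a tied pair: 0.0 (literal counting, default) or the
        conventional 0.5.
    max_rounds:
        Optional seeded uniform subsample of rounds for expensive trainers;
        full |P| x |N| enumeration is the default protocol.
    record:
        Optional list collecting per-round dicts (p index, n index, scores,
        c value) for export.
    """
    if score_fn is None:
        raise ValueError("score_fn is required")
    nP, nN = len(positives), len(negatives)
    if nP < 2 or nN < 2:
        raise ValueError("LPOCV requires at least 2 examples per class")
    rounds = [(i, j) for i in range(nP) for j in range(nN)]
    if max_rounds is not None and max_rounds < len(rounds):
        picker = np.random.default_rng(seed)
        keep = picker.choice(len(rounds), size=max_rounds, replace=False)
        rounds = [rounds[k] for k in sorted(keep)]

    total = 0.0
    for r, (i, j) in enumerate(rounds):
        train_pos = [p for k, p in enumerate(positives) if k != i]
        train_neg = [n for k, n in enumerate(negatives) if k != j]
        round_seed = (int(seed) * 100003 + r) % (2 ** 31)
        try:
            model = trainer(train_pos, train_neg, round_seed)
            sp_ = float(score_fn(model, positives[i]))
            sn_ = float(score_fn(model, negatives[j]))
        except Exception as exc:
            raise RuntimeError(f"LPOCV trainer failed in round {r} "
                               f"(pair p={i}, n={j}): {exc}") from exc
        c = 1.0 if sp_ > sn_ else (tie_value if sp_ == sn_ else 0.0)
        total += c
        if record is not None:
            record.append({"round": r, "p_index": i, "n_index": j,
                           "pos_score": sp_, "neg_score": sn_, "c": c})
    auc = total / len(rounds)
    var = auc_variance(auc, nP, nN)
    report = EvalReport(auc=auc, sd=math.sqrt(var), n_pos=nP, n_neg=nN)
    se, (lo, hi), p = significance(auc, var, nP, nN)
    report.se, report.ci_low, report.ci_high, report.p_value = se, lo, hi, p
    return report


def auc_variance(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil (1982) variance of a Mann-Whitney AUC estimate.

    var = [A(1-A) + (nP-1)(Q1 - A^2) + (nN-1)(Q2 - A^2)] / (nP * nN)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A).
    """
    A = float(auc)
    if not 0.0 <= A <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {A}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    q1 = A / (2.0 - A)
    q2 = 2.0 * A * A / (1.0 + A)
    var = (A * (1.0 - A) + (n_pos - 1) * (q1 - A * A)
           + (n_neg - 1) * (q2 - A * A)) / (n_pos * n_neg)
    return float(max(var, 0.0))


def significance(
    auc: float,
    variance: float,
    n_pos: int,
    n_neg: int,
    alpha: float = 0.05,
    se_denominator: str = "total",
) -> tuple[float, tuple[float, float], float]:
    """Standard error, normal CI, and two-sided p-value against AUC = 0.5.

    ``se_denominator`` selects the sd -> SE conversion: ``"total"`` divides
    the standard deviation by sqrt(nP + nN) (default), ``"pairs"`` by
    sqrt(nP * nN).  CI bounds are reported unclipped; callers may truncate
    for display.
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    sd = math.sqrt(variance)
    if se_denominator == "total":
        se = sd / math.sqrt(n_pos + n_neg)
    elif se_denominator == "pairs":
        se = sd / math.sqrt(n_pos * n_neg)
    else:
        raise ValueError("se_denominator must be 'total' or 'pairs'")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ci = (auc - z * se, auc + z * se)
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    return se, ci, float(min(p, 1.0))


def holdout_report(model, X_test, y_test, positive_label) -> EvalReport:
    """Percent error and perplexity of a fitted classifier on a held-out set."""
    y = np.asarray(y_test)
    pred = model.predict(X_test)
    probs = model.predict_proba(X_test)
    clf = model[-1] if hasattr(model, "steps") else model
    cols = np.searchsorted(clf.classes_, y)
    q = probs[np.arange(len(y)), cols]
    return EvalReport(percent_error=percent_error(pred, y),
                      perplexity=perplexity(np.clip(q, 1e-12, 1.0)))
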