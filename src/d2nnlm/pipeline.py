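"""End-to-end assembly: load -> features -> (SVD) -> split -> train -> evaluate.

The three neural variants and the n-gram LM baseline are assembled as
sklearn estimators:

* ``nnlm``     — NGramVectorizer -> NeuralLMClassifier(1 hidden layer)
* ``dnnlm``    — NGramVectorizer -> NeuralLMClassifier(3 hidden layers)
* ``d2nnlm``   — NGramVectorizer -> SVDReducer -> NeuralLMClassifier(3 layers)
* ``ngram_lm`` — NGramLMClassifier

so a "trainer" for leave-pair-out evaluation is simply a clone-and-fit of
the chosen estimator with a per-round derived seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from . import __version__
from .baseline import NGramLMClassifier
from .corpus import POSITIVE, Transcript, load_transcripts, make_split
from .evaluation import EvalReport, holdout_report, lpocv_auc
from .network import NeuralLMClassifier, grid_search, save_model
from .ngrams import NGramVectorizer
from .reduction import SVDReducer

logger = logging.getLogger(__name__)

MODELS = ("nnlm", "dnnlm", "d2nnlm", "ngram_lm")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Unusable input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one run byte-for-byte."""

    positive_dir: str = ""
    control_dir: str = ""
    output_dir: str = "run"
    format: str = "plain"
    model: str = "d2nnlm"
    ngram_order: int = 4
    hidden_layers: int | None = None  # None = variant default (1 or 3)
    hidden_units_grid: tuple[int, ...] = (5, 11, 19)
    batch_size_grid: tuple[int, ...] = (9,)
    proportions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    evaluation: str = "holdout"  # or "lpocv"
    svd: bool = True
    svd_k: int | str = "auto"
    vector_mode: str = "binary"
    epochs: int = 500
    learning_rate: float = 0.01
    l1: float = 1e-4
    l2: float = 1e-4
    select_on: str = "validation"
    tie_value: float = 0.0
    fit_scope: str = "train_only"  # or "full_corpus" (leaks test vocabulary!)
    seed: int = 0

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ConfigError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.model == "d2nnlm" and not self.svd:
            raise ConfigError("d2nnlm requires SVD-reduced features (svd=True)")
        if self.model in ("nnlm", "dnnlm") and self.svd:
            raise ConfigError(
                f"{self.model} consumes the raw sparse n-gram vectors; set svd=False")
        if self.ngram_order < 1:
            raise ConfigError("ngram_order must be >= 1")
        if self.fit_scope not in ("train_only", "full_corpus"):
            raise ConfigError("fit_scope must be 'train_only' or 'full_corpus'")
        if self.fit_scope == "full_corpus" and self.evaluation == "lpocv":
            raise ConfigError("full_corpus feature fitting is a holdout-only mode")

    def manifest(self) -> dict:
        cfg = asdict(self)
        blob = json.dumps(cfg, sort_keys=True)
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "package_version": __version__,
        }


def make_model(
    model: str = "d2nnlm",
    ngram_order: int = 4,
    hidden_layers: int | None = None,
    hidden_units: int = 11,
    batch_size: int = 9,
    epochs: int = 500,
    learning_rate: float = 0.01,
    l1: float = 1e-4,
    l2: float = 1e-4,
    svd_k: int | str = "auto",
    vector_mode: str = "binary",
    random_state: int = 0,
):
    """Build the estimator for one model variant (unfitted)."""
    if model == "ngram_lm":
        return NGramLMClassifier(n=ngram_order)
    if model not in MODELS:
        raise ConfigError(f"unknown model {model!r}")
    depth = hidden_layers if hidden_layers is not None else (1 if model == "nnlm" else 3)
    net = NeuralLMClassifier(
        hidden_layers=depth, hidden_units=hidden_units, epochs=epochs,
        batch_size=batch_size, learning_rate=learning_rate, l1=l1, l2=l2,
        random_state=random_state)
    steps = [("ngrams", NGramVectorizer(n=ngram_order, mode=vector_mode))]
    if model == "d2nnlm":
        # the network consumes the left-singular matrix itself (O(1) entries)
        steps.append(("svd", SVDReducer(k=svd_k, scale="unit")))
    steps.append(("net", net))
    return Pipeline(steps)


def model_confidence(model, transcripts: Sequence[Transcript]) -> np.ndarray:
    """Ranking score per transcript: probability (or log-LR) of the positive class."""
    if isinstance(model, NGramLMClassifier):
        return model.confidence(list(transcripts))
    probs = model.predict_proba(list(transcripts))
    clf = model[-1] if isinstance(model, Pipeline) else model
    col = int(np.flatnonzero(clf.classes_ == POSITIVE)[0])
    return probs[:, col]


def _labels(transcripts: Sequence[Transcript]) -> np.ndarray:
    return np.asarray([t.label for t in transcripts])


def lpocv_evaluate(estimator, transcripts: Sequence[Transcript], seed: int = 0,
                   tie_value: float = 0.0, max_rounds: int | None = None,
                   record: list | None = None) -> EvalReport:
    """Full leave-pair-out evaluation of an estimator on labeled transcripts."""
    pos = [t for t in transcripts if t.label == POSITIVE]
    neg = [t for t in transcripts if t.label != POSITIVE]

    def trainer(train_pos, train_neg, round_seed):
        model = clone(estimator)
        try:  # neural variants reseed per round; the count-based LM has no RNG
            if isinstance(model, Pipeline):
                model.set_params(net__random_state=round_seed)
            else:
                model.set_params(random_state=round_seed)
        except ValueError:
            pass
        return model.fit(train_pos + train_neg, _labels(train_pos + train_neg))

    def score_fn(model, transcript):
        return float(model_confidence(model, [transcript])[0])

    return lpocv_auc(trainer, pos, neg, score_fn=score_fn, tie_value=tie_value,
                     seed=seed, max_rounds=max_rounds, record=record)


def depth_sweep(
    transcripts: Sequence[Transcript],
    layers: Sequence[int] = (2, 3, 4, 5),
    model: str = "d2nnlm",
    ngram_order: int = 4,
    hidden_units: int = 11,
    batch_size: int = 9,
    proportions=(0.5, 0.25, 0.25),
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Held-out percent error and perplexity as the hidden-layer count varies.

    Reuses one stratified split for all depths so the curves are comparable.
    """
    split = make_split(transcripts, proportions, seed=seed)
    train = split.subset(transcripts, "train")
    test = split.subset(transcripts, "test")
    batch_size = min(batch_size, len(train))
    rows = []
    for depth in layers:
        est = make_model(model=model, ngram_order=ngram_order,
                         hidden_layers=int(depth), hidden_units=hidden_units,
                         batch_size=batch_size, random_state=seed, **kwargs)
        est.fit(train, _labels(train))
        rep = holdout_report(est, test, _labels(test), POSITIVE)
        rows.append({"hidden_layers": int(depth),
                     "percent_error": rep.percent_error,
                     "perplexity": rep.perplexity})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig,
                 transcripts: Sequence[Transcript] | None = None) -> EvalReport:
    """Execute one configured run and write its artifacts.

    Writes to ``config.output_dir``: ``manifest.json``, ``split.json``,
    ``report.json``/``report.tsv``, ``grid.tsv`` (neural models), the model
    archive, and for LPOCV a per-round score dump.  Fully reproducible from
    the config and seed.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if transcripts is None:
        if not config.positive_dir or not config.control_dir:
            raise ConfigError("positive_dir and control_dir are required")
        transcripts = (
            load_transcripts(config.positive_dir, config.format, "positive")
            + load_transcripts(config.control_dir, config.format, "control"))
    transcripts = list(transcripts)
    if not any(t.label == POSITIVE for t in transcripts) or \
       not any(t.label != POSITIVE for t in transcripts):
        raise DataError("need transcripts of both classes")

    (out / "manifest.json").write_text(
        json.dumps(config.manifest(), indent=1, sort_keys=True) + "\n",
        encoding="utf-8")

    neural = config.model != "ngram_lm"

    if config.evaluation == "lpocv":
        est = make_model(
            model=config.model, ngram_order=config.ngram_order,
            hidden_layers=config.hidden_layers,
            hidden_units=config.hidden_units_grid[0],
            batch_size=config.batch_size_grid[0], epochs=config.epochs,
            learning_rate=config.learning_rate, l1=config.l1, l2=config.l2,
            svd_k=config.svd_k, vector_mode=config.vector_mode,
            random_state=config.seed)
        if neural and (len(config.hidden_units_grid) > 1
                       or len(config.batch_size_grid) > 1):
            est = _select_by_grid(est, transcripts, config)
        record: list = []
        report = lpocv_evaluate(est, transcripts, seed=config.seed,
                                tie_value=config.tie_value, record=record)
        pd.DataFrame(record).to_csv(out / "rounds.tsv", sep="\t", index=False)
    else:
        split = make_split(transcripts, config.proportions, seed=config.seed)
        (out / "split.json").write_text(json.dumps({
            "train": list(split.train_ids), "test": list(split.test_ids),
            "validation": list(split.validation_ids)}, indent=1) + "\n",
            encoding="utf-8")
        train = split.subset(transcripts, "train")
        test = split.subset(transcripts, "test")
        val = split.subset(transcripts, "validation")
        base = make_model(
            model=config.model, ngram_order=config.ngram_order,
            hidden_layers=config.hidden_layers, epochs=config.epochs,
            learning_rate=config.learning_rate, l1=config.l1, l2=config.l2,
            svd_k=config.svd_k, vector_mode=config.vector_mode,
            random_state=config.seed)
        test_input = test
        if neural and config.fit_scope == "full_corpus":
            # mimics protocols that decompose the pooled corpus before
            # splitting; the held-out vocabulary leaks into the features
            logger.warning(
                "fit_scope=full_corpus: n-gram vocabulary and SVD basis are "
                "fitted on ALL transcripts including the held-out sets")
            features = Pipeline(base.steps[:-1]).fit(transcripts)
            Xtr, Xv, Xte = (features.transform(s) for s in (train, val, test))
            best, best_params, table = grid_search(
                clone(base.steps[-1][1]), (Xtr, _labels(train)),
                (Xv, _labels(val)), (Xte, _labels(test)),
                config.hidden_units_grid, config.batch_size_grid, POSITIVE,
                select_on=config.select_on)
            table.to_csv(out / "grid.tsv", sep="\t", index=False)
            save_model(best, out / "model.zip")
            est, test_input = best, Xte
        elif neural:
            best, best_params, table = grid_search(
                base, (train, _labels(train)), (val, _labels(val)),
                (test, _labels(test)), config.hidden_units_grid,
                config.batch_size_grid, POSITIVE, select_on=config.select_on,
                h_param="net__hidden_units", b_param="net__batch_size")
            table.to_csv(out / "grid.tsv", sep="\t", index=False)
            save_model(best[-1], out / "model.zip")
            est = best
        else:
            est = base.fit(train, _labels(train))
            est.export_counts(out / "ngram_lm")
        report = holdout_report(est, test_input, _labels(test), POSITIVE)

    report.to_json(out / "report.json")
    report.to_tsv(out / "report.tsv")
    return report


def _select_by_grid(est, transcripts, config: RunConfig):
    """Pick (H, batch) once on a stratified split, then use it for LPOCV."""
    split = make_split(transcripts, config.proportions, seed=config.seed)
    train = split.subset(transcripts, "train")
    test = split.subset(transcripts, "test")
    val = split.subset(transcripts, "validation")
    _, best_params, _ = grid_search(
        est, (train, _labels(train)), (val, _labels(val)),
        (test, _labels(test)), config.hidden_units_grid,
        config.batch_size_grid, POSITIVE, select_on=config.select_on,
        h_param="net__hidden_units", b_param="net__batch_size")
    est = clone(est)
    est.set_params(net__hidden_units=best_params["hidden_units"],
                   net__batch_size=best_params["batch_size"])
    return est
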