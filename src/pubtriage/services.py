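"""The three user-facing operations: Train, Classify, Search Keywords.

Each service is a plain function returning a JSON-serializable report; the
CLI is a thin wrapper.  ``service_train`` runs the full pipeline — read,
balance, select paragraphs, split, build vocabulary (training side only),
encode, train, evaluate — persisting the model and vocabulary artifacts.
``service_classify`` short-circuits off-topic articles (no keyword
paragraph) to an irrelevant verdict without ever loading the model.  One
structured log line is emitted per pipeline stage with its counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_io import (
    RELEVANT,
    Article,
    KeywordSet,
    load_artifacts,
    read_keywords,
    read_training_dir,
    save_artifacts,
)
from .errors import CorpusError, PipelineStageError, PubtriageError
from .model import TrainConfig, build_mlp, cross_validate, evaluate, forward, train
from .preprocess import (
    DEFAULT_VOCAB_SIZE,
    build_vocabulary,
    encode_one_hot,
    keyword_hits,
    normalize_tokens,
    select_relevant_paragraphs,
)
from .sampling import make_split_plan, undersample_balance
from .thresholds import ThresholdConfig, assign_label

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the Train service needs beyond the input paths."""

    seed: int = 0
    epochs: int = 30
    learning_rate: float = 0.01
    batch_size: int = 8
    hidden_units: int = 64
    hidden_layers: int = 2
    vocab_size: int = DEFAULT_VOCAB_SIZE
    test_frac: float = 0.10
    folds: int = 10
    run_cv: bool = False

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
        )


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except PubtriageError as exc:
        raise PipelineStageError(name, exc) from exc


def service_train(
    training_dir: str | Path,
    keywords_file: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full training pipeline and persist artifacts under ``out_dir``.

    The report mirrors the Train response shape: train/test accuracy and
    loss, epochs, sample counts, the model version, and the per-test-sample
    ``[true value, classification value]`` pairs.
    """
    cfg = config or PipelineConfig()
    corpus = _stage("read_corpus", read_training_dir, training_dir)
    keywords = _stage("read_keywords", read_keywords, keywords_file)
    logger.info("stage=read_corpus articles=%d counts=%s",
                len(corpus), corpus.class_counts)

    balanced = _stage("balance", undersample_balance, corpus, cfg.seed)
    logger.info("stage=balance articles=%d counts=%s",
                len(balanced), balanced.class_counts)

    def _select():
        lemmas_by_id: dict[str, list[str]] = {}
        kept = 0
        for article in balanced.articles:
            paragraphs = select_relevant_paragraphs(article, keywords)
            kept += len(paragraphs)
            lemmas: list[str] = []
            for p in paragraphs:
                lemmas.extend(normalize_tokens(p))
            lemmas_by_id[article.id] = lemmas
        return lemmas_by_id, kept

    lemmas_by_id, n_kept = _stage("select_paragraphs", _select)
    logger.info("stage=select_paragraphs paragraphs_kept=%d", n_kept)

    plan = _stage("split", make_split_plan, balanced,
                  test_frac=cfg.test_frac, k=cfg.folds, seed=cfg.seed)
    vocab = _stage(
        "build_vocabulary",
        build_vocabulary,
        (lemmas_by_id[i] for i in plan.trainval_ids),
        cfg.vocab_size,
    )
    logger.info("stage=build_vocabulary size=%d", len(vocab))

    def _encode():
        label_of = {a.id: a.label for a in balanced.articles}
        rows = {i: encode_one_hot(lemmas_by_id[i], vocab) for i in lemmas_by_id}
        X_tr = np.stack([rows[i] for i in plan.trainval_ids])
        y_tr = np.array([1.0 if label_of[i] == RELEVANT else 0.0
                         for i in plan.trainval_ids])
        X_te = np.stack([rows[i] for i in plan.test_ids])
        y_te = np.array([1.0 if label_of[i] == RELEVANT else 0.0
                         for i in plan.test_ids])
        return X_tr, y_tr, X_te, y_te

    X_train, y_train, X_test, y_test = _stage("encode", _encode)
    logger.info("stage=encode n_train=%d n_test=%d dim=%d",
                len(y_train), len(y_test), len(vocab))

    def _fit():
        model = build_mlp(len(vocab), hidden_units=cfg.hidden_units,
                          hidden_layers=cfg.hidden_layers, seed=cfg.seed)
        return train(model, X_train, y_train, cfg.train_config())

    model, history = _stage("train", _fit)
    cm, test_metrics, per_sample = _stage("evaluate", evaluate, model, X_test, y_test)
    logger.info("stage=evaluate test_accuracy=%.4f test_loss=%.4f",
                test_metrics.accuracy, test_metrics.loss)

    report = {
        "version": model.version,
        "epochs": cfg.epochs,
        "n_train": int(len(y_train)),
        "n_test": int(len(y_test)),
        "train": {
            "accuracy": history[-1]["accuracy"] if history else None,
            "loss": history[-1]["loss"] if history else None,
        },
        "test": {"accuracy": test_metrics.accuracy, "loss": test_metrics.loss},
        "confusion_matrix": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "test_results": per_sample,
        "counts": {
            "articles_read": len(corpus),
            "articles_balanced": len(balanced),
            "paragraphs_kept": n_kept,
            "vocabulary_size": len(vocab),
        },
        "history": history,
    }
    if cfg.run_cv:
        id_row = {i: r for r, i in enumerate(plan.trainval_ids)}
        fold_idx = [np.array([id_row[i] for i in fold]) for fold in plan.folds]
        cv = _stage("cross_validate", cross_validate, X_train, y_train,
                    fold_idx, cfg.train_config(), cfg.hidden_units, cfg.hidden_layers)
        accs = [m.accuracy for m in cv]
        losses = [m.loss for m in cv]
        report["validation"] = {
            "folds": cfg.folds,
            "accuracy_mean": float(np.mean(accs)),
            "accuracy_std": float(np.std(accs)),
            "loss_mean": float(np.mean(losses)),
            "loss_std": float(np.std(losses)),
        }
    _stage("save_artifacts", save_artifacts, model, vocab, out_dir)
    return report


def service_classify(
    article: Article | list[str],
    model_dir: str | Path,
    keywords: KeywordSet,
    thresholds: ThresholdConfig | None = None,
) -> dict:
    """Classify one article; off-topic articles never touch the model.

    Returns ``{"relevant": false, "reason": "off-topic"}`` when no paragraph
    contains a keyword (the model is not even loaded), otherwise the
    relevance likelihood, the four-way triage band, and the model version.
    """
    if not isinstance(article, Article):
        article = Article(id="query", paragraphs=list(article))
    selected = select_relevant_paragraphs(article, keywords)
    if not selected:
        return {"relevant": False, "reason": "off-topic"}
    model, vocab = load_artifacts(model_dir)
    lemmas: list[str] = []
    for p in selected:
        lemmas.extend(normalize_tokens(p))
    likelihood = forward(model, encode_one_hot(lemmas, vocab))
    band = assign_label(likelihood, thresholds)
    return {
        "relevant": likelihood >= 0.5,
        "likelihood": likelihood,
        "triage": band.value,
        "version": model.version,
    }


def service_search_keywords(
    files: list[str | Path], keywords: KeywordSet
) -> dict[str, object]:
    """Map each file name to the list of keywords found in its text.

    Files are JSON paragraph arrays (the corpus convention); an unreadable
    file yields a per-file error entry while the others are still processed.
    """
    report: dict[str, object] = {}
    for path in files:
        p = Path(path)
        try:
            content = json.loads(p.read_text(encoding="utf-8"))
            if not isinstance(content, list) or not all(isinstance(x, str) for x in content):
                raise CorpusError(f"{p.name}: expected a JSON array of paragraph strings")
            report[p.name] = keyword_hits(" ".join(content), keywords)
        except (OSError, json.JSONDecodeError, PubtriageError) as exc:
            report[p.name] = {"error": str(exc)}
    return report


def report_to_json(report: dict) -> str:
    """Canonical serialization: byte-identical for identical reports."""
    return json.dumps(report, sort_keys=True, ensure_ascii=False, indent=2)
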