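"""Classifier training, recall-targeted calibration, and evaluation.

Two classification granularities share this module:

* **abstracts** are represented as bags of 1–3-grams over lowercased,
  stopword-filtered, stemmed tokens, with the vocabulary truncated to the
  most frequent grams and cell values weighted by TF (log(1+count)) and
  IDF (log(N/df)) transforms — a classic string-to-word-vector
  configuration;
* **sentences** arrive as engineered feature matrices built by
  :mod:`phenodefminer.ner_features`.

Four classical algorithms are supported (linear-kernel SVM, logistic
regression, Gaussian naive Bayes, and a CART decision tree standing in for
C4.5), each exposing a continuous score — SVM margin, class-1 probability,
or leaf class frequency — so every model admits threshold sweeping.
:func:`calibrate_threshold` picks the operating point for a recall target
(default 95%), and :func:`metrics_at_recall` reports accuracy, precision,
recall and F-measure at that point.

Neural score providers (CNN / BERT-style models) are out of scope as
implementations; :class:`AdapterConfig` records the interface contract so
externally computed scores can reuse the same calibration and evaluation
path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._stem import stem
from .corpus_io import AbstractDocument

__all__ = [
    "ALGORITHMS",
    "VectorizerConfig",
    "AbstractVectorizer",
    "vectorize_abstracts",
    "SplitConfig",
    "split_train_test",
    "TrainedClassifier",
    "train_classifier",
    "predict_scores",
    "OperatingPoint",
    "calibrate_threshold",
    "apply_threshold",
    "EvalReport",
    "evaluate",
    "evaluate_weighted",
    "metrics_at_recall",
    "AdapterConfig",
    "save_model",
    "load_model",
]

ALGORITHMS = ("svm", "logistic_regression", "naive_bayes", "decision_tree")

_TOKEN = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)


def load_stopwords(name: str = "default") -> frozenset[str]:
    """The named stopword list (only "default" and "none" are bundled)."""
    if name == "none":
        return frozenset()
    raw = resources.files("phenodefminer.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w.strip() for w in raw.splitlines() if w.strip())


@dataclass(frozen=True)
class VectorizerConfig:
    """Bag-of-n-grams vectorizer settings.

    Defaults mirror the standard configuration for abstract triage:
    lowercasing, a 1000-gram vocabulary cap, iterated Lovins-style
    stemming, stopword removal, 1–3-grams, and TF and IDF transforms.
    """

    lowercase: bool = True
    words_to_keep: int = 1000
    stemmer: Literal["lovins_iterated", "none"] = "lovins_iterated"
    stopword_list: str = "default"
    ngram_min: int = 1
    ngram_max: int = 3
    tf_transform: bool = True
    idf_transform: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.ngram_min <= self.ngram_max):
            raise ValueError("require 1 <= ngram_min <= ngram_max")
        if self.words_to_keep < 1:
            raise ValueError("words_to_keep must be >= 1")


class EmptyVocabularyError(ValueError):
    """Raised when filtering removes every candidate vocabulary gram."""


class AbstractVectorizer:
    """Fit-on-train / frozen-on-test n-gram vectorizer.

    ``fit`` learns the vocabulary (the ``words_to_keep`` grams with the
    highest total frequency in the training corpus, frequency ties broken
    lexicographically) and the document frequencies behind the IDF
    transform.  ``transform`` never extends the vocabulary, so test
    documents cannot leak terms into the feature space.
    """

    def __init__(self, config: Optional[VectorizerConfig] = None):
        self.config = config or VectorizerConfig()
        self._stopwords = load_stopwords(self.config.stopword_list)
        self.vocabulary_: Optional[dict[str, int]] = None
        self._idf: Optional[np.ndarray] = None
        self._n_train_docs: int = 0

    # -- analysis ----------------------------------------------------------

    def _analyze(self, text: str) -> list[str]:
        cfg = self.config
        if cfg.lowercase:
            text = text.lower()
        tokens = [t for t in _TOKEN.findall(text) if t.lower() not in self._stopwords]
        if cfg.stemmer == "lovins_iterated":
            # the stemmer operates on case-folded tokens
            tokens = [stem(t.casefold()) for t in tokens]
        grams: list[str] = []
        for n in range(cfg.ngram_min, cfg.ngram_max + 1):
            grams.extend(" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1))
        return grams

    # -- fitting -----------------------------------------------------------

    def fit(self, docs: Sequence[AbstractDocument]) -> "AbstractVectorizer":
        if not docs:
            raise ValueError("cannot fit a vectorizer on an empty corpus")
        totals: dict[str, int] = {}
        doc_grams: list[set[str]] = []
        for doc in docs:
            grams = self._analyze(doc.text())
            doc_grams.append(set(grams))
            for g in grams:
                totals[g] = totals.get(g, 0) + 1
        if not totals:
            raise EmptyVocabularyError(
                "vocabulary is empty after tokenization, stopword removal and stemming"
            )
        ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
        kept = [g for g, _ in ranked[: self.config.words_to_keep]]
        self.vocabulary_ = {g: j for j, g in enumerate(sorted(kept))}
        self._n_train_docs = len(docs)
        df = np.zeros(len(self.vocabulary_), dtype=float)
        for grams in doc_grams:
            for g in grams:
                j = self.vocabulary_.get(g)
                if j is not None:
                    df[j] += 1
        with np.errstate(divide="ignore"):
            self._idf = np.where(df > 0, np.log(self._n_train_docs / np.maximum(df, 1)), 0.0)
        return self

    def transform(self, docs: Sequence[AbstractDocument]) -> np.ndarray:
        if self.vocabulary_ is None:
            raise RuntimeError("vectorizer is not fitted")
        X = np.zeros((len(docs), len(self.vocabulary_)), dtype=float)
        for i, doc in enumerate(docs):
            for g in self._analyze(doc.text()):
                j = self.vocabulary_.get(g)
                if j is not None:
                    X[i, j] += 1.0
        if self.config.tf_transform:
            X = np.log1p(X)
        if self.config.idf_transform:
            X = X * self._idf
        return X

    def fit_transform(self, docs: Sequence[AbstractDocument]) -> np.ndarray:
        return self.fit(docs).transform(docs)

    @property
    def feature_names(self) -> list[str]:
        if self.vocabulary_ is None:
            raise RuntimeError("vectorizer is not fitted")
        return sorted(self.vocabulary_, key=self.vocabulary_.get)  # type: ignore[arg-type]


def vectorize_abstracts(
    docs: Sequence[AbstractDocument], cfg: Optional[VectorizerConfig] = None
) -> tuple[np.ndarray, list[str], AbstractVectorizer]:
    """Fit a vectorizer on ``docs`` and return (matrix, vocabulary, vectorizer).

    The returned vectorizer is frozen: apply ``transform`` to held-out
    documents without refitting.
    """
    vec = AbstractVectorizer(cfg)
    X = vec.fit_transform(docs)
    return X, vec.feature_names, vec


# ---------------------------------------------------------------------------
# Train/test split


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.70
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def split_train_test(records: Sequence, cfg: SplitConfig) -> tuple[list, list]:
    """Reproducible 70/30-style split of labeled records.

    Stratifies on ``record.label`` by default; a stratified split of a
    single-class corpus raises ``ValueError``.
    """
    records = list(records)
    labels = [getattr(r, "label") for r in records]
    stratify = None
    if cfg.stratified:
        if len(set(labels)) < 2:
            raise ValueError("stratified split requires at least two classes")
        stratify = labels
    idx_train, idx_test = train_test_split(
        np.arange(len(records)),
        train_size=cfg.train_fraction,
        random_state=cfg.seed,
        stratify=stratify,
        shuffle=True,
    )
    return [records[i] for i in idx_train], [records[i] for i in idx_test]


# ---------------------------------------------------------------------------
# Training and scoring


@dataclass
class TrainedClassifier:
    """A fitted model plus its feature-space descriptor.

    The score contract is: higher score = more confidently positive.  SVM
    scores are decision-function margins; the other algorithms report the
    class-1 probability (for the tree this is the leaf class frequency).
    """

    algorithm: str
    estimator: object
    n_features: int
    feature_names: Optional[tuple[str, ...]] = None

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature matrix width {X.shape[1] if X.ndim == 2 else 'N/A'} does not match "
                f"model feature space (expected {self.n_features})"
            )
        return X

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = self._check(X)
        if self.algorithm == "svm":
            return np.asarray(self.estimator.decision_function(X), dtype=float)
        return np.asarray(self.estimator.predict_proba(X)[:, 1], dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._check(X)), dtype=int)


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    if algorithm == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def train_classifier(
    X: np.ndarray,
    y: Sequence[int],
    algorithm: str,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> TrainedClassifier:
    """Fit one of the four classical algorithms on a numeric matrix.

    Raises ``ValueError`` for a single-class label vector, non-finite
    feature values, or an unknown algorithm name.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    est = _make_estimator(algorithm, seed)
    est.fit(X, y)
    return TrainedClassifier(
        algorithm=algorithm,
        estimator=est,
        n_features=X.shape[1],
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def predict_scores(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """One finite score per row, monotone with positive-class confidence."""
    return model.scores(X)


# ---------------------------------------------------------------------------
# Recall-targeted calibration


@dataclass(frozen=True)
class OperatingPoint:
    """A score cutoff with the metrics achieved on the calibration set.

    ``reachable`` is False only when even classifying everything positive
    cannot meet ``target_recall`` (then ``threshold`` sits just below the
    minimum score).
    """

    threshold: float
    achieved_recall: float
    achieved_precision: float
    target_recall: float = 0.95
    reachable: bool = True


def _recall_precision(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return recall, precision


def calibrate_threshold(
    scores: Sequence[float], labels: Sequence[int], target_recall: float = 0.95
) -> OperatingPoint:
    """Choose the largest score cutoff whose recall meets the target.

    Candidate cutoffs are the distinct scores plus one sentinel above the
    maximum (the empty-positive prediction, which is what a recall target
    of 0 selects).  Among cutoffs achieving the same (minimal sufficient)
    recall, the one maximizing precision wins; residual ties go to the
    larger threshold.  Predictions are positive at ``score >= threshold``.

    Raises ``ValueError`` when the labels contain no positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.any(labels == 1):
        raise ValueError("calibration requires at least one positive label")

    distinct = np.unique(scores)  # ascending
    sentinel = distinct[-1] + 1.0
    candidates = np.concatenate([distinct, [sentinel]])

    feasible: list[tuple[float, float, float]] = []  # (threshold, recall, precision)
    for t in candidates:
        r, p = _recall_precision(scores, labels, t)
        if r >= target_recall:
            feasible.append((float(t), r, p))
    if not feasible:
        t = float(distinct[0]) - 1e-9
        r, p = _recall_precision(scores, labels, t)
        return OperatingPoint(
            threshold=t,
            achieved_recall=r,
            achieved_precision=p,
            target_recall=target_recall,
            reachable=False,
        )
    t_star, r_star, _ = max(feasible, key=lambda trp: trp[0])
    same_recall = [trp for trp in feasible if trp[1] == r_star]
    best = max(same_recall, key=lambda trp: (trp[2], trp[0]))
    return OperatingPoint(
        threshold=best[0],
        achieved_recall=best[1],
        achieved_precision=best[2],
        target_recall=target_recall,
        reachable=True,
    )


def apply_threshold(scores: Sequence[float], op: OperatingPoint) -> np.ndarray:
    """Hard labels at an operating point (positive at score >= threshold)."""
    return (np.asarray(scores, dtype=float) >= op.threshold).astype(int)


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class EvalReport:
    """Positive-class accuracy/precision/recall/F for one prediction set.

    ``at_target_recall`` optionally carries the same metrics measured at a
    calibrated operating point.
    """

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    at_target_recall: Optional["EvalReport"] = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
        }
        if self.at_target_recall is not None:
            d.update(
                {f"{k}_at_target_recall": v for k, v in self.at_target_recall.as_dict().items()}
            )
        return d


def evaluate(predicted_labels: Sequence[int], labels: Sequence[int]) -> EvalReport:
    """Positive-class metrics with the 0-denominator-gives-0 convention."""
    pred = np.asarray(predicted_labels, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.shape != y.shape:
        raise ValueError("predicted_labels and labels must have equal length")
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = len(y)
    accuracy = (tp + tn) / n if n else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return EvalReport(accuracy=accuracy, precision=precision, recall=recall, f_measure=f)


def evaluate_weighted(predicted_labels: Sequence[int], labels: Sequence[int]) -> EvalReport:
    """Support-weighted average of per-class precision/recall/F.

    Offered alongside the positive-class report because published
    evaluations sometimes average across classes, which makes accuracy,
    precision and recall coincide on balanced errors.
    """
    pred = np.asarray(predicted_labels, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.shape != y.shape:
        raise ValueError("predicted_labels and labels must have equal length")
    pos = evaluate(pred, y)
    neg = evaluate(1 - pred, 1 - y)
    w_pos = float(np.mean(y == 1)) if len(y) else 0.0
    w_neg = 1.0 - w_pos
    return EvalReport(
        accuracy=pos.accuracy,
        precision=w_pos * pos.precision + w_neg * neg.precision,
        recall=w_pos * pos.recall + w_neg * neg.recall,
        f_measure=w_pos * pos.f_measure + w_neg * neg.f_measure,
    )


def metrics_at_recall(
    scores: Sequence[float], labels: Sequence[int], target_recall: float = 0.95
) -> tuple[EvalReport, OperatingPoint]:
    """Evaluate at the operating point calibrated for ``target_recall``."""
    op = calibrate_threshold(scores, labels, target_recall)
    report = evaluate(apply_threshold(scores, op), labels)
    return report, op


# ---------------------------------------------------------------------------
# External score-provider contract (no implementation shipped)


@dataclass(frozen=True)
class AdapterConfig:
    """Interface contract for external neural score providers.

    Deep models (CNN / BERT-family) are trained outside this package; the
    contract they must honour to plug into the calibration and evaluation
    path is: sequences truncated to the first ``max_sequence_length``
    tokens, zero-padded to that length, fine-tuned at the recorded
    learning rate, and scores returned with higher = more positive.  These
    fields are documentation, not enforced behaviour.
    """

    max_sequence_length: int = 512
    truncation: str = "keep_first_tokens"
    padding: str = "zeros_to_max_length"
    learning_rate: float = 5e-5


# ---------------------------------------------------------------------------
# Persistence


def save_model(model: TrainedClassifier, path: Union[str, Path]) -> None:
    """Persist a trained classifier (joblib archive with a format tag)."""
    joblib.dump(
        {
            "format_version": 1,
            "algorithm": model.algorithm,
            "estimator": model.estimator,
            "n_features": model.n_features,
            "feature_names": model.feature_names,
        },
        path,
    )


def load_model(path: Union[str, Path]) -> TrainedClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unrecognized model archive format")
    return TrainedClassifier(
        algorithm=payload["algorithm"],
        estimator=payload["estimator"],
        n_features=payload["n_features"],
        feature_names=payload["feature_names"],
    )
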