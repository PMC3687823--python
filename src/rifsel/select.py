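"""GeneRIF sentence classification, top-3 ranking and evaluation.

Four learners commonly used for text categorization are supported:
Naïve Bayes (``NB``, Gaussian likelihoods over the numeric features),
a linear-kernel SVM (``SVM-linear``, margin mapped to a probability by a
logistic calibration fitted on training folds), a decision tree (``J48``)
and boosted decision trees (``AdaBoostM1-J48``).  Evaluation reports
precision, recall and F-measure on the GeneRIF-positive class; for
curation support, the top three sentences per citation are ranked by the
classifier's positive-class confidence.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "ALGORITHMS",
    "SelectorModel",
    "EvalResult",
    "train",
    "predict",
    "rank_top3",
    "evaluate",
    "class_balance",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("NB", "SVM-linear", "J48", "AdaBoostM1-J48")


@dataclass
class EvalResult:
    """Precision/recall/F on the GeneRIF-positive class."""

    precision: float
    recall: float
    f_measure: float
    tp: int
    fp: int
    fn: int

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvalResult":
        if min(tp, fp, fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if tp + fp == 0:
            # no positive predictions: precision defined as 0 (degenerate)
            logger.info("no positive predictions; precision defined as 0")
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn else 0.0
        if precision + recall > 0:
            f = 2 * precision * recall / (precision + recall)
        else:
            f = 0.0
        return cls(precision, recall, f, tp, fp, fn)

    def as_dict(self) -> dict[str, float | int]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
        }


@dataclass
class SelectorModel:
    """A fitted GeneRIF sentence classifier."""

    algorithm: str
    estimator: object
    columns: tuple[str, ...]
    feature_hash: str
    seed: int

    def save(self, dest: Union[str, Path]) -> None:
        joblib.dump(self, dest)

    @classmethod
    def load(cls, source: Union[str, Path]) -> "SelectorModel":
        model = joblib.load(source)
        if not isinstance(model, cls):
            raise TypeError(f"{source}: not a serialized SelectorModel")
        return model


def _config_hash(matrix: FeatureMatrix) -> str:
    payload = matrix.config.describe() + "|" + "|".join(matrix.columns)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _make_estimator(algorithm: str, seed: int, adaboost_rounds: int = 10):
    if algorithm == "NB":
        return GaussianNB()
    if algorithm == "SVM-linear":
        return CalibratedClassifierCV(
            LinearSVC(random_state=seed), method="sigmoid", cv=3
        )
    if algorithm == "J48":
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)
    if algorithm == "AdaBoostM1-J48":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(criterion="entropy"),
            n_estimators=adaboost_rounds,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def train(
    matrix: FeatureMatrix,
    algorithm: str,
    seed: int = 0,
    adaboost_rounds: int = 10,
) -> SelectorModel:
    """Fit a sentence classifier on a labeled feature matrix.

    Deterministic for a fixed seed.  Raises when the labels contain a
    single class.
    """
    if matrix.labels is None:
        raise ValueError("training requires a labeled feature matrix")
    y = matrix.labels.to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_estimator(algorithm, seed, adaboost_rounds)
    est.fit(matrix.data.to_numpy(dtype=float), y)
    return SelectorModel(
        algorithm=algorithm,
        estimator=est,
        columns=tuple(matrix.columns),
        feature_hash=_config_hash(matrix),
        seed=seed,
    )


def predict(model: SelectorModel, matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-row (label, confidence); confidence is the positive-class score."""
    missing = [c for c in model.columns if c not in matrix.columns]
    extra = [c for c in matrix.columns if c not in model.columns]
    if missing or extra:
        raise ValueError(
            f"feature columns do not match the model: missing {missing}, "
            f"unexpected {extra}"
        )
    X = matrix.data[list(model.columns)].to_numpy(dtype=float)
    proba = model.estimator.predict_proba(X)
    pos_col = list(model.estimator.classes_).index(1)
    conf = np.clip(proba[:, pos_col], 0.0, 1.0)
    return pd.DataFrame(
        {"label": conf >= 0.5, "confidence": conf}, index=matrix.data.index
    )


def rank_top3(
    model: SelectorModel, citation_id: str, matrix: FeatureMatrix
) -> list[tuple[int, float]]:
    """Up to three (position, confidence) pairs for one citation, by
    descending confidence; ties break to the smaller position."""
    preds = predict(model, matrix)
    if citation_id not in preds.index.get_level_values("citation_id"):
        raise ValueError(f"matrix has no rows for citation {citation_id!r}")
    sub = preds.loc[citation_id]
    ranked = sorted(
        ((int(pos), float(row.confidence)) for pos, row in sub.iterrows()),
        key=lambda pc: (-pc[1], pc[0]),
    )
    return ranked[:3]


def evaluate(model: SelectorModel, matrix: FeatureMatrix) -> EvalResult:
    """P/R/F on the GeneRIF-positive class of a labeled test matrix."""
    if matrix.labels is None:
        raise ValueError("evaluation requires a labeled feature matrix")
    if len(matrix.data) == 0:
        raise ValueError("empty test set")
    preds = predict(model, matrix)
    gold = matrix.labels.to_numpy().astype(bool)
    hat = preds["label"].to_numpy()
    tp = int((hat & gold).sum())
    fp = int((hat & ~gold).sum())
    fn = int((~hat & gold).sum())
    return EvalResult.from_counts(tp, fp, fn)


def class_balance(labels: Sequence[bool]) -> tuple[int, int, int, float, float]:
    """(total, positives, negatives, positive %, negative %); percentages
    are 100 * count / total rounded to 2 decimals."""
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    total = len(labels)
    pos = sum(bool(l) for l in labels)
    neg = total - pos
    return total, pos, neg, round(100.0 * pos / total, 2), round(100.0 * neg / total, 2)
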