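"""Discourse zoning of abstract sentences.

Structured abstracts carry explicit section headings (BACKGROUND,
OBJECTIVE, METHODS, RESULTS, CONCLUSIONS); :func:`distill_labels` turns
them into per-sentence discourse labels that serve as distant supervision.
Two labelers are trained on such data and later provide the ``dis``
feature for GeneRIF sentence selection:

* a *binary ensemble*: one boosted-decision-trees scorer per label over
  bag-of-words + position features, which may abstain (``Unknown``) when
  no scorer is confident, and
* a *sequence* model: a linear-chain CRF over the same per-sentence
  features with label-transition weights, which always commits to a label.

The title sentence (position 1) is always labeled ``Title``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix, hstack
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.feature_extraction.text import CountVectorizer

from ._resources import heading_map as _default_heading_map
from .corpus import Citation
from .crf import LinearChainCRF

__all__ = [
    "CORE_LABELS",
    "DiscourseModel",
    "distill_labels",
    "distill_corpus",
    "train_binary_ensemble",
    "train_crf",
    "predict_discourse",
    "evaluate_discourse",
]

logger = logging.getLogger(__name__)

#: the five trainable section labels, in tie-break priority order
CORE_LABELS = ("Background", "Objective", "Methods", "Results", "Conclusions")
TITLE = "Title"
UNKNOWN = "Unknown"


@dataclass
class DiscourseModel:
    """A trained discourse labeler (binary ensemble or sequence CRF)."""

    kind: str  # "binary-ensemble" | "sequence"
    vectorizer: CountVectorizer
    scorers: dict[str, HistGradientBoostingClassifier] | None
    crf: LinearChainCRF | None
    seed: int
    config: dict = field(default_factory=dict)
    threshold: float = 0.5

    def save(self, dest: Union[str, Path]) -> None:
        joblib.dump(self, dest)

    @classmethod
    def load(cls, source: Union[str, Path]) -> "DiscourseModel":
        model = joblib.load(source)
        if not isinstance(model, cls):
            raise TypeError(f"{source}: not a serialized DiscourseModel")
        return model


# --- label distillation -----------------------------------------------------

def distill_labels(
    citation: Citation,
    heading_map: Mapping[str, str] | None = None,
) -> list[tuple[int, str]] | None:
    """Per-sentence discourse labels inherited from section headings.

    Every abstract sentence inherits the canonical label of its enclosing
    section; the title sentence is labeled ``Title``.  A citation with any
    heading absent from ``heading_map`` is skipped entirely (returns None,
    logged).  Overlapping section ranges raise a data error.
    """
    if heading_map is None:
        heading_map = _default_heading_map()
    if not citation.section_labels:
        raise ValueError(f"citation {citation.citation_id}: no section labels")
    norm = {k.upper(): v for k, v in heading_map.items()}

    labels: list[tuple[int, str]] = [(1, TITLE)]
    seen_end = 1
    for heading, (first, last) in citation.section_labels:
        if first <= seen_end or first > last:
            raise ValueError(
                f"citation {citation.citation_id}: overlapping or invalid "
                f"section range {heading!r} ({first}, {last})"
            )
        canon = norm.get(heading.strip().rstrip(":").upper())
        if canon is None:
            logger.info(
                "citation %s: unmapped heading %r; skipping citation",
                citation.citation_id,
                heading,
            )
            return None
        for pos in range(first, last + 1):
            labels.append((pos, canon))
        seen_end = last
    return labels


def distill_corpus(
    citations: Sequence[Citation],
    heading_map: Mapping[str, str] | None = None,
) -> tuple[list[Citation], dict[str, dict[int, str]]]:
    """Distill labels for a whole corpus, dropping skipped citations.

    Returns the accepted citations and a citation id -> position -> label
    mapping suitable for the trainers (Title entries excluded).
    """
    kept: list[Citation] = []
    lookup: dict[str, dict[int, str]] = {}
    for cit in citations:
        labels = distill_labels(cit, heading_map)
        if labels is None:
            continue
        kept.append(cit)
        lookup[cit.citation_id] = {p: lab for p, lab in labels if lab != TITLE}
    return kept, lookup


# --- feature building (shared by both labelers) -----------------------------

def _sentence_features(
    citations: Sequence[Citation],
    vectorizer: CountVectorizer,
    fit: bool,
) -> tuple[csr_matrix, list[tuple[str, int]]]:
    """Bag-of-words + pos + posf rows for every abstract sentence (title
    excluded: structured-abstract supervision has no title sentences)."""
    texts, pos, posf, keys = [], [], [], []
    for cit in citations:
        n = cit.n_sentences
        for s in cit.sentences:
            if s.position == 1:
                continue
            texts.append(s.text)
            pos.append(s.position)
            posf.append(n - s.position)
            keys.append((cit.citation_id, s.position))
    if fit:
        bow = vectorizer.fit_transform(texts)
    else:
        bow = vectorizer.transform(texts)
    extra = csr_matrix(np.column_stack([pos, posf]).astype(np.float64))
    X = hstack([bow.astype(np.float64), extra]).tocsr()
    return X, keys


def _gold_label_lookup(
    citations: Sequence[Citation],
    gold: Mapping[str, Mapping[int, str]] | None,
) -> dict[str, dict[int, str]]:
    """Labels per citation: explicit mapping wins, else sentence gold."""
    if gold is not None:
        return {cid: dict(m) for cid, m in gold.items()}
    out: dict[str, dict[int, str]] = {}
    for cit in citations:
        out[cit.citation_id] = {
            s.position: s.gold_discourse
            for s in cit.sentences
            if s.position > 1 and s.gold_discourse is not None
        }
    return out


# --- binary ensemble --------------------------------------------------------

def train_binary_ensemble(
    citations: Sequence[Citation],
    labels: Mapping[str, Mapping[int, str]] | None = None,
    seed: int = 0,
    max_features: int = 300,
    min_support: int = 10,
    threshold: float = 0.5,
    max_iter: int = 80,
) -> DiscourseModel:
    """One boosted-decision-trees binary scorer per core discourse label.

    Features are bag-of-words (capped vocabulary) plus the two position
    features (pos, posf).  ``labels`` maps citation id -> position ->
    label; when omitted, sentence-level gold discourse labels are used.
    Deterministic for a fixed seed.
    """
    lookup = _gold_label_lookup(citations, labels)
    vectorizer = CountVectorizer(lowercase=True, max_features=max_features)
    X, keys = _sentence_features(citations, vectorizer, fit=True)
    y = np.array([lookup.get(cid, {}).get(p, "") for cid, p in keys])
    mask = y != ""
    X, y = X[mask], y[mask]

    present = [lab for lab in CORE_LABELS if (y == lab).sum() > 0]
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 discourse labels")
    for lab in present:
        n_pos = int((y == lab).sum())
        if n_pos < min_support:
            raise ValueError(
                f"label {lab!r} has only {n_pos} positive sentences "
                f"(minimum {min_support})"
            )

    Xd = np.asarray(X.todense(), dtype=np.float64)
    scorers: dict[str, HistGradientBoostingClassifier] = {}
    for lab in present:
        clf = HistGradientBoostingClassifier(
            random_state=seed, max_iter=max_iter, early_stopping=False
        )
        clf.fit(Xd, (y == lab).astype(int))
        scorers[lab] = clf
    return DiscourseModel(
        kind="binary-ensemble",
        vectorizer=vectorizer,
        scorers=scorers,
        crf=None,
        seed=seed,
        config={"max_features": max_features, "max_iter": max_iter},
        threshold=threshold,
    )


# --- sequence model ---------------------------------------------------------

def train_crf(
    citations: Sequence[Citation],
    labels: Mapping[str, Mapping[int, str]] | None = None,
    seed: int = 0,
    max_features: int = 300,
    c2: float = 1.0,
    max_iter: int = 120,
) -> DiscourseModel:
    """Linear-chain CRF over full per-abstract label sequences.

    Each training abstract must provide a label for every abstract
    sentence (a full ordered sequence).  Deterministic for fixed inputs.
    """
    lookup = _gold_label_lookup(citations, labels)
    vectorizer = CountVectorizer(lowercase=True, max_features=max_features)
    X, keys = _sentence_features(citations, vectorizer, fit=True)
    row_of = {k: i for i, k in enumerate(keys)}

    seq_X, seq_y = [], []
    for cit in citations:
        positions = [s.position for s in cit.sentences if s.position > 1]
        if not positions:
            raise ValueError(f"citation {cit.citation_id}: empty abstract sequence")
        labs = lookup.get(cit.citation_id, {})
        if any(p not in labs for p in positions):
            raise ValueError(
                f"citation {cit.citation_id}: incomplete label sequence"
            )
        rows = [row_of[(cit.citation_id, p)] for p in positions]
        seq_X.append(X[rows])
        seq_y.append([labs[p] for p in positions])

    crf = LinearChainCRF(c2=c2, max_iter=max_iter).fit(seq_X, seq_y)
    return DiscourseModel(
        kind="sequence",
        vectorizer=vectorizer,
        scorers=None,
        crf=crf,
        seed=seed,
        config={"max_features": max_features, "c2": c2, "max_iter": max_iter},
    )


# --- prediction -------------------------------------------------------------

def predict_discourse(
    model: DiscourseModel, citation: Citation
) -> list[tuple[int, str, float]]:
    """Per-sentence (position, label, confidence).

    Position 1 is always ``(1, Title, 1.0)``.  The binary ensemble returns
    the label of the most confident scorer, or ``Unknown`` when no scorer
    clears its decision threshold (abstention is a legitimate outcome).
    The sequence model returns the best-path label, never ``Unknown``.
    """
    if not citation.sentences:
        raise ValueError("citation must be segmented before prediction")
    out: list[tuple[int, str, float]] = [(1, TITLE, 1.0)]
    abstract = [s for s in citation.sentences if s.position > 1]
    if not abstract:
        return out

    X, _ = _sentence_features([citation], model.vectorizer, fit=False)
    if model.kind == "binary-ensemble":
        if model.scorers is None:
            raise RuntimeError("ensemble model has no scorers (untrained?)")
        Xd = np.asarray(X.todense(), dtype=np.float64)
        probs = {lab: clf.predict_proba(Xd)[:, 1] for lab, clf in model.scorers.items()}
        for i, s in enumerate(abstract):
            best_lab, best_p = UNKNOWN, 0.0
            for lab in CORE_LABELS:  # fixed priority order breaks ties
                p = float(probs.get(lab, np.zeros(len(abstract)))[i])
                if p > best_p:
                    best_lab, best_p = lab, p
            if best_p < model.threshold:
                out.append((s.position, UNKNOWN, best_p))
            else:
                out.append((s.position, best_lab, best_p))
    elif model.kind == "sequence":
        if model.crf is None:
            raise RuntimeError("sequence model has no CRF (untrained?)")
        labs, conf = model.crf.predict_with_confidence(X)
        for s, lab, c in zip(abstract, labs, conf):
            out.append((s.position, lab, float(c)))
    else:
        raise ValueError(f"unknown model kind: {model.kind!r}")
    return out


# --- evaluation -------------------------------------------------------------

def evaluate_discourse(
    model: DiscourseModel,
    citations: Sequence[Citation],
    labels: Mapping[str, Mapping[int, str]] | None = None,
) -> pd.DataFrame:
    """Per-label one-vs-rest counts and P/R/F over abstract sentences.

    Returns a table with columns Positives, TP, FP, Precision, Recall,
    F-measure, indexed by discourse label.
    """
    if not citations:
        raise ValueError("empty test set")
    lookup = _gold_label_lookup(citations, labels)
    gold: list[str] = []
    pred: list[str] = []
    for cit in citations:
        predictions = {p: lab for p, lab, _ in predict_discourse(model, cit)}
        for s in cit.sentences:
            if s.position == 1:
                continue
            g = lookup.get(cit.citation_id, {}).get(s.position)
            if g is None:
                raise ValueError(
                    f"citation {cit.citation_id}: missing gold label at "
                    f"position {s.position}"
                )
            gold.append(g)
            pred.append(predictions[s.position])

    gold_arr, pred_arr = np.array(gold), np.array(pred)
    rows = []
    for lab in CORE_LABELS:
        positives = int((gold_arr == lab).sum())
        tp = int(((gold_arr == lab) & (pred_arr == lab)).sum())
        fp = int(((gold_arr != lab) & (pred_arr == lab)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / positives if positives else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append((lab, positives, tp, fp, precision, recall, f))
    return pd.DataFrame(
        rows,
        columns=["Discourse", "Positives", "TP", "FP", "Precision", "Recall", "F-measure"],
    ).set_index("Discourse")
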