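"""Per-sentence feature extraction and matrix assembly.

Feature blocks (selected by name in :class:`FeatureConfig`):

``pos``
    Sentence number from the start of the citation; the title is 1.
``posf``
    Distance from the end: total sentence count minus the sentence
    number, so the last sentence scores 0.
``text``
    Bag-of-words counts of the lowercased, stop-word-filtered sentence
    tokens, as unigrams or bigrams.
``gene``
    Three columns from the lexicon's mentions: mention count, distinct
    resolved gene ids, binary presence.
``dis`` / ``disg``
    One-hot discourse label of the sentence.  ``dis`` is fed by a trained
    labeler (ensemble or sequence, per ``discourse_source``); ``disg``
    uses the citation's gold discourse annotation.  Gold ``Purpose``
    labels map to the ``Objective`` column so both sources share one
    vocabulary.
``go``
    Gene Ontology terminology density: a self-contained score rewarding
    long GO-term matches in the sentence (not comparable to external
    GO-annotation scorers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._resources import stopwords as _stopwords
from .corpus import Citation, Sentence
from .lexicon import GeneMention

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "DISCOURSE_ONEHOT",
    "extract_pos",
    "extract_posf",
    "extract_text",
    "extract_gene",
    "extract_discourse",
    "extract_go_density",
    "assemble",
]

VALID_FEATURES = frozenset({"pos", "posf", "text", "gene", "dis", "disg", "go"})

#: one-hot vocabulary for the discourse feature
DISCOURSE_ONEHOT = (
    "Background",
    "Objective",
    "Methods",
    "Results",
    "Conclusions",
    "Title",
    "Unknown",
)

#: gold 6-way annotation -> one-hot vocabulary
_GOLD_TO_ONEHOT = {
    "Background": "Background",
    "Purpose": "Objective",
    "Methods": "Methods",
    "Results": "Results",
    "Conclusions": "Conclusions",
    "Title": "Title",
}

_WORD = re.compile(r"\w+")


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature blocks to compute and how."""

    feature_set: frozenset[str]
    text_ngram: int = 1
    stopword_list: str = "english-basic"
    discourse_source: str = "predicted-ensemble"

    def __init__(
        self,
        feature_set,
        text_ngram: int = 1,
        stopword_list: str = "english-basic",
        discourse_source: str = "predicted-ensemble",
    ):
        fs = frozenset(feature_set)
        if not fs:
            raise ValueError("feature_set must be non-empty")
        unknown = fs - VALID_FEATURES
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        if {"dis", "disg"} <= fs:
            raise ValueError("dis and disg are mutually exclusive in one config")
        if text_ngram not in (1, 2):
            raise ValueError("text_ngram must be 1 or 2")
        if discourse_source not in ("predicted-ensemble", "predicted-sequence", "gold"):
            raise ValueError(f"invalid discourse_source: {discourse_source!r}")
        object.__setattr__(self, "feature_set", fs)
        object.__setattr__(self, "text_ngram", text_ngram)
        object.__setattr__(self, "stopword_list", stopword_list)
        object.__setattr__(self, "discourse_source", discourse_source)

    def describe(self) -> str:
        return " + ".join(sorted(self.feature_set))


@dataclass
class FeatureMatrix:
    """Per-sentence feature values with optional GeneRIF labels.

    ``data`` is indexed by (citation_id, position); ``labels`` (when
    present) aligns with ``data`` and holds the gold GeneRIF flag.
    """

    data: pd.DataFrame
    config: FeatureConfig
    labels: pd.Series | None = None
    text_vocabulary: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.labels is not None and not self.labels.index.equals(self.data.index):
            raise ValueError("labels index must match feature rows")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def rows_for(self, citation_id: str) -> pd.DataFrame:
        return self.data.loc[citation_id]

    def to_tsv(self, dest) -> None:
        df = self.data.copy()
        if self.labels is not None:
            df["generif"] = self.labels.astype(int)
        df.to_csv(dest, sep="\t")


# --- individual extractors --------------------------------------------------

def extract_pos(sentence: Sentence) -> int:
    """Sentence number from the start of the citation (title = 1)."""
    return sentence.position


def extract_posf(sentence: Sentence, citation: Citation) -> int:
    """Total sentence count minus the sentence number (last sentence = 0)."""
    if not citation.sentences:
        raise ValueError("citation must be segmented")
    return citation.n_sentences - sentence.position


def _tokens(text: str, stop: frozenset[str]) -> list[str]:
    return [t for t in _WORD.findall(text.lower()) if t not in stop]


def extract_text(sentence: Sentence, config: FeatureConfig) -> dict[str, int]:
    """Bag-of-words term counts (unigrams or bigrams of consecutive
    surviving tokens after lowercasing and stop-word removal)."""
    toks = _tokens(sentence.text, _stopwords(config.stopword_list))
    if config.text_ngram == 1:
        grams = toks
    else:
        grams = [f"{a}_{b}" for a, b in zip(toks, toks[1:])]
    counts: dict[str, int] = {}
    for g in grams:
        counts[g] = counts.get(g, 0) + 1
    return counts


def extract_gene(
    sentence: Sentence, mentions: Sequence[GeneMention]
) -> tuple[int, int, int]:
    """(mention count, distinct resolved gene ids, binary presence)."""
    ms = [m for m in mentions if m.sentence_position == sentence.position]
    distinct = {m.resolved_id for m in ms if m.resolved_id is not None}
    return len(ms), len(distinct), int(bool(ms))


def extract_discourse(label: str) -> dict[str, int]:
    """One-hot encoding of a discourse label (gold Purpose -> Objective)."""
    canon = _GOLD_TO_ONEHOT.get(label, label)
    if canon not in DISCOURSE_ONEHOT:
        raise ValueError(f"unknown discourse label: {label!r}")
    return {lab: int(lab == canon) for lab in DISCOURSE_ONEHOT}


def extract_go_density(
    sentence: Sentence, go_term_table: Mapping[str, str]
) -> float:
    """GO terminology density of a sentence.

    Greedy leftmost-longest, non-overlapping matching of GO-term token
    sequences against the sentence tokens; the score is the sum of
    (matched token count)^2 over matches, normalized by the sentence
    token count.  Zero when nothing matches.  Invariant under sentence
    self-concatenation.
    """
    if not go_term_table:
        raise ValueError("GO term table is empty")
    term_tokens = sorted(
        (tuple(_WORD.findall(term.lower())) for term in go_term_table.values()),
        key=len,
        reverse=True,
    )
    term_tokens = [t for t in term_tokens if t]
    toks = [t.lower() for t in _WORD.findall(sentence.text)]
    if not toks:
        return 0.0
    score = 0
    i = 0
    while i < len(toks):
        matched = 0
        for tt in term_tokens:  # longest-first
            if tuple(toks[i : i + len(tt)]) == tt:
                matched = len(tt)
                break
        if matched:
            score += matched * matched
            i += matched
        else:
            i += 1
    return score / len(toks)


# --- matrix assembly --------------------------------------------------------

def load_go_table(source) -> dict[str, str]:
    """Two-column text table: term id <TAB> term string."""
    from pathlib import Path

    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    table = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term_id, term = line.split("\t", 1)
        table[term_id] = term.strip()
    return table


def assemble(
    citations: Sequence[Citation],
    config: FeatureConfig,
    *,
    mentions: Mapping[str, Sequence[GeneMention]] | None = None,
    discourse_labels: Mapping[tuple[str, int], str] | None = None,
    go_table: Mapping[str, str] | None = None,
    text_vocabulary: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Assemble the feature matrix for a citation set.

    Dependencies must be supplied for the requested blocks: ``mentions``
    (citation id -> mention list) for ``gene``; ``discourse_labels``
    ((citation id, position) -> label) for ``dis`` unless
    ``discourse_source`` is ``gold``; ``go_table`` for ``go``.  For
    ``text``, pass the training matrix's ``text_vocabulary`` at test time
    so columns line up.  Column order is deterministic.  Gold GeneRIF
    flags, when present on every sentence, become the label column.
    """
    fs = config.feature_set
    if "gene" in fs and mentions is None:
        raise ValueError("feature 'gene' requested but mentions missing")
    if "go" in fs and go_table is None:
        raise ValueError("feature 'go' requested but go_table missing")
    need_predictions = "dis" in fs and config.discourse_source != "gold"
    if need_predictions and discourse_labels is None:
        raise ValueError("feature 'dis' requested but discourse predictions missing")

    rows: list[dict[str, float]] = []
    keys: list[tuple[str, int]] = []
    labels: list[bool | None] = []
    text_counts: list[dict[str, int]] = []

    for cit in citations:
        if not cit.sentences:
            raise ValueError(f"citation {cit.citation_id}: not segmented")
        cit_mentions = mentions.get(cit.citation_id, []) if mentions else []
        for s in cit.sentences:
            row: dict[str, float] = {}
            if "pos" in fs:
                row["pos"] = extract_pos(s)
            if "posf" in fs:
                row["posf"] = extract_posf(s, cit)
            if "gene" in fs:
                count, distinct, present = extract_gene(s, cit_mentions)
                row["gene_count"] = count
                row["gene_distinct"] = distinct
                row["gene_present"] = present
            if "dis" in fs or "disg" in fs:
                if "disg" in fs or config.discourse_source == "gold":
                    if s.position == 1:
                        label = "Title"
                    else:
                        label = s.gold_discourse
                    if label is None:
                        raise ValueError(
                            f"feature '{'disg' if 'disg' in fs else 'dis'}': citation "
                            f"{cit.citation_id} position {s.position} has no gold "
                            "discourse label"
                        )
                else:
                    label = discourse_labels.get((cit.citation_id, s.position))
                    if label is None:
                        raise ValueError(
                            f"feature 'dis': no discourse prediction for citation "
                            f"{cit.citation_id} position {s.position}"
                        )
                for lab, v in extract_discourse(label).items():
                    row[f"dis_{lab}"] = v
            if "go" in fs:
                row["go_density"] = extract_go_density(s, go_table)
            rows.append(row)
            keys.append((cit.citation_id, s.position))
            labels.append(s.gold_generif)
            if "text" in fs:
                text_counts.append(extract_text(s, config))

    index = pd.MultiIndex.from_tuples(keys, names=["citation_id", "position"])
    base_cols: list[str] = []
    for name in ("pos", "posf"):
        if name in fs:
            base_cols.append(name)
    if "gene" in fs:
        base_cols += ["gene_count", "gene_distinct", "gene_present"]
    if "dis" in fs or "disg" in fs:
        base_cols += [f"dis_{lab}" for lab in DISCOURSE_ONEHOT]
    if "go" in fs:
        base_cols.append("go_density")
    df = pd.DataFrame(rows, index=index, columns=base_cols, dtype=float) if base_cols else pd.DataFrame(index=index)

    vocab_out: tuple[str, ...] | None = None
    if "text" in fs:
        if text_vocabulary is None:
            vocab_out = tuple(sorted({g for c in text_counts for g in c}))
        else:
            vocab_out = tuple(text_vocabulary)
        arr = np.zeros((len(text_counts), len(vocab_out)))
        col_of = {g: j for j, g in enumerate(vocab_out)}
        for i, counts in enumerate(text_counts):
            for g, c in counts.items():
                j = col_of.get(g)
                if j is not None:
                    arr[i, j] = c
        text_df = pd.DataFrame(
            arr, index=index, columns=[f"text_{g}" for g in vocab_out]
        )
        df = pd.concat([df, text_df], axis=1)

    label_series = None
    if all(l is not None for l in labels) and labels:
        label_series = pd.Series([bool(l) for l in labels], index=index, name="generif")
    return FeatureMatrix(
        data=df, config=config, labels=label_series, text_vocabulary=vocab_out
    )
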