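"""High-level orchestration: citation annotation and matrix building.

Glues the modules together the way the production flow would: expand
locally defined abbreviations, match gene mentions against the
dictionary, normalize them, predict discourse labels, and assemble the
feature matrix for a chosen feature combination.
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

from .corpus import Citation, Sentence
from .discourse import DiscourseModel, predict_discourse
from .features import FeatureConfig, FeatureMatrix, assemble
from .lexicon import (
    GeneDictionary,
    GeneMention,
    GeneProfile,
    context_terms_for,
    disambiguate_official,
    disambiguate_profile,
    expand_abbreviations,
)

__all__ = ["annotate_mentions", "predict_corpus_discourse", "build_matrix"]


def _expanded_sentences(citation: Citation) -> list[Sentence]:
    """Sentences with locally defined abbreviations replaced by their
    long forms (definitions collected over the whole citation text)."""
    full = " ".join(s.text for s in citation.sentences)
    _, mapping = expand_abbreviations(full)
    if not mapping:
        return list(citation.sentences)
    out = []
    for s in citation.sentences:
        text = s.text
        for sf, lf in mapping.items():
            text = re.sub(rf"(?<![\w(]){re.escape(sf)}(?![\w)])", lf, text)
        out.append(Sentence(position=s.position, text=text))
    return out


def annotate_mentions(
    citation: Citation,
    dictionary: GeneDictionary,
    profiles: Mapping[str, GeneProfile] | None = None,
    context_window: int = 0,
    homonym_list=None,
) -> list[GeneMention]:
    """Match and normalize gene mentions for one segmented citation.

    Matching runs on abbreviation-expanded sentence text.  Ambiguous
    mentions are resolved by context-profile similarity when ``profiles``
    is given, with officialness as fallback; otherwise by officialness
    alone.
    """
    from .lexicon import match_mentions  # local import avoids cycle confusion

    if not citation.sentences:
        raise ValueError(f"citation {citation.citation_id}: not segmented")
    sentences = _expanded_sentences(citation)
    mentions: list[GeneMention] = []
    for sent in sentences:
        for m in match_mentions(sent, dictionary, homonym_list):
            if profiles is not None and len(m.candidate_ids) > 1:
                context = context_terms_for(sentences, sent.position, context_window)
                disambiguate_profile(m, context, profiles, dictionary)
            else:
                disambiguate_official(m, dictionary)
            mentions.append(m)
    return mentions


def predict_corpus_discourse(
    model: DiscourseModel, citations: Sequence[Citation]
) -> dict[tuple[str, int], str]:
    """(citation id, position) -> predicted discourse label, for ``dis``."""
    out: dict[tuple[str, int], str] = {}
    for cit in citations:
        for pos, label, _ in predict_discourse(model, cit):
            out[(cit.citation_id, pos)] = label
    return out


def build_matrix(
    citations: Sequence[Citation],
    config: FeatureConfig,
    *,
    dictionary: GeneDictionary | None = None,
    profiles: Mapping[str, GeneProfile] | None = None,
    discourse_model: DiscourseModel | None = None,
    go_table: Mapping[str, str] | None = None,
    text_vocabulary: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Assemble a feature matrix, computing the dependencies on demand.

    ``gene`` needs a dictionary; ``dis`` with a predicted source needs a
    discourse model; ``go`` needs a GO term table.
    """
    mentions = None
    if "gene" in config.feature_set:
        if dictionary is None:
            raise ValueError("feature 'gene' needs a gene dictionary")
        mentions = {
            c.citation_id: annotate_mentions(c, dictionary, profiles) for c in citations
        }
    discourse_labels = None
    if "dis" in config.feature_set and config.discourse_source != "gold":
        if discourse_model is None:
            raise ValueError("feature 'dis' needs a trained discourse model")
        want = (
            "binary-ensemble"
            if config.discourse_source == "predicted-ensemble"
            else "sequence"
        )
        if discourse_model.kind != want:
            raise ValueError(
                f"discourse_source {config.discourse_source!r} needs a "
                f"{want} model, got {discourse_model.kind!r}"
            )
        discourse_labels = predict_corpus_discourse(discourse_model, citations)
    return assemble(
        citations,
        config,
        mentions=mentions,
        discourse_labels=discourse_labels,
        go_table=go_table,
        text_vocabulary=text_vocabulary,
    )
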