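"""Automatable citation-filtering rules from the data-set construction
pipeline.

Two stages are implemented.  Journal-level: journals whose citations are
too often confounded by common model-species terms are excluded
(strictly-less-than-threshold acceptance).  Citation-level: drop records
without an abstract, records indexed to non-human species by MeSH, records
without any gene mention, review articles spanning three or more distinct
genes, and publication types outside {Journal Article, Meta-Analysis,
Review}.  Rules that the original curation workflow applies manually
(single-patient case reports; "basic biology is the primary point") are
out of scope here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._resources import nonhuman_mesh as _default_nonhuman
from .corpus import Citation
from .lexicon import GeneMention

__all__ = [
    "DEFAULT_SPECIES_TERMS",
    "FilterReport",
    "journal_confound_filter",
    "citation_filters",
]

logger = logging.getLogger(__name__)

#: the 11 common model-species terms used for journal filtering
DEFAULT_SPECIES_TERMS = (
    "mouse",
    "murine",
    "yeast",
    "fly",
    "drosophila",
    "cow",
    "cattle",
    "bovine",
    "worm",
    "c. elegans",
    "plant",
)

ALLOWED_PUBLICATION_TYPES = frozenset({"Journal Article", "Meta-Analysis", "Review"})

#: citation-level rules, applied in order
RULES = (
    "no_abstract",
    "nonhuman_mesh",
    "no_gene_mention",
    "review_many_genes",
    "publication_type",
)


@dataclass
class FilterReport:
    """Outcome of the citation-level filter cascade."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    survivors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.removed and self.n_input != len(self.survivors) + sum(self.removed.values()):
            raise ValueError("filter report does not reconcile: input != survivors + removed")


def _species_pattern(term: str) -> re.Pattern:
    # whole-token, case-insensitive; "c. elegans" tolerates flexible spacing
    escaped = re.escape(term).replace(r"\ ", r"\s+")
    return re.compile(rf"(?<!\w){escaped}(?!\w)", re.IGNORECASE)


def journal_confound_filter(
    journals: Mapping[str, Sequence[Citation]],
    species_terms: Sequence[str] = DEFAULT_SPECIES_TERMS,
    threshold: float = 0.40,
) -> set[str]:
    """Journals whose confounded-citation fraction is strictly below the
    threshold.

    A citation is confounded when its title+abstract contains at least one
    model-species term (whole-token, case-insensitive).  A journal with no
    citations is excluded (logged).
    """
    patterns = [_species_pattern(t) for t in species_terms]
    accepted: set[str] = set()
    for journal, citations in journals.items():
        if not citations:
            logger.warning("journal %r has no citations; excluded", journal)
            continue
        confounded = 0
        for cit in citations:
            text = f"{cit.title} {cit.abstract}"
            if any(p.search(text) for p in patterns):
                confounded += 1
        if confounded / len(citations) < threshold:
            accepted.add(journal)
    return accepted


def citation_filters(
    citations: Sequence[Citation],
    mentions: Mapping[str, Sequence[GeneMention]],
    nonhuman_mesh: frozenset[str] | set[str] | None = None,
) -> FilterReport:
    """Apply the automatable citation filters in order and report counts.

    ``mentions`` maps citation id -> gene mentions (citation-wide).  Each
    rule sees only the survivors of the previous one; the report counts
    reconcile exactly with the input.
    """
    if nonhuman_mesh is None:
        nonhuman_mesh = _default_nonhuman()
    removed: dict[str, int] = {r: 0 for r in RULES}
    removed_ids: dict[str, list[str]] = {r: [] for r in RULES}
    survivors: list[str] = []

    for cit in citations:
        rule = _first_violated_rule(cit, mentions.get(cit.citation_id, []), nonhuman_mesh)
        if rule is None:
            survivors.append(cit.citation_id)
        else:
            removed[rule] += 1
            removed_ids[rule].append(cit.citation_id)

    return FilterReport(
        n_input=len(citations),
        removed=removed,
        removed_ids=removed_ids,
        survivors=survivors,
    )


def _first_violated_rule(
    cit: Citation,
    cit_mentions: Sequence[GeneMention],
    nonhuman: frozenset[str] | set[str],
) -> str | None:
    if not cit.abstract.strip():
        return "no_abstract"
    if (cit.mesh_headings & set(nonhuman)) and "Humans" not in cit.mesh_headings:
        return "nonhuman_mesh"
    if not cit_mentions:
        return "no_gene_mention"
    if "Review" in cit.publication_types:
        distinct = {m.resolved_id for m in cit_mentions if m.resolved_id is not None}
        if len(distinct) >= 3:
            return "review_many_genes"
    if not (cit.publication_types & ALLOWED_PUBLICATION_TYPES):
        return "publication_type"
    return None
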