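"""Gene-name lexicon: dictionary construction, variant generation,
longest-first mention matching, abbreviation resolution and normalization.

The dictionary maps surface forms (official symbols, official names,
synonyms and punctuation variants) to candidate gene identifiers.  Entries
are ordered longest-to-shortest so that matching finds the longest possible
mention before any of its components.  Ambiguous mentions (several
candidate identifiers) are normalized either by an *officialness* heuristic
(official symbol > official name > synonym) or by comparing the mention
context against per-gene tf-idf term profiles.

Surface forms on the shipped homonym list (``resources/homonyms.txt``)
match case-sensitively to avoid false positives on common English words
("WAS", "CAT", ...); all other forms match case-insensitively.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

from ._resources import homonyms as _default_homonyms
from ._resources import stopwords as _stopwords
from .corpus import Sentence

__all__ = [
    "GeneRecord",
    "GeneDictionary",
    "GeneMention",
    "GeneProfile",
    "DEFAULT_BANNED_SUFFIXES",
    "read_gene_records",
    "generate_variants",
    "build_dictionary",
    "expand_abbreviations",
    "match_mentions",
    "disambiguate_official",
    "build_profiles",
    "disambiguate_profile",
]

logger = logging.getLogger(__name__)

#: misleading name endings excluded from the dictionary
DEFAULT_BANNED_SUFFIXES = ("disease", "syndrome", "susceptibility")

#: officialness ranks; lower is preferred during normalization
RANK_OFFICIAL_SYMBOL = 0
RANK_OFFICIAL_NAME = 1
RANK_SYNONYM = 2


@dataclass
class GeneRecord:
    """One gene: stable identifier, official symbol/name and synonyms."""

    gene_id: str
    official_symbol: str
    official_name: str
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")


@dataclass
class GeneDictionary:
    """Surface form -> candidate gene ids, ordered longest-first.

    ``entries`` is a list of ``(surface_form, {gene_id: officialness_rank})``
    sorted by descending form length, ties broken lexicographically.
    """

    entries: list[tuple[str, dict[str, int]]]
    _by_lower: dict[str, dict[str, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_lower = {form.lower(): cands for form, cands in self.entries}

    def candidates(self, surface: str) -> dict[str, int]:
        """Candidate gene ids (with ranks) for a surface form, or {}."""
        return self._by_lower.get(surface.lower(), {})

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, dest: Union[str, Path]) -> None:
        """Serialize as a versioned tab-separated file."""
        lines = ["#rifsel-gene-dictionary\tv1"]
        for form, cands in self.entries:
            cell = ",".join(f"{gid}:{rank}" for gid, rank in sorted(cands.items()))
            lines.append(f"{form}\t{cell}")
        Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, source: Union[str, Path]) -> "GeneDictionary":
        lines = Path(source).read_text(encoding="utf-8").splitlines()
        if not lines or not lines[0].startswith("#rifsel-gene-dictionary"):
            raise ValueError(f"{source}: not a serialized gene dictionary")
        entries = []
        for line in lines[1:]:
            if not line.strip():
                continue
            form, cell = line.split("\t")
            cands = {}
            for item in cell.split(","):
                gid, rank = item.rsplit(":", 1)
                cands[gid] = int(rank)
            entries.append((form, cands))
        return cls(entries=entries)


@dataclass
class GeneMention:
    """A matched gene name span within one sentence.

    ``span`` is 0-based, half-open, in sentence-text character offsets.
    """

    sentence_position: int
    span: tuple[int, int]
    matched_text: str
    candidate_ids: frozenset[str]
    resolved_id: str | None = None

    def __post_init__(self) -> None:
        if not self.candidate_ids:
            raise ValueError("candidate_ids must be non-empty")
        if self.resolved_id is not None and self.resolved_id not in self.candidate_ids:
            raise ValueError("resolved_id must be one of candidate_ids")


@dataclass
class GeneProfile:
    """tf-idf weighted term vector characterizing one gene."""

    gene_id: str
    term_weights: dict[str, float]


# --- gene record I/O --------------------------------------------------------

def read_gene_records(source: Union[str, Path, IO[str]]) -> list[GeneRecord]:
    """Read a tab-separated gene table: gene_id, symbol, name, synonyms
    (pipe-separated), mirroring the public ``gene_info`` layout."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    records = []
    for i, line in enumerate(text.splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"gene record line {i}: expected >= 3 tab-separated fields")
        gene_id, symbol, name = parts[0], parts[1], parts[2]
        syns = [s for s in parts[3].split("|") if s] if len(parts) > 3 else []
        records.append(GeneRecord(gene_id, symbol, name, syns))
    return records


def write_gene_records(records: Iterable[GeneRecord], dest: Union[str, Path]) -> None:
    lines = [
        "\t".join((r.gene_id, r.official_symbol, r.official_name, "|".join(r.synonyms)))
        for r in records
    ]
    Path(dest).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --- dictionary construction ------------------------------------------------

def generate_variants(name: str) -> set[str]:
    """Punctuation/spacing variants for a gene name.

    Names with exactly one dash yield a dash-to-space variant and a
    dash-removed variant (``cortexin-2`` -> ``cortexin 2``, ``cortexin2``);
    any other name yields no variants.  The original is kept by the caller.
    """
    if not name:
        raise ValueError("name must be non-empty")
    if name.count("-") != 1:
        return set()
    return {name.replace("-", " "), name.replace("-", "")}


def build_dictionary(
    records: Sequence[GeneRecord],
    banned_suffixes: Sequence[str] = DEFAULT_BANNED_SUFFIXES,
) -> GeneDictionary:
    """Build the longest-first matching dictionary from gene records.

    Every official symbol, official name and synonym contributes itself plus
    its punctuation variants; duplicates are collapsed with candidate-id
    sets merged; forms ending (case-insensitively) in a banned suffix are
    removed.  When one gene exposes the same surface form under several
    name types, the best (lowest) officialness rank wins.
    """
    if not records:
        raise ValueError("cannot build a dictionary from an empty record list")
    banned = tuple(s.lower() for s in banned_suffixes)
    acc: dict[str, dict[str, int]] = {}
    display: dict[str, str] = {}

    def add(form: str, gene_id: str, rank: int) -> None:
        form = form.strip()
        if not form:
            return
        if form.lower().endswith(banned):
            return
        key = form.lower()
        cands = acc.setdefault(key, {})
        if gene_id not in cands or rank < cands[gene_id]:
            cands[gene_id] = rank
        # keep the first-seen casing as the canonical display form
        display.setdefault(key, form)

    for rec in records:
        for name, rank in (
            (rec.official_symbol, RANK_OFFICIAL_SYMBOL),
            (rec.official_name, RANK_OFFICIAL_NAME),
            *((s, RANK_SYNONYM) for s in rec.synonyms),
        ):
            if not name:
                continue
            add(name, rec.gene_id, rank)
            for variant in generate_variants(name):
                add(variant, rec.gene_id, rank)

    entries = [(display[key], cands) for key, cands in acc.items()]
    entries.sort(key=lambda e: (-len(e[0]), e[0].lower()))
    return GeneDictionary(entries=entries)


# --- abbreviation resolution (Schwartz & Hearst alignment) ------------------

_PAREN = re.compile(r"\(([^()]+)\)")


def _valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= 10):
        return False
    if len(sf.split()) > 2:
        return False
    if not any(ch.isalpha() for ch in sf):
        return False
    return sf[0].isalnum()


def _best_long_form(short: str, candidate: str) -> str | None:
    """Character alignment: walk the short form right-to-left, matching each
    alphanumeric character in the candidate text moving leftwards; the first
    character of the short form must start a word of the long form."""
    s = len(short) - 1
    l = len(candidate) - 1
    while s >= 0:
        ch = short[s].lower()
        if not ch.isalnum():
            s -= 1
            continue
        while (l >= 0 and candidate[l].lower() != ch) or (
            s == 0 and l > 0 and candidate[l - 1].isalnum()
        ):
            l -= 1
        if l < 0:
            return None
        s -= 1
        l -= 1
    start = candidate.rfind(" ", 0, l + 1) + 1
    return candidate[start:]


def expand_abbreviations(text: str) -> tuple[str, dict[str, str]]:
    """Resolve parenthetical abbreviation definitions and replace later
    occurrences of each short form with its long form.

    Returns the expanded text and the ``short -> long`` mapping.  Unmatched
    parentheticals are left untouched.
    """
    mapping: dict[str, str] = {}
    for m in _PAREN.finditer(text):
        sf = m.group(1).strip()
        if not _valid_short_form(sf) or sf in mapping:
            continue
        # candidate long form: up to min(|sf|+5, 2|sf|) words before the paren
        before = text[: m.start()].rstrip()
        # stay within the current sentence/clause
        cut = max(before.rfind(". "), before.rfind("; "))
        if cut >= 0:
            before = before[cut + 2 :]
        words = before.split()
        max_words = min(len(sf) + 5, len(sf) * 2)
        candidate = " ".join(words[-max_words:]) if words else ""
        if not candidate:
            continue
        long_form = _best_long_form(sf, candidate)
        if long_form and long_form.lower() != sf.lower():
            mapping[sf] = long_form

    if not mapping:
        return text, mapping

    expanded = text
    for sf, lf in mapping.items():
        # replace standalone occurrences of the short form occurring after
        # its definition; the definition "(SF)" itself is preserved
        def_pos = expanded.find(f"({sf})")
        def_end = def_pos + len(sf) + 2 if def_pos >= 0 else 0
        pattern = re.compile(rf"(?<![\w(]){re.escape(sf)}(?![\w)])")
        head, tail = expanded[:def_end], expanded[def_end:]
        expanded = head + pattern.sub(lf, tail)
    return expanded, mapping


# --- mention matching -------------------------------------------------------

_WORD = re.compile(r"\w+")


def _is_word(ch: str) -> bool:
    return bool(ch) and (ch.isalnum() or ch == "_")


def match_mentions(
    sentence: Sentence,
    dictionary: GeneDictionary,
    homonym_list: frozenset[str] | set[str] | None = None,
) -> list[GeneMention]:
    """Greedy leftmost-longest, non-overlapping dictionary matching.

    Matches anchor at token boundaries.  Matching is case-insensitive
    except for surface forms on ``homonym_list`` (default: the shipped
    homonym file), which must match exactly.
    """
    if homonym_list is None:
        homonym_list = _default_homonyms()
    text = sentence.text
    lower = text.lower()
    token_starts = [m.start() for m in _WORD.finditer(text)]
    mentions: list[GeneMention] = []
    i = 0
    while i < len(token_starts):
        start = token_starts[i]
        best: tuple[str, dict[str, int]] | None = None
        for form, cands in dictionary.entries:  # longest-first
            end = start + len(form)
            if end > len(text):
                continue
            if lower[start:end] != form.lower():
                continue
            if _is_word(text[end]) if end < len(text) else False:
                continue  # must end at a token boundary
            if form in homonym_list and text[start:end] != form:
                continue  # homonyms require exact case
            best = (form, cands)
            break
        if best is None:
            i += 1
            continue
        form, cands = best
        end = start + len(form)
        mentions.append(
            GeneMention(
                sentence_position=sentence.position,
                span=(start, end),
                matched_text=text[start:end],
                candidate_ids=frozenset(cands),
            )
        )
        while i < len(token_starts) and token_starts[i] < end:
            i += 1
    return mentions


# --- normalization ----------------------------------------------------------

def disambiguate_official(mention: GeneMention, dictionary: GeneDictionary) -> GeneMention:
    """Resolve a mention by officialness: official symbol beats official
    name beats synonym; ties break to the smallest gene id."""
    ranks = dictionary.candidates(mention.matched_text)
    best = min(mention.candidate_ids, key=lambda gid: (ranks.get(gid, RANK_SYNONYM), gid))
    mention.resolved_id = best
    return mention


def _tokenize(text: str, stop: frozenset[str]) -> list[str]:
    return [t for t in _WORD.findall(text.lower()) if t not in stop]


def build_profiles(
    training_texts: Mapping[str, Sequence[str]],
    stopword_list: str = "english-basic",
) -> dict[str, GeneProfile]:
    """Per-gene tf-idf term profiles from training texts.

    idf follows the ``log(N / df)`` convention over the gene set, so a term
    occurring in every gene's texts gets weight zero.  A gene whose texts
    reduce to stop words only (or to all-zero weights) is a configuration
    error.
    """
    stop = _stopwords(stopword_list)
    tf: dict[str, dict[str, int]] = {}
    for gene_id, texts in training_texts.items():
        if not texts:
            raise ValueError(f"gene {gene_id}: no training texts")
        counts: dict[str, int] = {}
        for text in texts:
            for tok in _tokenize(text, stop):
                counts[tok] = counts.get(tok, 0) + 1
        if not counts:
            raise ValueError(f"gene {gene_id}: training texts contain only stop words")
        tf[gene_id] = counts

    n = len(tf)
    df: dict[str, int] = {}
    for counts in tf.values():
        for term in counts:
            df[term] = df.get(term, 0) + 1

    profiles: dict[str, GeneProfile] = {}
    for gene_id, counts in tf.items():
        weights = {t: c * math.log(n / df[t]) for t, c in counts.items()}
        if not any(w > 0 for w in weights.values()):
            raise ValueError(
                f"gene {gene_id}: profile has no discriminative terms "
                "(all terms are shared by every gene)"
            )
        profiles[gene_id] = GeneProfile(gene_id, weights)
    return profiles


def _cosine(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    dot = sum(w * b[t] for t, w in a.items() if t in b)
    na = math.sqrt(sum(w * w for w in a.values()))
    nb = math.sqrt(sum(w * w for w in b.values()))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return dot / (na * nb)


def disambiguate_profile(
    mention: GeneMention,
    context_terms: Sequence[str],
    profiles: Mapping[str, GeneProfile],
    dictionary: GeneDictionary,
    stopword_list: str = "english-basic",
) -> GeneMention:
    """Resolve a mention by cosine similarity between the context term
    profile and each candidate gene's profile.

    Falls back to :func:`disambiguate_official` when a candidate lacks a
    profile or when all similarities tie (e.g. all zero).
    """
    stop = _stopwords(stopword_list)
    context: dict[str, float] = {}
    for term in context_terms:
        for tok in _tokenize(term, stop):
            context[tok] = context.get(tok, 0.0) + 1.0

    missing = [gid for gid in mention.candidate_ids if gid not in profiles]
    if missing:
        logger.warning(
            "mention %r: candidates %s lack profiles; falling back to officialness",
            mention.matched_text,
            missing,
        )
        return disambiguate_official(mention, dictionary)

    sims = {
        gid: _cosine(context, profiles[gid].term_weights) for gid in mention.candidate_ids
    }
    best_sim = max(sims.values())
    winners = [gid for gid, s in sims.items() if s == best_sim]
    if len(winners) > 1:
        return disambiguate_official(mention, dictionary)
    mention.resolved_id = winners[0]
    return mention


def context_terms_for(
    sentences: Sequence[Sentence], position: int, window: int = 0
) -> list[str]:
    """Context for disambiguation: the mention's sentence plus ``window``
    neighboring sentences on each side (positions are 1-based)."""
    lo, hi = position - window, position + window
    return [s.text for s in sentences if lo <= s.position <= hi]
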