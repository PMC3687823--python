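"""Citation data model, readers/writers and sentence segmentation.

A :class:`Citation` is one MEDLINE-style record: title, abstract, journal,
publication types and MeSH headings, optionally with structured-abstract
section headings and gold annotations.  After :func:`segment_sentences` the
citation carries an ordered sentence list in which the title is sentence 1
and abstract sentences are numbered 2..N.

Two on-disk representations are supported:

* a read-only subset of PubMed/MEDLINE XML (PMID, Journal/Title,
  PublicationType, MeshHeading/DescriptorName, ArticleTitle, AbstractText
  with optional ``Label`` attributes), and
* a line-delimited JSON fixture dialect (one record per line) used by the
  synthetic generator and the test suite; see :func:`write_citations`.

Fixture dialect fields::

    id        str   citation identifier (required)
    title     str   citation title (required, non-empty)
    abstract  str   abstract text ("" allowed; filtering happens downstream)
    journal   str
    pub_types [str]
    mesh      [str]
    sections  [[heading, text], ...]   optional raw structured-abstract chunks
    sentences [{text, generif?, discourse?, claim?, subcategory?}, ...]
              optional pre-segmented sentences carrying gold annotations;
              the first entry is the title sentence.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

from lxml import etree

__all__ = [
    "Sentence",
    "Citation",
    "CitationParseError",
    "read_citations",
    "write_citations",
    "segment_sentences",
]

DISCOURSE_GOLD_LABELS = frozenset(
    {"Background", "Conclusions", "Methods", "Purpose", "Results", "Title"}
)
CLAIM_LABELS = frozenset({"Established", "Putative", "Non-Claim"})
SUBCATEGORY_LABELS = frozenset(
    {"Expression", "Function", "Isolation", "Other", "Reference", "Structure"}
)


class CitationParseError(ValueError):
    """Malformed citation record; message names the record index and field."""


@dataclass
class Sentence:
    """One sentence of a citation; position 1 is the title."""

    position: int
    text: str
    gold_generif: bool | None = None
    gold_discourse: str | None = None
    gold_claim: str | None = None
    gold_subcategory: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"sentence position must be >= 1, got {self.position}")
        if self.gold_discourse is not None and self.gold_discourse not in DISCOURSE_GOLD_LABELS:
            raise ValueError(f"invalid gold discourse label: {self.gold_discourse!r}")
        if self.gold_claim is not None and self.gold_claim not in CLAIM_LABELS:
            raise ValueError(f"invalid gold claim label: {self.gold_claim!r}")
        if self.gold_subcategory is not None and self.gold_subcategory not in SUBCATEGORY_LABELS:
            raise ValueError(f"invalid gold subcategory label: {self.gold_subcategory!r}")


@dataclass
class Citation:
    """One MEDLINE-style citation record."""

    citation_id: str
    title: str
    abstract: str = ""
    journal: str = ""
    publication_types: set[str] = field(default_factory=set)
    mesh_headings: set[str] = field(default_factory=set)
    #: raw structured-abstract chunks as read from the source: (heading, text)
    abstract_sections: list[tuple[str, str]] | None = None
    #: after segmentation: (heading, (first_position, last_position)) per section
    section_labels: list[tuple[str, tuple[int, int]]] | None = None
    sentences: list[Sentence] = field(default_factory=list)

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)


# --- sentence segmentation -------------------------------------------------

#: abbreviations that never terminate a sentence (compared lowercased)
PROTECTED_ABBREVIATIONS = frozenset(
    {
        "e.g.", "i.e.", "vs.", "cf.", "ca.", "al.", "et al.", "etc.",
        "fig.", "figs.", "ref.", "refs.", "no.", "nos.", "vol.",
        "dr.", "mr.", "mrs.", "ms.", "prof.", "st.", "approx.", "resp.",
    }
)

_BOUNDARY = re.compile(r"([.!?]+)(\s+)")


def _split_block(text: str) -> list[str]:
    """Rule-based sentence split: terminal punctuation followed by space,
    unless the preceding token is a protected abbreviation or a single
    initial (``J. Smith``)."""
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end(1)
        prefix = text[start:end]
        # token immediately before the boundary, including its periods
        tok = re.search(r"(\S+)$", prefix)
        word = tok.group(1).lower() if tok else ""
        if word in PROTECTED_ABBREVIATIONS:
            continue
        # "et al." style two-token abbreviation
        two = re.search(r"(\S+\s+\S+)$", prefix)
        if two and two.group(1).lower() in PROTECTED_ABBREVIATIONS:
            continue
        # single-letter initial: "J."
        if re.fullmatch(r"[A-Za-z]\.", word):
            continue
        piece = prefix.strip()
        if piece:
            sentences.append(piece)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def segment_sentences(citation: Citation) -> Citation:
    """Populate ``citation.sentences`` in place (and return the citation).

    The title becomes position 1; abstract sentences are numbered 2..N.
    Structured-abstract chunks are segmented per section and the section
    ranges recorded in ``section_labels``.  Multi-paragraph abstracts are
    concatenated with a single space.  Deterministic: same input, same
    sentence list.
    """
    if not citation.title.strip():
        raise ValueError(f"citation {citation.citation_id}: title is empty")
    if citation.sentences:
        return citation  # already segmented (e.g. fixture carried sentences)

    sentences = [Sentence(position=1, text=citation.title.strip())]
    pos = 2
    if citation.abstract_sections:
        ranges: list[tuple[str, tuple[int, int]]] = []
        for heading, chunk in citation.abstract_sections:
            parts = _split_block(chunk)
            if not parts:
                continue
            first = pos
            for part in parts:
                sentences.append(Sentence(position=pos, text=part))
                pos += 1
            ranges.append((heading, (first, pos - 1)))
        citation.section_labels = ranges
    else:
        for part in _split_block(citation.abstract):
            sentences.append(Sentence(position=pos, text=part))
            pos += 1
    citation.sentences = sentences
    return citation


# --- fixture dialect (JSON lines) ------------------------------------------

def _citation_from_json(obj: dict, index: int) -> Citation:
    for fld in ("id", "title"):
        if not obj.get(fld):
            raise CitationParseError(f"record {index}: missing field {fld!r}")
    sections = obj.get("sections")
    cit = Citation(
        citation_id=str(obj["id"]),
        title=obj["title"],
        abstract=obj.get("abstract", ""),
        journal=obj.get("journal", ""),
        publication_types=set(obj.get("pub_types", [])),
        mesh_headings=set(obj.get("mesh", [])),
        abstract_sections=[(h, t) for h, t in sections] if sections else None,
    )
    if "sentences" in obj:
        sents = []
        for i, s in enumerate(obj["sentences"]):
            try:
                sents.append(
                    Sentence(
                        position=i + 1,
                        text=s["text"],
                        gold_generif=s.get("generif"),
                        gold_discourse=s.get("discourse"),
                        gold_claim=s.get("claim"),
                        gold_subcategory=s.get("subcategory"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise CitationParseError(f"record {index}: sentence {i + 1}: {exc}") from exc
        cit.sentences = sents
        if sections:
            # reconstruct section position ranges from chunk sentence counts
            ranges = []
            pos = 2
            for heading, chunk in cit.abstract_sections or []:
                n = len(_split_block(chunk))
                if n:
                    ranges.append((heading, (pos, pos + n - 1)))
                    pos += n
            cit.section_labels = ranges or None
    return cit


def _sentence_to_json(s: Sentence) -> dict:
    out: dict = {"text": s.text}
    if s.gold_generif is not None:
        out["generif"] = s.gold_generif
    if s.gold_discourse is not None:
        out["discourse"] = s.gold_discourse
    if s.gold_claim is not None:
        out["claim"] = s.gold_claim
    if s.gold_subcategory is not None:
        out["subcategory"] = s.gold_subcategory
    return out


def _citation_to_json(c: Citation) -> dict:
    obj: dict = {"id": c.citation_id, "title": c.title, "abstract": c.abstract}
    if c.journal:
        obj["journal"] = c.journal
    if c.publication_types:
        obj["pub_types"] = sorted(c.publication_types)
    if c.mesh_headings:
        obj["mesh"] = sorted(c.mesh_headings)
    if c.abstract_sections:
        obj["sections"] = [[h, t] for h, t in c.abstract_sections]
    if c.sentences:
        obj["sentences"] = [_sentence_to_json(s) for s in c.sentences]
    return obj


# --- PubMed XML subset ------------------------------------------------------

def _read_xml(data: bytes) -> list[Citation]:
    root = etree.fromstring(data)
    articles = root.findall(".//MedlineCitation")
    if not articles and root.tag == "MedlineCitation":
        articles = [root]
    citations = []
    for i, art in enumerate(articles):
        pmid = art.findtext("PMID")
        title = art.findtext(".//ArticleTitle")
        if not pmid:
            raise CitationParseError(f"record {i}: missing field 'PMID'")
        if not title:
            raise CitationParseError(f"record {i}: missing field 'ArticleTitle'")
        journal = art.findtext(".//Journal/Title") or ""
        pub_types = {
            el.text.strip() for el in art.findall(".//PublicationTypeList/PublicationType")
            if el.text
        }
        mesh = {
            el.text.strip()
            for el in art.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
            if el.text
        }
        chunks = art.findall(".//Abstract/AbstractText")
        sections: list[tuple[str, str]] | None = None
        abstract = ""
        if chunks:
            if any(el.get("Label") for el in chunks):
                sections = [(el.get("Label", ""), (el.text or "").strip()) for el in chunks]
                abstract = " ".join(t for _, t in sections if t)
            else:
                abstract = " ".join((el.text or "").strip() for el in chunks).strip()
        citations.append(
            Citation(
                citation_id=pmid.strip(),
                title=title.strip(),
                abstract=abstract,
                journal=journal.strip(),
                publication_types=pub_types,
                mesh_headings=mesh,
                abstract_sections=sections,
            )
        )
    return citations


# --- public reader / writer -------------------------------------------------

def read_citations(source: Union[str, Path, IO[str]]) -> list[Citation]:
    """Read citations from PubMed-style XML or the JSON-lines fixture dialect.

    The format is sniffed from the first non-blank character (``<`` means
    XML).  Records lacking a title are rejected with
    :class:`CitationParseError`; an empty abstract is allowed.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("<"):
        return _read_xml(stripped.encode("utf-8"))
    citations = []
    index = 0
    for line in text.splitlines():
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CitationParseError(f"record {index}: invalid JSON: {exc}") from exc
        citations.append(_citation_from_json(obj, index))
        index += 1
    return citations


def write_citations(citations: Iterable[Citation], dest: Union[str, Path, IO[str]]) -> None:
    """Write citations in the JSON-lines fixture dialect (one record/line)."""
    lines = [json.dumps(_citation_to_json(c), ensure_ascii=False) for c in citations]
    payload = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(payload)
    else:
        Path(dest).write_text(payload, encoding="utf-8")
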