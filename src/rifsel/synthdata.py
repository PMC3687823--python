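"""Seeded synthetic corpora with the statistical structure the selection
method exploits.

The generator emulates the regularities the real task rests on, without
any external downloads:

* abstracts follow the Background -> Objective -> Methods -> Results ->
  Conclusions discourse, each section with its own vocabulary;
* GeneRIF-positive sentences concentrate at the title and the last two
  sentences, with an overall positive rate calibrated to roughly 42%;
* a toy gene inventory is planted into the text, including ambiguous
  names shared by two genes (resolvable from the surrounding
  gene-specific vocabulary), single-dash names exercising variant
  generation, a case-sensitive English homonym, and parenthetical
  abbreviation definitions aligned the Schwartz--Hearst way;
* a small Gene Ontology phrase table whose terms appear in Results and
  Conclusions sentences.

Everything is a pure function of :class:`SynthConfig`; the same config
reproduces byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus import Citation, Sentence
from .lexicon import GeneRecord

__all__ = [
    "SynthConfig",
    "SynthCorpus",
    "PlantedMention",
    "default_gene_inventory",
    "default_gene_vocab",
    "default_go_table",
    "generate_corpus",
    "generate_structured_abstracts",
]

SECTION_ORDER = ("Background", "Objective", "Methods", "Results", "Conclusions")

#: headings as they would appear in a structured abstract
_HEADING_OF = {
    "Background": "BACKGROUND",
    "Objective": "OBJECTIVE",
    "Methods": "METHODS",
    "Results": "RESULTS",
    "Conclusions": "CONCLUSIONS",
}

_SECTION_VOCAB: dict[str, tuple[str, ...]] = {
    "Background": (
        "prevalence", "burden", "aetiology", "epidemiology", "cohort",
        "incidence", "chronic", "worldwide", "pathogenesis", "remains",
        "poorly", "understood", "carcinoma", "susceptible", "heritable",
    ),
    "Objective": (
        "aimed", "investigate", "determine", "whether", "hypothesis",
        "evaluate", "assess", "sought", "examine", "role", "objective",
        "purpose", "goal", "study", "association",
    ),
    "Methods": (
        "patients", "samples", "assay", "immunoblot", "genotyped",
        "sequencing", "cohorts", "recruited", "measured", "protocol",
        "cultured", "transfected", "quantified", "microscopy", "statistical",
    ),
    "Results": (
        "observed", "significant", "increased", "decreased", "correlation",
        "expression", "levels", "compared", "controls", "fold", "higher",
        "lower", "associated", "detected", "mutation",
    ),
    "Conclusions": (
        "novel", "suggest", "demonstrate", "conclude", "indicate",
        "therapeutic", "target", "biomarker", "function", "regulates",
        "contributes", "implicate", "mechanism", "insight", "findings",
    ),
}

_TITLE_VOCAB: tuple[str, ...] = (
    "promotes", "suppresses", "modulates", "drives", "links", "controls",
    "tumor", "growth", "inflammation", "progression", "survival",
    "differentiation", "human", "cells", "cancer",
)

_SHARED_VOCAB: tuple[str, ...] = (
    "protein", "gene", "analysis", "data", "clinical", "tissue", "sample",
    "group", "effect", "level", "value", "result", "change", "model", "test",
)


def default_gene_inventory() -> list[GeneRecord]:
    """Toy human gene inventory: ambiguous synonym ``p40`` (two genes),
    single-dash names for variant generation, the English homonym ``WAS``
    and abbreviation-friendly official names."""
    return [
        GeneRecord("101", "VEGFA", "vascular endothelial growth factor A", ["VEGF"]),
        GeneRecord("102", "TNF", "tumor necrosis factor", ["TNF-alpha"]),
        GeneRecord("103", "CTXN2", "cortexin 2", ["cortexin-2"]),
        GeneRecord("104", "WAS", "WASP actin nucleation promoting factor", ["WASP"]),
        GeneRecord("105", "EBP1", "ErbB3 binding protein 1", ["p40"]),
        GeneRecord("106", "SQSTM1", "sequestosome 1", ["p40", "p62"]),
        GeneRecord("107", "BRCA1", "BRCA1 DNA repair associated", []),
        GeneRecord("108", "EGFR", "epidermal growth factor receptor", ["ERBB1"]),
    ]


def default_gene_vocab() -> dict[str, tuple[str, ...]]:
    """Disjoint per-gene context vocabularies used for profile building
    and for seeding disambiguation contexts."""
    return {
        "101": ("angiogenesis", "vascular", "endothelium", "permeability", "hypoxia"),
        "102": ("cytokine", "necrosis", "septic", "macrophage", "inflammatory"),
        "103": ("cortex", "neuronal", "membrane", "brain", "synaptic"),
        "104": ("actin", "cytoskeleton", "wiskott", "aldrich", "immunodeficiency"),
        "105": ("ribosome", "biogenesis", "nucleolar", "erbb3", "proliferative"),
        "106": ("autophagy", "ubiquitin", "aggregate", "sequestosome", "inclusion"),
        "107": ("repair", "homologous", "recombination", "breast", "ovarian"),
        "108": ("receptor", "tyrosine", "kinase", "lung", "adenocarcinoma"),
    }


def default_go_table() -> dict[str, str]:
    """Small Gene Ontology phrase table (term id -> term string)."""
    return {
        "GO:0006915": "apoptosis",
        "GO:0042981": "regulation of apoptosis",
        "GO:0007165": "signal transduction",
        "GO:0016055": "wnt signaling pathway",
        "GO:0006281": "dna repair",
        "GO:0008283": "cell population proliferation",
        "GO:0007049": "cell cycle",
        "GO:0006914": "autophagy",
    }


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults define the study conditions.

    Positive placement approximates the observed GeneRIF position
    distribution: the title and the final sentences carry most positives,
    and the overall positive rate lands near 42%.
    """

    seed: int = 0
    n_citations: int = 550
    #: (min, max) sentences per section, in canonical order
    section_lengths: tuple[tuple[str, tuple[int, int]], ...] = (
        ("Background", (1, 2)),
        ("Objective", (1, 1)),
        ("Methods", (1, 2)),
        ("Results", (2, 3)),
        ("Conclusions", (2, 2)),
    )
    words_per_sentence: tuple[int, int] = (6, 10)
    p_positive_title: float = 0.97
    p_positive_last_two: float = 0.95
    p_positive_body: float = 0.16
    genes_per_citation: tuple[int, int] = (1, 3)
    abbrev_def_prob: float = 0.30
    go_phrase_prob: float = 0.25
    #: fraction of tokens drawn from the shared vocabulary instead of the
    #: section vocabulary (0 = fully separable sections)
    vocabulary_overlap: float = 0.0
    structured_headings: bool = True

    def __post_init__(self) -> None:
        if self.n_citations < 1:
            raise ValueError("n_citations must be >= 1")
        if not self.section_lengths:
            raise ValueError("section_lengths must be non-empty")
        for label, (lo, hi) in self.section_lengths:
            if label not in SECTION_ORDER or lo < 0 or hi < lo:
                raise ValueError(f"invalid section length range for {label!r}")
        if sum(hi for _, (_, hi) in self.section_lengths) < 1:
            raise ValueError("config generates zero abstract sentences")
        for p in (self.p_positive_title, self.p_positive_last_two, self.p_positive_body):
            if not 0.0 <= p <= 1.0:
                raise ValueError("placement probabilities must lie in [0, 1]")
        if max(self.p_positive_title, self.p_positive_last_two, self.p_positive_body) == 0:
            raise ValueError("at least one placement probability must be positive")
        if not 0.0 <= self.vocabulary_overlap <= 1.0:
            raise ValueError("vocabulary_overlap must lie in [0, 1]")


@dataclass
class PlantedMention:
    """Ground truth for one planted gene mention."""

    citation_id: str
    position: int
    surface: str
    true_gene_id: str
    ambiguous: bool


@dataclass
class SynthCorpus:
    """A generated corpus plus all ground truth needed by the pipeline."""

    citations: list[Citation]
    gene_records: list[GeneRecord]
    go_table: dict[str, str]
    true_mentions: list[PlantedMention]
    #: per-gene texts for profile building (emulating curated abstracts)
    profile_texts: dict[str, list[str]]
    config: SynthConfig

    def train_test_split(
        self, n_train: int = 400, n_test: int = 150
    ) -> tuple[list[Citation], list[Citation]]:
        """Leading ``n_train`` citations for training, next ``n_test`` for
        testing (echoing a 373/151 style random split: generation order is
        already random)."""
        if n_train + n_test > len(self.citations):
            raise ValueError("not enough citations for the requested split")
        return self.citations[:n_train], self.citations[n_train : n_train + n_test]


# --- internals --------------------------------------------------------------

def _draw_tokens(rng, vocab: Sequence[str], n: int, overlap: float) -> list[str]:
    out = []
    for _ in range(n):
        if overlap > 0 and rng.random() < overlap:
            out.append(_SHARED_VOCAB[rng.integers(len(_SHARED_VOCAB))])
        else:
            out.append(vocab[rng.integers(len(vocab))])
    return out


def _sentence_text(rng, cfg: SynthConfig, label: str) -> list[str]:
    lo, hi = cfg.words_per_sentence
    n = int(rng.integers(lo, hi + 1))
    return _draw_tokens(rng, _SECTION_VOCAB[label], n, cfg.vocabulary_overlap)


def _finish(tokens: list[str]) -> str:
    text = " ".join(tokens)
    return text[0].upper() + text[1:] + "."


def _ambiguous_surfaces(genes: Sequence[GeneRecord]) -> set[str]:
    seen: dict[str, set[str]] = {}
    for g in genes:
        for name in (g.official_symbol, g.official_name, *g.synonyms):
            seen.setdefault(name.lower(), set()).add(g.gene_id)
    return {name for name, ids in seen.items() if len(ids) > 1}


def generate_corpus(config: SynthConfig | None = None) -> SynthCorpus:
    """Generate a fully annotated synthetic citation corpus.

    Every citation carries gold GeneRIF flags, gold discourse labels
    consistent with its section structure, planted gene mentions with
    known true identifiers, and (sometimes) a parenthetical abbreviation
    definition.  Reproducible from the config seed.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = default_gene_inventory()
    gene_vocab = default_gene_vocab()
    go_table = default_go_table()
    go_phrases = [v for v in go_table.values()]
    ambiguous = _ambiguous_surfaces(genes)

    citations: list[Citation] = []
    planted: list[PlantedMention] = []

    for idx in range(cfg.n_citations):
        cid = f"S{idx + 1:05d}"
        k_lo, k_hi = cfg.genes_per_citation
        k = int(rng.integers(k_lo, k_hi + 1))
        chosen = [genes[i] for i in rng.choice(len(genes), size=k, replace=False)]
        main = chosen[0]

        # section skeleton
        section_sents: list[tuple[str, list[str]]] = []  # (label, tokens)
        for label, (lo, hi) in cfg.section_lengths:
            n_sent = int(rng.integers(lo, hi + 1))
            for _ in range(n_sent):
                section_sents.append((label, _sentence_text(rng, cfg, label)))
        n_abs = len(section_sents)
        n_total = n_abs + 1

        # GO phrases in Results/Conclusions sentences
        for i, (label, toks) in enumerate(section_sents):
            if label in ("Results", "Conclusions") and rng.random() < cfg.go_phrase_prob:
                phrase = go_phrases[rng.integers(len(go_phrases))]
                insert_at = int(rng.integers(0, len(toks) + 1))
                section_sents[i] = (label, toks[:insert_at] + phrase.split() + toks[insert_at:])

        # title mentions the main gene's symbol
        title_tokens = _draw_tokens(rng, _TITLE_VOCAB, 6, cfg.vocabulary_overlap)
        title = f"{main.official_symbol} " + " ".join(title_tokens)
        planted_here = [PlantedMention(cid, 1, main.official_symbol, main.gene_id, False)]

        # abbreviation definition: long form (SYMBOL) in the first sentence,
        # short form reused later
        define_abbrev = rng.random() < cfg.abbrev_def_prob and n_abs >= 2
        if define_abbrev:
            label0, toks0 = section_sents[0]
            section_sents[0] = (
                label0,
                toks0 + main.official_name.split() + [f"({main.official_symbol})"],
            )

        # plant body mentions for each chosen gene
        for g in chosen:
            amb = [s for s in (g.official_symbol, g.official_name, *g.synonyms)
                   if s.lower() in ambiguous]
            n_mentions = int(rng.integers(1, 3))
            for j in range(n_mentions):
                sent_idx = int(rng.integers(0, n_abs))
                label, toks = section_sents[sent_idx]
                if j == 0 and amb:
                    surface = amb[0]
                    is_amb = True
                else:
                    surface = g.official_symbol
                    is_amb = False
                context = list(gene_vocab[g.gene_id][:3])
                insert_at = int(rng.integers(0, len(toks) + 1))
                new_toks = toks[:insert_at] + [surface] + context + toks[insert_at:]
                section_sents[sent_idx] = (label, new_toks)
                planted_here.append(
                    PlantedMention(cid, sent_idx + 2, surface, g.gene_id, is_amb)
                )

        # assemble sentences with gold labels
        sentences = [Sentence(position=1, text=title + ".")]
        sentences[0].gold_discourse = "Title"
        for i, (label, toks) in enumerate(section_sents):
            pos = i + 2
            s = Sentence(position=pos, text=_finish(toks))
            s.gold_discourse = label if label != "Objective" else "Purpose"
            sentences.append(s)

        # GeneRIF flags by position class
        for s in sentences:
            if s.position == 1:
                p = cfg.p_positive_title
            elif s.position >= n_total - 1:
                p = cfg.p_positive_last_two
            else:
                p = cfg.p_positive_body
            s.gold_generif = bool(rng.random() < p)
            if s.gold_generif:
                s.gold_claim = "Established" if rng.random() < 0.7 else "Putative"
                subcats = ("Function", "Expression", "Structure", "Isolation",
                           "Reference", "Other")
                weights = np.array([0.45, 0.2, 0.1, 0.05, 0.1, 0.1])
                s.gold_subcategory = subcats[
                    int(rng.choice(len(subcats), p=weights))
                ]
            else:
                s.gold_claim = "Non-Claim"

        # abstract text and structured sections
        sections: list[tuple[str, str]] = []
        i = 0
        for label in SECTION_ORDER:
            chunk = [
                s.text for (lab, _), s in zip(section_sents, sentences[1:]) if lab == label
            ]
            if chunk:
                sections.append((_HEADING_OF[label], " ".join(chunk)))
        abstract = " ".join(s.text for s in sentences[1:])

        ranges = []
        pos = 2
        for heading, chunk_text in sections:
            n_in = sum(
                1 for (lab, _) in section_sents if _HEADING_OF[lab] == heading
            )
            ranges.append((heading, (pos, pos + n_in - 1)))
            pos += n_in

        cit = Citation(
            citation_id=cid,
            title=title + ".",
            abstract=abstract,
            journal="Synthetic Journal of Human Genetics",
            publication_types={"Journal Article"},
            mesh_headings={"Humans"},
            abstract_sections=sections if cfg.structured_headings else None,
            section_labels=ranges if cfg.structured_headings else None,
            sentences=sentences,
        )
        citations.append(cit)
        planted.extend(planted_here)

    # per-gene profile texts from the gene vocabularies
    profile_texts: dict[str, list[str]] = {}
    for g in genes:
        vocab = gene_vocab[g.gene_id]
        texts = []
        for _ in range(5):
            toks = _draw_tokens(rng, vocab, 8, 0.0)
            texts.append(_finish(toks))
        profile_texts[g.gene_id] = texts

    return SynthCorpus(
        citations=citations,
        gene_records=genes,
        go_table=go_table,
        true_mentions=planted,
        profile_texts=profile_texts,
        config=cfg,
    )


def generate_structured_abstracts(
    config: SynthConfig | None = None,
) -> tuple[list[Citation], list[Citation]]:
    """Labeled structured abstracts for discourse training, pre-split
    2/3 train, 1/3 test.

    Sentences carry gold discourse labels matching their generating
    section (``Objective`` stored as gold ``Purpose`` per the 6-way gold
    scheme; the distilled heading labels are available via
    ``section_labels``).
    """
    cfg = config or SynthConfig()
    corpus = generate_corpus(replace(cfg, abbrev_def_prob=0.0, go_phrase_prob=0.0,
                                     genes_per_citation=(1, 1)))
    n_train = (2 * len(corpus.citations)) // 3
    return corpus.citations[:n_train], corpus.citations[n_train:]
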