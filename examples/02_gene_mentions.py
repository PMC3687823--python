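"""Find and normalize gene mentions with the dictionary matcher.

Builds a tiny lexicon (including an ambiguous synonym and a dash
variant), expands a parenthetical abbreviation, and resolves candidates
by officialness and by context profiles.
"""

from rifsel.corpus import Citation, segment_sentences
from rifsel.lexicon import GeneRecord, build_dictionary, build_profiles
from rifsel.pipeline import annotate_mentions

records = [
    GeneRecord("101", "VEGFA", "vascular endothelial growth factor A", ["VEGF"]),
    GeneRecord("105", "EBP1", "ErbB3 binding protein 1", ["p40"]),
    GeneRecord("106", "SQSTM1", "sequestosome 1", ["p40", "p62"]),
    GeneRecord("103", "CTXN2", "cortexin 2", ["cortexin-2"]),
]
dictionary = build_dictionary(records)
print(f"dictionary entries (longest first): {[f for f, _ in dictionary.entries][:4]} ...")

profiles = build_profiles(
    {
        "101": ["angiogenesis vascular endothelium permeability"],
        "105": ["ribosome biogenesis nucleolar proliferation"],
        "106": ["autophagy ubiquitin aggregate inclusion"],
        "103": ["cortex neuronal membrane"],
    }
)

citation = segment_sentences(
    Citation(
        "9003",
        "Cortexin2 and p40 in autophagy.",
        "Levels of vascular endothelial growth factor A (VEGFA) were measured. "
        "The p40 protein localised to ubiquitin positive aggregate structures. "
        "VEGFA rose while cortexin-2 did not.",
    )
)

for m in annotate_mentions(citation, dictionary, profiles=profiles):
    print(
        f"sentence {m.sentence_position}: {m.matched_text!r} "
        f"candidates={sorted(m.candidate_ids)} resolved={m.resolved_id}"
    )

# "Cortexin2" matches through the generated dash-removed variant; the
# ambiguous "p40" resolves to SQSTM1 (gene 106) because its sentence talks
# about autophagy and ubiquitin; the second "VEGFA" demonstrates that the
# abbreviation defined in sentence 2 is matched via its expanded long form.
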