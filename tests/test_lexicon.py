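"""Gene lexicon: dictionary, variants, abbreviations, matching,
normalization — with independent oracles for matching and profiles."""

import math
import re

import numpy as np
import pytest

from rifsel import synthdata
from rifsel.corpus import Sentence
from rifsel.lexicon import (
    GeneDictionary,
    GeneMention,
    GeneRecord,
    build_dictionary,
    build_profiles,
    disambiguate_official,
    disambiguate_profile,
    expand_abbreviations,
    generate_variants,
    match_mentions,
)
from rifsel.pipeline import annotate_mentions


class TestVariants:
    def test_single_dash_name_yields_space_and_removed_variants(self):
        assert generate_variants("cortexin-2") == {"cortexin 2", "cortexin2"}

    @pytest.mark.parametrize("name", ["tp53", "nf-kappa-b", "plain name"])
    def test_zero_or_multi_dash_names_yield_nothing(self, name):
        assert generate_variants(name) == set()

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            generate_variants("")


class TestBuildDictionary:
    def test_banned_suffix_names_excluded(self):
        recs = [GeneRecord("g1", "APP", "Alzheimer disease", ["amyloid precursor"])]
        d = build_dictionary(recs)
        forms = {f.lower() for f, _ in d.entries}
        assert "alzheimer disease" not in forms
        assert "amyloid precursor" in forms

    @pytest.mark.parametrize("name", ["x syndrome", "y susceptibility"])
    def test_other_banned_suffixes(self, name):
        d = build_dictionary([GeneRecord("g1", "OK", name, [])])
        assert all(not f.lower().endswith(("syndrome", "susceptibility")) for f, _ in d.entries)

    def test_shared_synonym_merges_candidates(self):
        recs = [
            GeneRecord("g1", "A1", "alpha one", ["p40"]),
            GeneRecord("g2", "B2", "beta two", ["p40"]),
        ]
        d = build_dictionary(recs)
        assert set(d.candidates("p40")) == {"g1", "g2"}

    def test_longest_first_ordering(self):
        recs = [
            GeneRecord("g1", "CTXN", "cortexin", []),
            GeneRecord("g2", "CTXN2", "cortexin-2", []),
        ]
        d = build_dictionary(recs)
        lengths = [len(f) for f, _ in d.entries]
        assert lengths == sorted(lengths, reverse=True)
        assert d.entries[0][0].lower().startswith("cortexin")
        assert len(d.entries[0][0]) > len("cortexin")

    def test_variants_present_and_dash_free(self):
        d = build_dictionary([GeneRecord("g1", "CTXN2", "cortexin-2", [])])
        forms = {f.lower() for f, _ in d.entries}
        assert {"cortexin-2", "cortexin 2", "cortexin2"} <= forms
        # no *generated* variant contains a dash
        variants = forms - {"cortexin-2", "ctxn2"}
        assert all("-" not in v for v in variants)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            build_dictionary([])

    def test_serialization_round_trip(self, tmp_path, small_corpus):
        d = build_dictionary(small_corpus.gene_records)
        path = tmp_path / "dict.tsv"
        d.save(path)
        d2 = GeneDictionary.load(path)
        assert d.entries == d2.entries


class TestAbbreviations:
    def test_schwartz_hearst_long_form_replaces_later_short_form(self):
        text = (
            "Levels of vascular endothelial growth factor (VEGF) were "
            "measured. VEGF rose after treatment."
        )
        expanded, mapping = expand_abbreviations(text)
        assert mapping == {"VEGF": "vascular endothelial growth factor"}
        assert "vascular endothelial growth factor rose after" in expanded
        # the definition itself is untouched
        assert "(VEGF)" in expanded

    def test_numeric_parenthetical_ignored(self):
        text = "The cohort (n = 25) was small."
        expanded, mapping = expand_abbreviations(text)
        assert expanded == text
        assert mapping == {}

    def test_no_parentheses_is_identity(self):
        text = "Nothing to expand here."
        assert expand_abbreviations(text) == (text, {})

    def test_unmatched_parenthetical_left_untouched(self):
        text = "An unrelated aside (XYZQ) follows. XYZQ again."
        expanded, mapping = expand_abbreviations(text)
        assert mapping == {}
        assert expanded == text

    def test_alignment_skips_interior_words(self):
        # S-H alignment walks right-to-left and may skip words
        text = "Treated with granulocyte colony stimulating factor (GCSF). GCSF helped."
        _, mapping = expand_abbreviations(text)
        assert mapping.get("GCSF") == "granulocyte colony stimulating factor"


def _toy_dictionary():
    return build_dictionary(
        [
            GeneRecord("g2", "CTXN2", "cortexin 2", []),
            GeneRecord("g1", "CTXN", "cortexin", []),
        ]
    )


class TestMatching:
    def test_longest_match_wins(self):
        d = _toy_dictionary()
        ms = match_mentions(Sentence(1, "cortexin 2 binds actin"), d, homonym_list=set())
        assert len(ms) == 1
        assert ms[0].matched_text == "cortexin 2"
        assert ms[0].candidate_ids == {"g2"}

    def test_homonym_requires_exact_case(self):
        d = build_dictionary([GeneRecord("g1", "WAS", "WASP factor", [])])
        lower = match_mentions(Sentence(1, "He was tired"), d, homonym_list={"WAS"})
        upper = match_mentions(Sentence(1, "WAS deficiency is rare"), d, homonym_list={"WAS"})
        assert lower == []
        assert len(upper) == 1 and upper[0].matched_text == "WAS"

    def test_disjoint_names_give_non_overlapping_spans(self):
        d = _toy_dictionary()
        ms = match_mentions(
            Sentence(1, "cortexin 2 regulates cortexin levels"), d, homonym_list=set()
        )
        assert len(ms) == 2
        (a, b) = sorted(m.span for m in ms)
        assert a[1] <= b[0]

    def test_match_requires_token_boundary(self):
        d = build_dictionary([GeneRecord("g1", "CAT", "catalase gene", [])])
        ms = match_mentions(Sentence(1, "concatenation of files"), d, homonym_list=set())
        assert ms == []


def _exhaustive_leftmost_longest(text, dictionary):
    """Independent oracle: enumerate every token-boundary match of every
    dictionary form, then repeatedly commit the leftmost (then longest)
    match and discard overlaps."""
    lower = text.lower()
    token_starts = [m.start() for m in re.finditer(r"\w+", text)]
    all_matches = []
    for form, _ in dictionary.entries:
        fl = form.lower()
        for i in token_starts:
            j = i + len(fl)
            if lower[i:j] != fl:
                continue
            if j < len(text) and (text[j].isalnum() or text[j] == "_"):
                continue
            all_matches.append((i, j))
    chosen = []
    while all_matches:
        start = min(m[0] for m in all_matches)
        at_start = [m for m in all_matches if m[0] == start]
        best = max(at_start, key=lambda m: m[1] - m[0])
        chosen.append(best)
        all_matches = [m for m in all_matches if m[0] >= best[1]]
    return chosen


class TestMatchingOracle:
    def test_greedy_equals_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(42)
        alphabet = ["alpha", "beta", "gamma", "delta", "p40", "kin", "ase", "x1"]
        for _ in range(1000):
            n_entries = int(rng.integers(1, 21))
            records = []
            for k in range(n_entries):
                n_tok = int(rng.integers(1, 4))
                name = " ".join(
                    alphabet[int(rng.integers(len(alphabet)))] for _ in range(n_tok)
                )
                records.append(GeneRecord(f"g{k}", name, f"name {k} zzz", []))
            d = build_dictionary(records)
            n_words = int(rng.integers(1, 31))
            sentence = " ".join(
                alphabet[int(rng.integers(len(alphabet)))] for _ in range(n_words)
            )
            got = [m.span for m in match_mentions(Sentence(1, sentence), d, homonym_list=set())]
            want = _exhaustive_leftmost_longest(sentence, d)
            assert got == want, f"sentence={sentence!r}"


class TestNormalization:
    def _ambig(self):
        recs = [
            GeneRecord("gA", "AAA", "alpha gene", ["shared"]),
            GeneRecord("gB", "shared", "beta gene", []),
        ]
        return build_dictionary(recs)

    def _mention(self, cands):
        return GeneMention(1, (0, 6), "shared", frozenset(cands))

    def test_official_symbol_beats_synonym(self):
        d = self._ambig()
        m = disambiguate_official(self._mention({"gA", "gB"}), d)
        assert m.resolved_id == "gB"  # gB holds "shared" as official symbol

    def test_singleton_resolves_to_itself(self):
        d = self._ambig()
        assert disambiguate_official(self._mention({"gA"}), d).resolved_id == "gA"

    def test_synonym_tie_breaks_to_smaller_id(self):
        recs = [
            GeneRecord("g1", "X1", "one", ["dup"]),
            GeneRecord("g2", "X2", "two", ["dup"]),
        ]
        d = build_dictionary(recs)
        m = GeneMention(1, (0, 3), "dup", frozenset({"g1", "g2"}))
        assert disambiguate_official(m, d).resolved_id == "g1"


class TestProfiles:
    def test_profile_weights_follow_log_idf_convention(self):
        texts = {
            "g1": ["kinase signaling kinase"],
            "g2": ["ribosome biogenesis"],
            "g3": ["kinase ribosome"],
        }
        profiles = build_profiles(texts)
        # df(kinase)=2 of 3 genes, tf in g1 = 2
        assert profiles["g1"].term_weights["kinase"] == pytest.approx(
            2 * math.log(3 / 2)
        )
        # term in every gene would get weight 0 -> absent from discrimination
        assert profiles["g2"].term_weights["ribosome"] == pytest.approx(math.log(3 / 2))

    def test_disjoint_vocabularies_give_disjoint_support(self):
        profiles = build_profiles({"g1": ["alpha beta"], "g2": ["gamma delta"]})
        s1 = set(profiles["g1"].term_weights)
        s2 = set(profiles["g2"].term_weights)
        assert s1.isdisjoint(s2)

    def test_stopword_only_text_is_configuration_error(self):
        with pytest.raises(ValueError, match="gX"):
            build_profiles({"gX": ["the of and"], "gY": ["kinase"]})

    def test_context_overlap_selects_matching_candidate(self):
        profiles = build_profiles(
            {"g1": ["angiogenesis vascular"], "g2": ["autophagy ubiquitin"],
             "g3": ["actin cytoskeleton"]}
        )
        d = build_dictionary(
            [
                GeneRecord("g1", "S1", "one", ["p40"]),
                GeneRecord("g2", "S2", "two", ["p40"]),
                GeneRecord("g3", "S3", "three", ["p40"]),
            ]
        )
        m = GeneMention(1, (0, 3), "p40", frozenset({"g1", "g2", "g3"}))
        out = disambiguate_profile(m, ["autophagy marker ubiquitin"], profiles, d)
        assert out.resolved_id == "g2"

    def test_all_zero_similarity_falls_back_to_officialness(self):
        profiles = build_profiles({"g1": ["alpha"], "g2": ["beta"]})
        d = build_dictionary(
            [GeneRecord("g1", "p40", "one", []), GeneRecord("g2", "S2", "two", ["p40"])]
        )
        m = GeneMention(1, (0, 3), "p40", frozenset({"g1", "g2"}))
        out = disambiguate_profile(m, ["unrelated words"], profiles, d)
        assert out.resolved_id == "g1"  # official symbol wins on fallback

    def test_missing_profile_falls_back(self):
        profiles = build_profiles({"g1": ["alpha"], "g9": ["beta"]})
        d = build_dictionary(
            [GeneRecord("g1", "p40", "one", []), GeneRecord("g2", "S2", "two", ["p40"])]
        )
        m = GeneMention(1, (0, 3), "p40", frozenset({"g1", "g2"}))
        out = disambiguate_profile(m, ["alpha"], profiles, d)
        assert out.resolved_id == "g1"


class TestDisambiguationRecovery:
    def test_profile_disambiguation_recovers_planted_ambiguous_mentions(self):
        """On a synthetic corpus with an ambiguous name shared by two genes
        (disjoint vocabularies, contexts from the true gene), >= 95% of at
        least 200 planted ambiguous mentions resolve correctly."""
        synth = synthdata.generate_corpus(
            synthdata.SynthConfig(seed=17, n_citations=1000)
        )
        dictionary = build_dictionary(synth.gene_records)
        profiles = build_profiles(synth.profile_texts)
        truth = {
            (p.citation_id, p.position, p.surface.lower()): p.true_gene_id
            for p in synth.true_mentions
            if p.ambiguous
        }
        assert len(truth) >= 200
        correct = total = 0
        by_cit = {c.citation_id: c for c in synth.citations}
        for (cid, pos, surface), true_id in truth.items():
            mentions = annotate_mentions(by_cit[cid], dictionary, profiles=profiles)
            for m in mentions:
                if m.sentence_position == pos and m.matched_text.lower() == surface:
                    total += 1
                    correct += m.resolved_id == true_id
                    break
        assert total >= 200
        assert correct / total >= 0.95
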