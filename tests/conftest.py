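"""Shared fixtures: synthetic corpora and trained discourse labelers.

Heavy artifacts (trained labelers, large corpora) are session-scoped so
unit tests and acceptance tests reuse one instance.
"""

from __future__ import annotations

import pytest

from rifsel import discourse, lexicon, synthdata


@pytest.fixture(scope="session")
def small_corpus() -> synthdata.SynthCorpus:
    """80 citations; enough for unit tests of mentions/features/filters."""
    return synthdata.generate_corpus(synthdata.SynthConfig(seed=3, n_citations=80))


@pytest.fixture(scope="session")
def study_corpus() -> synthdata.SynthCorpus:
    """The study-sized corpus: 550 citations (400 train / 150 test)."""
    return synthdata.generate_corpus(synthdata.SynthConfig(seed=11, n_citations=550))


@pytest.fixture(scope="session")
def gene_dictionary(small_corpus) -> lexicon.GeneDictionary:
    return lexicon.build_dictionary(small_corpus.gene_records)


@pytest.fixture(scope="session")
def structured_split():
    """2,000 structured abstracts pre-split 2/3 train / 1/3 test."""
    cfg = synthdata.SynthConfig(seed=21, n_citations=2000)
    return synthdata.generate_structured_abstracts(cfg)


@pytest.fixture(scope="session")
def discourse_ensemble(structured_split) -> discourse.DiscourseModel:
    train, _ = structured_split
    kept, lookup = discourse.distill_corpus(train)
    return discourse.train_binary_ensemble(kept, lookup, seed=0)


@pytest.fixture(scope="session")
def discourse_crf(structured_split) -> discourse.DiscourseModel:
    train, _ = structured_split
    kept, lookup = discourse.distill_corpus(train)
    return discourse.train_crf(kept, lookup, seed=0)
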