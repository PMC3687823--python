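"""Discourse zoning: label distillation, both labelers, evaluation."""

import numpy as np
import pytest

from rifsel import discourse, synthdata
from rifsel.corpus import Citation, segment_sentences
from rifsel.discourse import (
    CORE_LABELS,
    distill_corpus,
    distill_labels,
    evaluate_discourse,
    predict_discourse,
    train_binary_ensemble,
    train_crf,
)


def _structured_citation(sections, cid="x"):
    text = " ".join(t for _, t in sections)
    c = Citation(cid, "Title here.", text, abstract_sections=list(sections))
    return segment_sentences(c)


class TestDistillLabels:
    def test_sentences_inherit_section_label(self):
        c = _structured_citation(
            [("BACKGROUND", "B one. B two."), ("RESULTS", "R one. R two. R three.")]
        )
        labels = distill_labels(c)
        assert labels == [
            (1, "Title"),
            (2, "Background"),
            (3, "Background"),
            (4, "Results"),
            (5, "Results"),
            (6, "Results"),
        ]

    def test_heading_variants_map_to_canonical_label(self):
        c = _structured_citation([("AIM", "We aimed high."), ("RESULTS", "R one.")])
        labels = dict(distill_labels(c))
        assert labels[2] == "Objective"

    def test_unmapped_heading_skips_citation(self):
        c = _structured_citation([("PATIENTS", "P one."), ("RESULTS", "R one.")])
        assert distill_labels(c) is None

    def test_overlapping_ranges_are_a_data_error(self):
        c = _structured_citation([("BACKGROUND", "B one. B two.")])
        c.section_labels = [("BACKGROUND", (2, 3)), ("RESULTS", (3, 3))]
        with pytest.raises(ValueError, match="overlapping"):
            distill_labels(c)

    def test_distilled_count_equals_abstract_sentence_count(self, structured_split):
        train, _ = structured_split
        kept, lookup = distill_corpus(train[:50])
        for c in kept:
            assert len(lookup[c.citation_id]) == c.n_sentences - 1


@pytest.fixture(scope="module")
def small_structured():
    cfg = synthdata.SynthConfig(seed=29, n_citations=240)
    return synthdata.generate_structured_abstracts(cfg)


@pytest.fixture(scope="module")
def small_ensemble(small_structured):
    train, _ = small_structured
    kept, lookup = distill_corpus(train)
    return train_binary_ensemble(kept, lookup, seed=0, max_features=150, max_iter=40)


@pytest.fixture(scope="module")
def small_crf(small_structured):
    train, _ = small_structured
    kept, lookup = distill_corpus(train[:80])
    return train_crf(kept, lookup, seed=0, max_features=100, max_iter=80)


class TestBinaryEnsemble:
    def test_recovers_planted_section_signal(self, small_structured, small_ensemble):
        _, test = small_structured
        kept, lookup = distill_corpus(test)
        table = evaluate_discourse(small_ensemble, kept, lookup)
        assert (table["F-measure"] >= 0.9).all()

    def test_same_seed_retrain_gives_identical_predictions(self, small_structured):
        train, test = small_structured
        kept, lookup = distill_corpus(train[:80])
        m1 = train_binary_ensemble(kept, lookup, seed=5, max_features=100, max_iter=30)
        m2 = train_binary_ensemble(kept, lookup, seed=5, max_features=100, max_iter=30)
        probe = test[0]
        assert predict_discourse(m1, probe) == predict_discourse(m2, probe)

    def test_single_label_training_set_rejected(self, small_structured):
        train, _ = small_structured
        kept, _ = distill_corpus(train[:40])
        only_results = {
            c.citation_id: {p: "Results" for p in range(2, c.n_sentences + 1)}
            for c in kept
        }
        with pytest.raises(ValueError, match="at least 2"):
            train_binary_ensemble(kept, only_results, seed=0)

    def test_low_support_label_named_in_error(self, small_structured):
        train, _ = small_structured
        kept, lookup = distill_corpus(train[:40])
        # flip a single sentence to Background-starved label setup
        starved = {cid: dict(m) for cid, m in lookup.items()}
        for cid in starved:
            starved[cid] = {
                p: ("Results" if lab != "Background" else lab)
                for p, lab in starved[cid].items()
            }
        # keep only 1 Background sentence overall
        seen = 0
        for cid in starved:
            for p, lab in list(starved[cid].items()):
                if lab == "Background":
                    seen += 1
                    if seen > 1:
                        starved[cid][p] = "Results"
        with pytest.raises(ValueError, match="Background"):
            train_binary_ensemble(kept, starved, seed=0)


class TestSequenceModel:
    def test_predictions_respect_canonical_section_order(
        self, small_structured, small_crf
    ):
        _, test = small_structured
        order = {lab: i for i, lab in enumerate(CORE_LABELS)}
        for c in test[:40]:
            labels = [lab for pos, lab, _ in predict_discourse(small_crf, c) if pos > 1]
            ranks = [order[lab] for lab in labels]
            assert ranks == sorted(ranks), c.citation_id

    def test_single_sentence_abstract_predicts_one_label(self, small_crf):
        c = segment_sentences(Citation("y", "Title.", "Novel suggest conclude target."))
        out = predict_discourse(small_crf, c)
        assert len(out) == 2
        assert out[0] == (1, "Title", 1.0)
        assert out[1][1] in CORE_LABELS

    def test_same_seed_retrain_gives_identical_weights_hash(self, small_structured):
        train, _ = small_structured
        kept, lookup = distill_corpus(train[:60])
        m1 = train_crf(kept, lookup, seed=1, max_features=80, max_iter=50)
        m2 = train_crf(kept, lookup, seed=1, max_features=80, max_iter=50)
        assert m1.crf.weights_hash() == m2.crf.weights_hash()

    def test_empty_sequence_is_a_data_error(self, small_structured):
        train, _ = small_structured
        kept, lookup = distill_corpus(train[:10])
        broken = dict(lookup)
        broken[kept[0].citation_id] = {}
        with pytest.raises(ValueError, match="incomplete"):
            train_crf(kept, broken, seed=0)


class TestPredictDiscourse:
    def test_title_always_gets_title_label_with_full_confidence(
        self, small_ensemble, small_crf, small_structured
    ):
        _, test = small_structured
        for model in (small_ensemble, small_crf):
            out = predict_discourse(model, test[0])
            assert out[0] == (1, "Title", 1.0)

    def test_ensemble_abstains_when_no_scorer_is_confident(self, small_ensemble):
        import dataclasses

        strict = dataclasses.replace(small_ensemble, threshold=1.01)
        c = segment_sentences(Citation("z", "Title.", "Observed significant increased."))
        out = predict_discourse(strict, c)
        assert all(lab == "Unknown" for pos, lab, _ in out if pos > 1)

    def test_sequence_model_never_abstains(self, small_crf, small_structured):
        _, test = small_structured
        for c in test[:10]:
            labels = {lab for pos, lab, _ in predict_discourse(small_crf, c)}
            assert "Unknown" not in labels

    def test_untrained_model_is_a_usage_error(self, small_ensemble):
        import dataclasses

        broken = dataclasses.replace(small_ensemble, scorers=None)
        c = segment_sentences(Citation("z", "Title.", "Some text."))
        with pytest.raises(RuntimeError, match="untrained"):
            predict_discourse(broken, c)


class TestEvaluateDiscourse:
    def test_perfect_predictions_score_one_everywhere(
        self, small_structured, small_ensemble
    ):
        # the separable corpus is learned perfectly: P = R = F = 1 per label
        _, test = small_structured
        kept, lookup = distill_corpus(test[:60])
        table = evaluate_discourse(small_ensemble, kept, lookup)
        assert (table[["Precision", "Recall", "F-measure"]] == 1.0).all().all()

    def test_all_unknown_predictions_give_zero_recall(
        self, small_structured, small_ensemble
    ):
        import dataclasses

        strict = dataclasses.replace(small_ensemble, threshold=1.01)
        _, test = small_structured
        kept, lookup = distill_corpus(test[:20])
        table = evaluate_discourse(strict, kept, lookup)
        assert (table["Recall"] == 0.0).all()

    def test_counts_yield_closed_form_prf(self, monkeypatch, small_ensemble):
        # constructed confusion: Positives=6, TP=3, FP=1 -> P=.75, R=.5, F=.6
        gold = ["Methods"] * 6 + ["Results"] * 4
        pred = ["Methods"] * 3 + ["Results"] * 3 + ["Methods"] + ["Results"] * 3
        cits = []
        lookup = {}
        for i, (g, p) in enumerate(zip(gold, pred)):
            c = segment_sentences(Citation(f"c{i}", "T.", "One sentence."))
            cits.append(c)
            lookup[f"c{i}"] = {2: g}
        fake = iter(pred)
        monkeypatch.setattr(
            discourse,
            "predict_discourse",
            lambda model, cit: [(1, "Title", 1.0), (2, next(fake), 0.9)],
        )
        table = evaluate_discourse(small_ensemble, cits, lookup)
        row = table.loc["Methods"]
        assert row["Positives"] == 6 and row["TP"] == 3 and row["FP"] == 1
        assert row["Precision"] == pytest.approx(0.75)
        assert row["Recall"] == pytest.approx(0.5)
        assert row["F-measure"] == pytest.approx(0.6)

    def test_empty_test_set_is_a_usage_error(self, small_ensemble):
        with pytest.raises(ValueError, match="empty"):
            evaluate_discourse(small_ensemble, [])
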