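"""Train discourse labelers on synthetic structured abstracts and zone a
citation's sentences.

Structured abstracts carry section headings (BACKGROUND, OBJECTIVE, ...)
that act as distant supervision; two labelers are trained and compared on
a held-out third.
"""

from rifsel.discourse import (
    distill_corpus,
    evaluate_discourse,
    predict_discourse,
    train_binary_ensemble,
    train_crf,
)
from rifsel.synthdata import SynthConfig, generate_structured_abstracts

train_set, test_set = generate_structured_abstracts(
    SynthConfig(seed=42, n_citations=300)
)
kept_train, labels_train = distill_corpus(train_set)
kept_test, labels_test = distill_corpus(test_set)

ensemble = train_binary_ensemble(kept_train, labels_train, seed=0)
crf = train_crf(kept_train, labels_train, seed=0)

for name, model in (("binary ensemble", ensemble), ("linear-chain CRF", crf)):
    table = evaluate_discourse(model, kept_test, labels_test)
    print(f"\n{name} on {len(kept_test)} held-out abstracts:")
    print(table.round(4))

print("\nzoning one citation with the ensemble:")
for pos, label, conf in predict_discourse(ensemble, kept_test[0]):
    print(f"  [{pos}] {label} ({conf:.2f})")

# Per-label Positives/TP/FP and P/R/F; on this separable vocabulary both
# labelers reach F = 1.0.  The zoned citation shows the forced Title label
# at position 1 and section labels tracking the generated structure.
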