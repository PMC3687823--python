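# Methods

This note documents the models and procedures implemented in `rifsel`,
the assumptions they make, the parameters that matter, and the design
choices taken where the design was genuinely open.

## The task

Given a MEDLINE-style citation (title + abstract), decide for every
sentence whether it is a candidate GeneRIF — a statement of novel gene
function worth curating against an NCBI Gene identifier — and present
the top three sentences by classifier confidence. The signal is mostly
*structural*: functional claims concentrate in the title and in the
concluding sentences, so sentence position and rhetorical role carry
more information than the sentence's own tokens. The package treats the
problem as binary per-sentence text categorization enriched with derived
features, plus the supporting machinery (gene-name normalization,
discourse zoning, citation filtering) that a production curation
assistant needs.

## Sentence model and segmentation

Sentences are numbered from 1 with the title as sentence 1; abstract
sentences follow in order. Segmentation is rule-based: a sentence
boundary is terminal punctuation (`.!?`) followed by whitespace, unless
the preceding token is on a protected-abbreviation list (`e.g.`, `i.e.`,
`vs.`, `Fig.`, `et al.`, ...) or is a single-letter initial. This is
deterministic and testable; it does not attempt the coverage of a
statistical splitter, and multi-paragraph abstracts are concatenated
with a single space before splitting. Character offsets inside sentences
are 0-based and half-open.

## Gene lexicon and normalization

The dictionary is built from gene records (identifier, official symbol,
official name, synonyms, mirroring the public `gene_info` layout).
Every name contributes itself plus punctuation variants: a name with
exactly one dash yields a dash-to-space and a dash-removed variant
(`cortexin-2` → `cortexin 2`, `cortexin2`); names with zero or several
dashes yield nothing (multi-dash names have too many plausible
rewritings for this simple scheme). Names ending in *disease*,
*syndrome* or *susceptibility* are dropped as misleading. Entries are
sorted longest-to-shortest (ties lexicographic) so the matcher finds a
full name before any component.

Matching is greedy leftmost-longest at token boundaries,
case-insensitive except for surface forms on the shipped homonym list
(`WAS`, `CAT`, `SET`, ...), which must match exactly — the list is an
editable text resource, since no published inventory of such collisions
exists. Matching operates on abbreviation-expanded text: parenthetical
definitions are resolved with the Schwartz–Hearst character alignment
(walk the short form right-to-left, match each alphanumeric character
leftwards in the candidate long form; the first character must start a
word), and later occurrences of the short form are replaced by the long
form before matching.

Ambiguous mentions (several candidate identifiers) are normalized two
ways:

- **Officialness**: official symbol (rank 0) beats official name (rank
  1) beats synonym (rank 2); remaining ties break to the smallest gene
  id for determinism.
- **Context profiles**: each gene gets a tf-idf term vector over
  lowercased, stop-word-filtered tokens of its training texts, with
  idf = log(N/df) over the gene set (a term present for every gene is
  weightless). The mention's context — its sentence plus `w` neighbor
  sentences, default `w = 0` exposed in config — is compared to each
  candidate profile by cosine similarity; ties and missing profiles fall
  back to officialness. Cosine over tf-idf is the standard
  scale-invariant choice; richer profile channels (MeSH, ontology
  annotations, parsed relations) are an extension point, not
  implemented.

## Discourse zoning

Structured abstracts provide distant supervision: each abstract sentence
inherits the canonical label of its enclosing section via an editable
heading map (AIM/AIMS/PURPOSE → Objective, CONCLUSION → Conclusions,
...); citations with any unmapped heading are skipped rather than
partially labeled. The title is always labeled `Title`.

Two labelers are trained on bag-of-words (capped vocabulary, default
300 terms) plus the two position features:

- **Binary ensemble**: one boosted-decision-trees scorer
  (histogram-based gradient boosting, 80 rounds, fixed seed) per label
  in {Background, Objective, Methods, Results, Conclusions}. At
  prediction time the most confident scorer wins; if none clears the
  0.5 posterior threshold the sentence is labeled `Unknown` —
  abstention is a legitimate outcome, and equal-confidence ties break by
  a fixed label-priority order for determinism.
- **Sequence model**: a linear-chain CRF implemented in-package
  (emission weights over the same features, transition/start/end weights
  over labels; L2-regularized negative log-likelihood minimized with
  L-BFGS, gradients by forward–backward). Prediction is the Viterbi
  path with per-position posterior marginals as confidences; the
  sequence model always commits to a label.

Corpus size for discourse training is a config knob; the shipped
defaults train on a few thousand abstracts, which is where the synthetic
task saturates.

## Features

- `pos` — sentence number from the start (title = 1).
- `posf` — total sentence count minus sentence number (last sentence
  = 0), capturing distance from the end; `pos + posf = N` is an
  invariant checked corpus-wide.
- `text` — lowercased, stop-word-filtered token counts, unigrams or
  bigrams of consecutive surviving tokens. Count weighting (rather than
  binary) is the default and is exposed in config. The stop-word list
  is a packaged snapshot of a standard English list.
- `gene` — three columns per sentence: mention count, distinct resolved
  gene ids, binary presence. The encoding supersets any single choice;
  learners ignore what they do not need.
- `dis` / `disg` — a one-hot over {Background, Objective, Methods,
  Results, Conclusions, Title, Unknown}. `dis` is fed by a trained
  labeler (ensemble or sequence, selected by `discourse_source`);
  `disg` uses the citation's gold annotation, with the 6-way gold label
  `Purpose` mapped onto the `Objective` column so both sources share one
  vocabulary. A config may use one or the other, not both.
- `go` — Gene Ontology terminology density: greedy leftmost-longest
  non-overlapping matching of GO-term token sequences, scored as
  Σ(match length)² normalized by sentence token count. The quadratic
  numerator rewards long, specific term matches; the normalization makes
  the score invariant under sentence self-concatenation. This is a
  self-contained stand-in for external GO-annotation scorers and its
  scale is **not** comparable to theirs.

## Selection classifiers

Four learners standard in text categorization: Naïve Bayes (Gaussian
likelihoods per feature), linear-kernel SVM, a decision tree, and
AdaBoost over decision trees (10 rounds, unrestricted depth, both
exposed in config). SVM margins are mapped to probabilities by a
logistic (Platt) calibration fitted on training folds, since a margin is
not a confidence. Evaluation reports precision, recall and F on the
GeneRIF-positive class only; with zero positive predictions precision is
defined as 0 (logged), consistent with the F = 0 convention. Ranking
returns up to three sentences per citation by descending confidence,
ties to the smaller position.

## Citation filtering

Journal level: a journal is accepted iff strictly fewer than 40% of its
citations contain one of the 11 model-species terms (mouse, murine,
yeast, fly, drosophila, cow, cattle, bovine, worm, c. elegans, plant) as
a whole token, case-insensitively. Citation level, in order: drop
citations without an abstract; drop citations whose MeSH headings
include a shipped non-human organism descriptor *and* lack `Humans`
(the conjunction is this package's predicate — indexing practice often
adds organism headings alongside `Humans` for comparative work); keep
only citations with at least one gene mention; drop reviews with three
or more distinct resolved genes; keep only publication types Journal
Article, Meta-Analysis or Review. The report reconciles exactly
(input = survivors + Σ removed) and the cascade is idempotent. Rules
requiring human judgment (single-patient case reports, "basic biology
is the primary point") are out of scope, as is the journal-descriptor
selection step, which expects a pre-filtered journal list as input.

## Synthetic data

The generator emulates the structure the method exploits, not the
language. Each citation has a title plus Background (1–2 sentences),
Objective (1), Methods (1–2), Results (2–3) and Conclusions (exactly 2)
sections, each drawing tokens from its own vocabulary; a
`vocabulary_overlap` knob moves tokens to a shared pool to degrade
separability. GeneRIF positives are placed by position class —
P(positive) = 0.97 for the title, 0.95 for the last two sentences, 0.16
elsewhere — chosen so the overall positive rate lands near the ~42%
regime of the curated sets while the title and tail dominate, matching
the observed GeneRIF position distribution; with these rates the
Bayes-optimal (title + last-two) rule has an analytic F around 0.83,
which is what a well-calibrated position+discourse classifier should
approach. Fixing Conclusions at two sentences aligns the discourse
one-hot with the last-two position class. A toy eight-gene inventory
plants mentions (symbols in titles, names/synonyms in the body),
including an ambiguous synonym shared by two genes whose surrounding
tokens come from the true gene's vocabulary, a single-dash name, the
homonym `WAS`, and — in ~30% of citations — a parenthetical
abbreviation definition whose long form aligns under Schwartz–Hearst.
Everything is a pure function of the config seed; regeneration is
byte-identical.

What passing on this corpus shows: the pipeline recovers planted
positional/discourse/lexical structure end to end, the matchers and
metrics are exact, and feature orderings (position+discourse ≫ position
alone) reproduce under the planted regime. What it does not show:
performance on real MEDLINE text, where discourse is noisier, abstracts
are frequently unstructured, vocabulary is vastly larger, and gene-name
ambiguity is heavier-tailed than a two-way synonym collision.

## Numerical choices and degenerate inputs

- All trainings take an explicit seed; retraining with the same seed
  reproduces identical predictions (CRF: identical weight hashes).
- The study-scale defaults — 550 citations split 400/150, 2,000
  structured abstracts split 2/3–1/3 — echo the corpus sizes of the
  curated annotation regime and keep the full test suite and the
  reproduction script in the minutes range on one CPU.
- Empty abstracts segment to a single title sentence; all-stop-word
  sentences produce empty text vectors; a gene whose profile texts
  reduce to stop words (or to terms shared by every gene) is a
  configuration error naming the gene.
- The CRF optimizes to `ftol = 1e-6` with at most 150 L-BFGS iterations;
  `c2 = 1.0` L2 regularization.
- The vocabulary-overlap monotonicity check uses the linear-SVM text
  classifier: its F tracks class separability monotonically, whereas
  Gaussian NB and tree learners on small bag-of-words counts show
  non-monotone artifacts at intermediate overlap.

## Known limitations

- The rule-based segmenter and the small protected-abbreviation list
  under-segment unusual punctuation; offsets are only meaningful against
  the expanded sentence text.
- Dictionary matching scans entries longest-first per token position —
  fine for curated lexicons up to ~10⁵ entries, but not indexed for
  larger ones.
- Profile disambiguation uses token-level profiles only; context windows
  wider than the sentence are supported but default to 0.
- The GO density feature is a terminology-evidence proxy, not an
  ontology annotator: it matches surface token sequences of term names.
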