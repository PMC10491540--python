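# Methods

## Pipeline

Training runs the stages in order: read the labeled corpus → balance classes
by random under-sampling → select keyword-bearing paragraphs → hold out a
test split and plan cross-validation folds → build the vocabulary from the
training side only → one-hot encode → train the network → evaluate on the
holdout → persist artifacts. Classification of a new article first repeats
paragraph selection; only if at least one paragraph carries a keyword are the
artifacts loaded and the network invoked. This off-topic short-circuit is a
contract, not an optimization: semantic search engines occasionally return
articles containing none of the query keywords, and such articles are
rejected outright.

## Text normalization

Order: tokenize (runs of `[a-z0-9]+` after lowercasing, so hyphens and all
punctuation split tokens), drop stop words, lemmatize. The stop list is
scikit-learn's frozen 318-word English list. The lemmatizer is rule-based and
deterministic: an exception table for common irregular forms, then ordered
suffix rules for plurals (`classes→class`, `studies→study`,
`dendrites→dendrite`) and -ed/-ing verb forms with consonant undoubling
(`stopped→stop`) and a final-e restoration heuristic (`tracing→trace`,
`analyzed→analyze`). The rules are not a dictionary lemmatizer — derivational
forms like *dendritic* stay distinct from *dendrite* — but keywords and
article text pass through the same rules, so matching is self-consistent,
which is what paragraph selection and encoding require. The rule-set version
and stop-list identity are pinned in `NORMALIZER_ID` and stored inside the
vocabulary artifact, so a saved model can never silently be used under
different normalization.

Keyword matching is a contiguous-lemma-sequence search: a (possibly
multi-word) keyword matches a text when its lemma sequence occurs as a
contiguous window of the text's lemma sequence. Because stop words are
removed before matching, two content words separated only by stop words
become adjacent; keywords themselves should therefore avoid stop words
(the shipped defaults do).

## Vocabulary and encoding

The vocabulary is the `max_size` (default 10,000) most frequent lemmas by
total occurrence count over the selected paragraphs of the training split
only — test articles never influence it. Ties at the cutoff break
lexicographically so artifact bytes are reproducible. Occurrence count
rather than document frequency is the deliberate reading of "most frequent":
it is the simplest basis and the choice is pinned by tests. Encoding is
presence/absence (1 if the lemma occurs at least once), which suits short
selected text, a domain-specific vocabulary, and a binary decision;
count/TF-IDF/embedding encodings are out of scope.

## Classifier and training

Input dimension = vocabulary size; two hidden layers of 64 ReLU units; one
sigmoid output giving the relevance likelihood (relevant = 1). Loss is
per-sample squared error, averaged per mini-batch. Optimization is plain
SGD: per epoch, a seeded shuffle, batches of 8 (the final short batch is
used, its gradient averaged over its actual size), update θ ← θ − 0.01·∇θL,
30 epochs. MSE with a sigmoid output is kept as the operating configuration
rather than "upgraded" to cross-entropy; the `TrainConfig.loss` field exists
so an alternative could be added without changing call sites. Weights
initialize from U(−1/√fan_in, 1/√fan_in), seeded, breaking ReLU symmetry;
biases start at zero. Initialization and shuffling draw from independent
seeded streams, so training is bit-reproducible: identical seed, data and
configuration give byte-identical artifacts and reports (JSON serializes
floats at shortest round-trip precision). Epoch metrics are computed on the
training split after that epoch's updates. Gradient correctness is enforced
by a central-finite-difference oracle at 1e−5 in the test suite.

Note that small corpora train slowly under these settings: the MSE-sigmoid
gradient is weak and 30 epochs over a few dozen articles is few updates.
The separability guarantees exercised in tests hold at ~400 articles and
above.

## Balancing and splitting

Under-sampling removes uniformly random majority-class articles until the
classes match (seeded, minority untouched). The test holdout is
`round(0.10·n)` (ties to even), the remaining 90% is cut into 10 folds of
near-equal size for cross-validation. Splits are not stratified: after
balancing, stratification is nearly moot, and unstratified random splitting
is the plain reading of the procedure. Balancing precedes splitting.

## Thresholds and calibration

Bands are half-open and closed on the upper comparison: p < 0.18 →
auto-reject, [0.18, 0.5) → review as probably-irrelevant, [0.5, 0.98) →
review as probably-relevant, ≥ 0.98 → auto-accept. The asymmetry (0.18 vs
0.98) reflects asymmetric damage: a falsely rejected relevant article is
lost, a falsely accepted irrelevant one merely wastes a data request.
Calibration curves enumerate candidate thresholds at the observed score
values plus {0, 1} — exact, no binning. Labor saved is measured per true
class (fraction of irrelevant articles auto-rejected on the negative side,
of relevant auto-accepted on the positive); the error at a threshold is the
fraction of the auto-decided set whose gold label disagrees. The per-100
summary takes per-class band fractions and auto-side error rates (the
latter expressed against the same per-class basis so the expectations are
exact), multiplies by class share at the given prevalence, and rounds each
review count to the nearest integer and the misclassification expectation
once on the sum.

## Synthetic corpus generator

The generator emulates the statistical structure the classifier exploits:
each article has 4–10 paragraphs of background tokens (uniform draws from a
500-token background vocabulary); ~25% of paragraphs (at least one per
article) additionally carry one query keyword plus class-conditional signal
tokens — each of 6 per-class signal tokens appears in a keyword paragraph of
its own class with probability 0.8 and of the other class with 0.1. Corpus
defaults are 400 articles at 40% prevalence, matching the imbalance of the
annotated corpus the tool was built for, and the 0.7 probability gap makes
the classes strongly separable, the regime in which the deployed tool
operates. Signal tokens are disjoint from keywords so selection and
classification difficulty vary independently. Word order is arbitrary
(the classifier is order-blind) but seeded; the ledger records paragraph
counts, keyword-paragraph indices, and every planted signal token.

The PDF-degradation mode inserts running header/footer lines and splits a
configurable fraction of words with a hyphen + space, destroying token
identity the way PDF extraction does. What the generator does *not* emulate:
real English prose, correlated token co-occurrence, citation structure, or
label noise. Passing tests therefore demonstrate that the pipeline's
mechanics are correct and that it learns cleanly separable bag-of-words
structure; they do not certify accuracy on real literature, which depends on
keyword quality and corpus annotation.

## Problem sizes

The test suite and acceptance script run end-to-end training on 400-article
corpora (vocabulary ≈ 520, ≈ 290 training articles), the scale at which the
generator's separability guarantee is comfortably exercised; the degradation
comparison uses 240 articles per seed across five seeds. These sizes were
chosen as the smallest at which the statistical claims under test are stable.

## Limitations

- The lemmatizer handles inflection, not derivation; keyword lists should
  include derivational variants they care about (e.g. both "dendrite" and
  "dendritic") — exactly as curator-maintained keyword files do in practice.
- Accuracy numbers on synthetic corpora characterize the pipeline, not any
  real triage task.
- The HTTP service layer is intentionally absent; the CLI and library
  functions are the interfaces, and a REST adapter would be a thin wrapper
  over `pubtriage.services`.
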