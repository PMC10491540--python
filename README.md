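# pubtriage

Automated triage of scientific publications for biocuration. Database
projects that curate peer-reviewed findings — the motivating case is a
repository of digitally reconstructed neural morphologies — retrieve
thousands of candidate articles per year by keyword search, of which only
~10% are actually relevant. The deciding evidence is usually a few technical
sentences buried in the methods, not the article's main topic, so every
candidate otherwise needs an expert read. `pubtriage` turns that read into a
calibrated, mostly-automatic decision.

## Method

For an article given as an ordered list of paragraphs:

1. **Paragraph selection.** Keep only paragraphs containing at least one
   configured query keyword (matching is case-insensitive and lemma-aware, so
   "Sholl analyses" matches the keyword `sholl analysis`). An article with no
   keyword paragraph is *off-topic* and is rejected without classification.
2. **Encoding.** Selected text is tokenized, stripped of punctuation and stop
   words, and lemmatized; the article becomes a binary presence vector *x*
   over the 10,000 most frequent training lemmas (1 if the lemma occurs,
   0 otherwise).
3. **Classification.** A feedforward network ŷ = f(x; Θ) — layers
   h⁽ⁿ⁾ = g⁽ⁿ⁾(W⁽ⁿ⁾ᵀx + b⁽ⁿ⁾), two hidden layers of 64 ReLU units and one
   sigmoid output — returns the likelihood ŷ ∈ [0, 1] that the article is
   relevant. Training minimizes squared error (y − ŷ)² by mini-batch SGD
   (θ ← θ − α·∇θL, α = 0.01, batch 8, 30 epochs) on a corpus balanced by
   random under-sampling, with a 10% test holdout and tenfold
   cross-validation on the remainder.
4. **Triage.** Likelihoods map to four decisions via thresholds
   (0.18, 0.5, 0.98): below 0.18 auto-reject, at or above 0.98 auto-accept,
   anything between goes to manual review. The thresholds are chosen from
   labor-saved vs. misclassification curves computed on gold-labeled scores
   (`pubtriage calibrate`).

A seeded synthetic-corpus generator (`pubtriage.generate_corpus`) produces
labeled article corpora with this exact structure — keyword-bearing
"methods-like" paragraphs carrying class-discriminative tokens amid
background text, plus a PDF-degradation mode (split words, header/footer
noise) — so the whole pipeline is testable without any real corpus.

## Worked example

Train on a generated 400-article corpus (40% relevant) written out in the
`Positive_<i>.json` / `Negative_<i>.json` convention:

```python
import pubtriage as pt
cfg = pt.GeneratorConfig(seed=42, n_articles=400)
corpus, ledger = pt.generate_corpus(cfg)
pt.write_training_dir(corpus, "data")
pt.write_keywords(pt.generator_keyword_set(cfg), "keywords.txt")
```

```bash
pubtriage train --data data --keywords keywords.txt --out model --seed 7
```

prints (abridged):

```json
{
  "counts": {"articles_read": 400, "articles_balanced": 320,
             "paragraphs_kept": 650, "vocabulary_size": 524},
  "n_train": 288, "n_test": 32, "epochs": 30,
  "train": {"accuracy": 0.9965, "loss": 0.1300},
  "test":  {"accuracy": 0.9688, "loss": 0.1386},
  "confusion_matrix": {"tp": 13, "fp": 0, "fn": 1, "tn": 18},
  "version": "m-b0780e0eeee0"
}
```

400 articles balance to 320 (the 160 relevant ones plus 160 sampled
irrelevant), split 288 train / 32 test; the held-out accuracy is 31/32. The
persisted `model/` holds the classifier and its vocabulary, checksummed and
schema-versioned. Classifying one article:

```bash
pubtriage classify --model-dir model --keywords keywords.txt --in article.json
# {"likelihood": 0.2869, "relevant": false, "triage": "negative_low", ...}
```

`triage: negative_low` means the likelihood fell in [0.18, 0.5): probably
irrelevant, but queued for manual review rather than auto-rejected. An
article with no keyword paragraph short-circuits to
`{"reason": "off-topic", "relevant": false}` without touching the model, and
`pubtriage search-keywords` reports which keywords occur in which files.

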