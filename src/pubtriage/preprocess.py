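"""Paragraph selection, token normalization, vocabulary building, one-hot encoding.

Text is normalized in the order: tokenize, drop punctuation and stop words,
lemmatize, lowercase (lowercasing happens first internally since the stop list
and lemma rules are lowercase; the result is the same).  Lemmatization is a
deterministic rule-based English lemmatizer — an exception table for common
irregular forms plus ordered suffix rules for plurals and -ed/-ing verb forms.
It is intentionally lightweight: keywords and article text pass through the
same rules, so keyword matching is consistent even where a rule deviates from
dictionary lemmas.  The stop list is scikit-learn's frozen English stop-word
list.  Both resources are pinned by ``NORMALIZER_ID``, recorded in the
vocabulary artifact, so a saved model is only ever used with the normalization
it was trained under.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .corpus_io import Article, KeywordSet
from .errors import ConfigError

#: Pinned normalization resource: rule set version / stop list (318 words).
NORMALIZER_ID = "pubtriage-rulelemma-1+sklearn-english-stop-318"

DEFAULT_VOCAB_SIZE = 10_000

_TOKEN_RE = re.compile(r"[a-z0-9]+")

# Irregular forms the suffix rules would get wrong.
_LEMMA_EXCEPTIONS = {
    "analyses": "analysis",
    "axes": "axis",
    "hypotheses": "hypothesis",
    "theses": "thesis",
    "mice": "mouse",
    "children": "child",
    "men": "man",
    "women": "woman",
    "feet": "foot",
    "teeth": "tooth",
    "criteria": "criterion",
    "media": "medium",
    "somata": "soma",
    "vertices": "vertex",
    "matrices": "matrix",
    "indices": "index",
    "species": "species",
    "used": "use",
    "using": "use",
    "made": "make",
    "found": "find",
    "shown": "show",
    "taken": "take",
    "given": "give",
    "done": "do",
    "seen": "see",
}

# Stems where a trailing double consonant is genuine (not -ed/-ing doubling).
_DOUBLING_CONSONANTS = "bdgmnprt"


def lemmatize(token: str) -> str:
    """Map a lowercase token to its lemma by exception table + suffix rules."""
    if token in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[token]
    t = token
    # -- plural nouns / third-person verbs --------------------------------
    if t.endswith("sses"):
        return t[:-2]                       # classes -> class
    if t.endswith("yses"):
        return t[:-2] + "is"                # dialyses -> dialysis
    if t.endswith("ies") and len(t) > 4:
        return t[:-3] + "y"                 # studies -> study
    if t.endswith("es") and t[:-2].endswith(("x", "ch", "sh", "z")):
        return t[:-2]                       # branches -> branch
    if t.endswith("s") and not t.endswith(("ss", "us", "is")) and len(t) > 3:
        return t[:-1]                       # dendrites -> dendrite
    # -- -ed / -ing verb forms --------------------------------------------
    for suffix in ("ing", "ed"):
        if t.endswith(suffix) and len(t) - len(suffix) >= 4:
            stem = t[: -len(suffix)]
            if stem[-1] == stem[-2] and stem[-1] in _DOUBLING_CONSONANTS:
                return stem[:-1]            # stopped -> stop
            if stem[-1] in "cgsuvz" and not stem.endswith("ss"):
                return stem + "e"           # tracing -> trace, analyzed -> analyze
            return stem                     # reconstructed -> reconstruct
    return t


def normalize_tokens(text: str) -> list[str]:
    """Tokenize, strip punctuation and stop words, lemmatize, lowercase."""
    tokens = _TOKEN_RE.findall(text.lower())
    return [lemmatize(t) for t in tokens if t not in ENGLISH_STOP_WORDS]


def _contains_subsequence(haystack: Sequence[str], needle: Sequence[str]) -> bool:
    """Contiguous occurrence of ``needle`` within ``haystack``."""
    n, m = len(haystack), len(needle)
    if m == 0 or m > n:
        return False
    first = needle[0]
    needle_t = tuple(needle)
    for i in range(n - m + 1):
        if haystack[i] == first and tuple(haystack[i : i + m]) == needle_t:
            return True
    return False


def keyword_lemma_sequences(keywords: KeywordSet) -> list[tuple[str, list[str]]]:
    """Each keyword with its lemma sequence (phrases stay multi-lemma)."""
    out = []
    for kw in keywords:
        lemmas = normalize_tokens(kw)
        if lemmas:
            out.append((kw, lemmas))
    return out


def keyword_hits(text: str, keywords: KeywordSet) -> list[str]:
    """Keywords whose lemma sequence occurs in the text's lemma sequence.

    Returned in keyword-file order, deduplicated.  Matching is
    case-insensitive and inflection-tolerant: "Sholl analyses" matches the
    keyword "sholl analysis".
    """
    lemmas = normalize_tokens(text)
    return [
        kw
        for kw, kw_lemmas in keyword_lemma_sequences(keywords)
        if _contains_subsequence(lemmas, kw_lemmas)
    ]


def select_relevant_paragraphs(article: Article, keywords: KeywordSet) -> list[str]:
    """Keep, in document order, exactly the paragraphs containing a keyword.

    An empty result marks the article as off-topic: it never reaches the
    classifier and is triaged irrelevant directly.
    """
    kw_lemma = keyword_lemma_sequences(keywords)
    selected = []
    for paragraph in article.paragraphs:
        lemmas = normalize_tokens(paragraph)
        if any(_contains_subsequence(lemmas, kl) for _, kl in kw_lemma):
            selected.append(paragraph)
    return selected


@dataclass
class Vocabulary:
    """Ordered lemma -> index map; defines the one-hot encoding dimension."""

    terms: list[str]
    max_size: int = DEFAULT_VOCAB_SIZE
    normalizer_id: str = NORMALIZER_ID
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.terms) > self.max_size:
            raise ConfigError(
                f"vocabulary has {len(self.terms)} terms, exceeds cap {self.max_size}"
            )
        self.index = {t: i for i, t in enumerate(self.terms)}
        if len(self.index) != len(self.terms):
            raise ConfigError("vocabulary terms are not unique")

    def __len__(self) -> int:
        return len(self.terms)

    def to_payload(self) -> dict:
        return {
            "terms": list(self.terms),
            "max_size": self.max_size,
            "normalizer_id": self.normalizer_id,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "Vocabulary":
        return cls(
            terms=list(payload["terms"]),
            max_size=int(payload["max_size"]),
            normalizer_id=str(payload["normalizer_id"]),
        )


def build_vocabulary(
    token_lists: Iterable[Sequence[str]], max_size: int = DEFAULT_VOCAB_SIZE
) -> Vocabulary:
    """The ``max_size`` most frequent lemmas by total occurrence count.

    Frequency is total token occurrences over the training split's selected
    paragraphs (not document frequency).  Ties at the cutoff break
    lexicographically, so the vocabulary is deterministic and invariant to
    article order.
    """
    if max_size < 1:
        raise ConfigError(f"max_size must be >= 1, got {max_size}")
    counts: Counter[str] = Counter()
    for tokens in token_lists:
        counts.update(tokens)
    if not counts:
        raise ConfigError("cannot build a vocabulary from an empty corpus")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return Vocabulary(terms=[t for t, _ in ranked[:max_size]], max_size=max_size)


def encode_one_hot(lemmas: Sequence[str], vocab: Vocabulary) -> np.ndarray:
    """Presence vector: bit i = 1 iff vocabulary term i occurs in ``lemmas``.

    Out-of-vocabulary lemmas are ignored; multiplicity is ignored.
    """
    x = np.zeros(len(vocab), dtype=np.float64)
    index = vocab.index
    for lemma in lemmas:
        i = index.get(lemma)
        if i is not None:
            x[i] = 1.0
    return x


def encode_article(article_paragraphs: Sequence[str], vocab: Vocabulary) -> np.ndarray:
    """One-hot encode the concatenated lemmas of already-selected paragraphs."""
    lemmas: list[str] = []
    for p in article_paragraphs:
        lemmas.extend(normalize_tokens(p))
    return encode_one_hot(lemmas, vocab)
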