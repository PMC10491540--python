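"""Class balancing and train/validation/test partitioning.

Balancing uses random under-sampling: majority-class articles are discarded
uniformly at random until both classes match the minority count.  Splitting
holds out a test fraction (default 10%) and partitions the remainder into k
folds (default 10) for cross-validation.  Both steps are seeded and happen
before any text leaves the articles, so the vocabulary can be built from the
training side only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import Corpus
from .errors import ConfigError, CorpusError


@dataclass
class SplitPlan:
    """Disjoint test / train-validation ids plus k folds over the latter.

    Invariants: ``test_ids`` and ``trainval_ids`` are disjoint and cover all
    ids; folds are pairwise disjoint, cover ``trainval_ids``, and their sizes
    differ by at most one.
    """

    test_ids: list[str]
    trainval_ids: list[str]
    folds: list[list[str]]
    seed: int


def undersample_balance(corpus: Corpus, seed: int) -> Corpus:
    """Discard random majority-class articles to match the minority count.

    The minority class is untouched; removal is uniform at random and
    reproducible from ``seed``.  Original article order is preserved among
    the retained articles.
    """
    counts = corpus.class_counts
    if any(c == 0 for c in counts.values()):
        empty = [label for label, c in counts.items() if c == 0]
        raise CorpusError(f"cannot balance: class(es) with zero articles: {empty}")
    minority = min(counts.values())
    rng = np.random.default_rng(seed)
    keep_ids: set[str] = set()
    for label, count in sorted(counts.items()):
        ids = [a.id for a in corpus.articles if a.label == label]
        if count > minority:
            ids = list(rng.choice(np.array(ids, dtype=object), size=minority, replace=False))
        keep_ids.update(ids)
    return Corpus([a for a in corpus.articles if a.id in keep_ids])


def make_split_plan(
    corpus: Corpus, test_frac: float = 0.10, k: int = 10, seed: int = 0
) -> SplitPlan:
    """Randomly hold out ``round(test_frac * n)`` articles; k-fold the rest.

    Rounding of the test size is to nearest, ties to even.  Splits are not
    stratified by class (after balancing, stratification is nearly moot);
    randomization is fully seeded.
    """
    if not 0.0 < test_frac < 1.0:
        raise ConfigError(f"test_frac must be in (0, 1), got {test_frac}")
    if k < 2:
        raise ConfigError(f"fold count must be >= 2, got {k}")
    ids = [a.id for a in corpus.articles]
    n = len(ids)
    if n < k + 1:
        raise ConfigError(f"need at least k+1={k + 1} articles, got {n}")
    n_test = int(round(test_frac * n))
    if n_test < 1 or n - n_test < k:
        raise ConfigError(f"test_frac {test_frac} leaves an unusable split for n={n}, k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    test_ids = shuffled[:n_test]
    trainval_ids = shuffled[n_test:]
    folds = [list(fold) for fold in np.array_split(np.array(trainval_ids, dtype=object), k)]
    return SplitPlan(test_ids=test_ids, trainval_ids=trainval_ids, folds=folds, seed=seed)
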