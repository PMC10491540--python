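"""Four-way triage bands and the labor-saved vs. misclassification calibration.

A likelihood p is mapped to one of four decisions by three cut points
(defaults t_low = 0.18, mid = 0.5, t_high = 0.98):

    p < t_low          -> negative_high   (auto-reject)
    t_low <= p < mid   -> negative_low    (manual review)
    mid <= p < t_high  -> positive_low    (manual review)
    p >= t_high        -> positive_high   (auto-accept)

Bands are half-open, closed on the upper comparison, so every p in [0, 1]
gets exactly one label.  The calibration curves sweep candidate thresholds
over the observed score values and report, per true class, the fraction of
articles decided automatically (labor saved) against the fraction of those
automatic decisions that contradict the gold label.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .corpus_io import IRRELEVANT, RELEVANT
from .errors import ConfigError


class TriageLabel(str, Enum):
    NEGATIVE_HIGH = "negative_high"
    NEGATIVE_LOW = "negative_low"
    POSITIVE_LOW = "positive_low"
    POSITIVE_HIGH = "positive_high"


@dataclass
class ThresholdConfig:
    t_low: float = 0.18
    mid: float = 0.5
    t_high: float = 0.98

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_low <= self.mid <= self.t_high <= 1.0:
            raise ConfigError(
                f"thresholds must satisfy 0 <= t_low <= mid <= t_high <= 1, "
                f"got ({self.t_low}, {self.mid}, {self.t_high})"
            )


def assign_label(likelihood: float, cfg: ThresholdConfig | None = None) -> TriageLabel:
    """Band a relevance likelihood into one of the four triage decisions."""
    cfg = cfg or ThresholdConfig()
    if not 0.0 <= likelihood <= 1.0:
        raise ConfigError(f"likelihood must be in [0, 1], got {likelihood}")
    if likelihood < cfg.t_low:
        return TriageLabel.NEGATIVE_HIGH
    if likelihood < cfg.mid:
        return TriageLabel.NEGATIVE_LOW
    if likelihood < cfg.t_high:
        return TriageLabel.POSITIVE_LOW
    return TriageLabel.POSITIVE_HIGH


@dataclass
class CurvePoint:
    """One candidate threshold on one side of the calibration sweep.

    ``labor_saved`` is the fraction of that side's true class decided
    automatically at this threshold; ``error`` is the fraction of the
    auto-decided set whose gold label disagrees with the automatic decision.
    """

    threshold: float
    labor_saved: float
    error: float


def _validate_scores(scores: Sequence[tuple[float, str]]) -> None:
    if not scores:
        raise ConfigError("calibration needs a non-empty gold-labeled score set")
    for p, label in scores:
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"score {p} outside [0, 1]")
        if label not in (RELEVANT, IRRELEVANT):
            raise ConfigError(f"unknown gold label: {label}")


def labor_error_curves(
    scores: Sequence[tuple[float, str]]
) -> tuple[list[CurvePoint], list[CurvePoint]]:
    """Sweep thresholds over the observed scores plus {0, 1}; no binning.

    Negative side: auto-set = {p < t}; labor saved is measured against the
    irrelevant-class count, the error against the auto-set (gold relevant =
    false irrelevant).  Positive side symmetrically with {p >= t} and gold
    irrelevant = false relevant.
    """
    _validate_scores(scores)
    n_irr = sum(1 for _, label in scores if label == IRRELEVANT)
    n_rel = sum(1 for _, label in scores if label == RELEVANT)
    if n_irr == 0 or n_rel == 0:
        raise ConfigError("calibration needs gold labels from both classes")
    thresholds = sorted({p for p, _ in scores} | {0.0, 1.0})
    negative, positive = [], []
    for t in thresholds:
        auto_neg = [(p, label) for p, label in scores if p < t]
        wrong_neg = sum(1 for _, label in auto_neg if label == RELEVANT)
        negative.append(
            CurvePoint(
                threshold=t,
                labor_saved=sum(1 for _, la in auto_neg if la == IRRELEVANT) / n_irr,
                error=wrong_neg / len(auto_neg) if auto_neg else 0.0,
            )
        )
        auto_pos = [(p, label) for p, label in scores if p >= t]
        wrong_pos = sum(1 for _, label in auto_pos if label == IRRELEVANT)
        positive.append(
            CurvePoint(
                threshold=t,
                labor_saved=sum(1 for _, la in auto_pos if la == RELEVANT) / n_rel,
                error=wrong_pos / len(auto_pos) if auto_pos else 0.0,
            )
        )
    return negative, positive


@dataclass
class BandFractions:
    """Per-true-class band statistics feeding the per-100 review arithmetic.

    ``review_irrelevant`` / ``review_relevant``: fraction of each true class
    whose likelihood lands in the manual-review band [t_low, t_high).
    ``auto_error_negative`` / ``auto_error_positive``: misclassified articles
    on each automatic side, expressed against the same per-class basis
    (irrelevant count on the negative side, relevant count on the positive),
    so that the per-100 expectations below are exact.
    """

    review_irrelevant: float
    review_relevant: float
    auto_error_negative: float = 0.0
    auto_error_positive: float = 0.0

    def __post_init__(self) -> None:
        for name in ("review_irrelevant", "review_relevant",
                     "auto_error_negative", "auto_error_positive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a fraction in [0, 1], got {v}")


def band_fractions_from_scores(
    scores: Sequence[tuple[float, str]], cfg: ThresholdConfig | None = None
) -> BandFractions:
    """Measure the band fractions of a gold-labeled score set."""
    cfg = cfg or ThresholdConfig()
    _validate_scores(scores)
    n_irr = sum(1 for _, label in scores if label == IRRELEVANT)
    n_rel = sum(1 for _, label in scores if label == RELEVANT)
    if n_irr == 0 or n_rel == 0:
        raise ConfigError("band fractions need gold labels from both classes")
    review_irr = sum(
        1 for p, la in scores if la == IRRELEVANT and cfg.t_low <= p < cfg.t_high
    )
    review_rel = sum(
        1 for p, la in scores if la == RELEVANT and cfg.t_low <= p < cfg.t_high
    )
    err_neg = sum(1 for p, la in scores if la == RELEVANT and p < cfg.t_low)
    err_pos = sum(1 for p, la in scores if la == IRRELEVANT and p >= cfg.t_high)
    return BandFractions(
        review_irrelevant=review_irr / n_irr,
        review_relevant=review_rel / n_rel,
        auto_error_negative=err_neg / n_irr,
        auto_error_positive=err_pos / n_rel,
    )


def review_load_summary(bands: BandFractions, prevalence: float) -> dict[str, int]:
    """Expected per-100-articles workload at a given relevance prevalence.

    Each review count is rounded to the nearest integer per term; the
    expected number of misclassified articles among the automatic decisions
    is rounded once on the sum.
    """
    if not 0.0 < prevalence < 1.0:
        raise ConfigError(f"prevalence must be in (0, 1), got {prevalence}")
    n_irr = 100.0 * (1.0 - prevalence)
    n_rel = 100.0 * prevalence
    review_irrelevant = round(n_irr * bands.review_irrelevant)
    review_relevant = round(n_rel * bands.review_relevant)
    return {
        "auto_reject": round(n_irr * (1.0 - bands.review_irrelevant)),
        "auto_accept": round(n_rel * (1.0 - bands.review_relevant)),
        "review_irrelevant": review_irrelevant,
        "review_relevant": review_relevant,
        "review_total": review_irrelevant + review_relevant,
        "expected_misclassified": round(
            n_irr * bands.auto_error_negative + n_rel * bands.auto_error_positive
        ),
    }
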