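"""Mapping observed counts to amplification categories.

Scoring guidelines bin the per-nucleus (or slide-mean) target count into
negative / equivocal / positive: counts of 6 or more are positive,
counts in [4, 6) equivocal, below 4 negative; when a control probe is
scored, a target/control ratio ≥ 2.0 is also positive.  Because thin
sections thin the observed counts, a truly amplified specimen can fall
into a lower category — this module quantifies that misclassification
probability as a function of true copy number and section thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .geometry import SectionSpec
from .observation import CountsPMF, pmf_for_spec

__all__ = [
    "CategoryRule",
    "CategoryProbabilities",
    "category_probabilities",
    "probability_grid",
    "classify_observed",
    "SHADE_LABELS",
]

#: Shading bins for the misclassification grid, from confidently negative
#: to confidently positive.
SHADE_LABELS = ("blue", "green", "yellow", "orange", "pink")


@dataclass(frozen=True)
class CategoryRule:
    """Count thresholds of the scoring guideline.

    ``positive`` when count ≥ ``positive_low`` (or ratio ≥ ``ratio_positive``
    where a ratio is available); ``equivocal`` when
    ``equivocal_low ≤ count < positive_low``; ``negative`` otherwise.
    Thresholds are inclusive on the left.
    """

    equivocal_low: float = 4.0
    positive_low: float = 6.0
    ratio_positive: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.equivocal_low < self.positive_low:
            raise ValueError("need 0 < equivocal_low < positive_low")


@dataclass(frozen=True)
class CategoryProbabilities:
    """Probability of each category for one (true copy number, section) cell."""

    p_negative: float
    p_equivocal: float
    p_positive: float

    @property
    def shade(self) -> str:
        """Five-bin confidence shading used in the misclassification grid."""
        if self.p_negative >= 0.9:
            return "blue"
        if self.p_negative >= 0.5:
            return "green"
        if self.p_positive >= 0.9:
            return "pink"
        if self.p_positive >= 0.5:
            return "orange"
        return "yellow"


def category_probabilities(
    n_true: int, spec: SectionSpec, rule: CategoryRule | None = None
) -> CategoryProbabilities:
    """Category probabilities from the single-nucleus binomial count.

    Counts are integers, so with the default rule the positive event is
    ``n ≥ 6`` and the equivocal event is ``n ∈ {4, 5}``.
    """
    rule = rule or CategoryRule()
    pmf = pmf_for_spec(n_true, spec)
    return _categorise_pmf(pmf, rule)


def _categorise_pmf(pmf: CountsPMF, rule: CategoryRule) -> CategoryProbabilities:
    p_pos = pmf.prob_at_least(rule.positive_low)
    p_eqv = pmf.prob_between(rule.equivocal_low, rule.positive_low)
    return CategoryProbabilities(
        p_negative=max(1.0 - p_pos - p_eqv, 0.0), p_equivocal=p_eqv, p_positive=p_pos
    )


def probability_grid(
    n_range,
    t_range,
    d: float = 3.0,
    c: float = 0.8,
    rule: CategoryRule | None = None,
) -> pd.DataFrame:
    """Misclassification grid over true copy number × section thickness.

    Returns one row per (N, t) cell with columns ``n_true``,
    ``thickness_um``, ``p_negative``, ``p_equivocal``, ``p_positive`` and
    the confidence ``shade`` label.
    """
    n_range = list(n_range)
    t_range = list(t_range)
    if not n_range or not t_range:
        raise ValueError("n_range and t_range must be non-empty")
    rule = rule or CategoryRule()
    rows = []
    for n in n_range:
        for t in t_range:
            cat = category_probabilities(n, SectionSpec(t=t, d=d, c=c), rule)
            rows.append(
                {
                    "n_true": n,
                    "thickness_um": t,
                    "p_negative": cat.p_negative,
                    "p_equivocal": cat.p_equivocal,
                    "p_positive": cat.p_positive,
                    "shade": cat.shade,
                }
            )
    return pd.DataFrame(rows)


def classify_observed(
    mean_count: float, ratio: float | None = None, rule: CategoryRule | None = None
) -> str:
    """Deterministic guideline label for a slide-level mean count.

    Positive when the target/control ratio (if supplied) is ≥ 2.0 or the
    mean count is ≥ 6; equivocal for mean counts in [4, 6); else negative.
    """
    rule = rule or CategoryRule()
    if mean_count < 0:
        raise ValueError("mean count must be non-negative")
    if ratio is not None and ratio < 0:
        raise ValueError("ratio must be non-negative")
    if (ratio is not None and ratio >= rule.ratio_positive) or mean_count >= rule.positive_low:
        return "positive"
    if mean_count >= rule.equivocal_low:
        return "equivocal"
    return "negative"
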