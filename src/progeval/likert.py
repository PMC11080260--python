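"""Likert-scale satisfaction classification via the demarcation threshold.

Caregiver acceptability is measured with a battery of five-point Likert items
(1 = strongly disagree ... 5 = strongly agree).  A respondent's total score is
compared against the *demarcation threshold*, the midpoint of the attainable
total-score range:

    cutoff = (n*max - n*min) / 2 + n*min

For 14 items on a 1-5 scale the cutoff is 42; totals strictly above the cutoff
classify the respondent as "satisfied", anything at or below it as
"dissatisfied" (a total exactly at the midpoint expresses no net agreement).

Item-level summaries use the top-two-box convention: a respondent counts as
satisfied with an item when the response is at or above ``agree_threshold``
(default 4 = agree).  These per-item counts, with the number of respondents as
denominator, are exactly the O/E pairs of the acceptability dimension's
indicators, so :func:`item_satisfaction_counts` feeds the scoring matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, InvalidRecordError
from .matrix import Indicator

__all__ = [
    "LikertScaleSpec",
    "RespondentRecord",
    "SatisfactionSummary",
    "SATISFIED",
    "DISSATISFIED",
    "demarcation_cutoff",
    "classify_total",
    "classify_respondent",
    "classify_totals",
    "item_satisfaction_counts",
]

SATISFIED = "satisfied"
DISSATISFIED = "dissatisfied"


@dataclass(frozen=True)
class LikertScaleSpec:
    """Shape of the Likert instrument: item count and per-item bounds."""

    n_items: int = 14
    item_min: int = 1
    item_max: int = 5

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise InvalidConfigError(f"n_items must be >= 1, got {self.n_items}")
        if not self.item_min < self.item_max:
            raise InvalidConfigError(
                f"item_min ({self.item_min}) must be below item_max ({self.item_max})"
            )

    @property
    def min_total(self) -> int:
        return self.n_items * self.item_min

    @property
    def max_total(self) -> int:
        return self.n_items * self.item_max

    @property
    def cutoff(self) -> float:
        return demarcation_cutoff(self)


@dataclass(frozen=True)
class RespondentRecord:
    """One caregiver: covariates plus the ordered Likert item responses."""

    id: str
    covariates: dict = field(default_factory=dict)
    item_responses: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_responses", tuple(self.item_responses))

    @property
    def total(self) -> int:
        return int(sum(self.item_responses))


@dataclass(frozen=True)
class SatisfactionSummary:
    """Aggregate classification results for a respondent set."""

    cutoff: float
    n_satisfied: int
    n_dissatisfied: int
    item_counts: tuple[int, ...]
    agree_threshold: int

    @property
    def n(self) -> int:
        return self.n_satisfied + self.n_dissatisfied

    @property
    def satisfied_proportion(self) -> float:
        return self.n_satisfied / self.n if self.n else float("nan")

    @property
    def item_percents(self) -> tuple[float, ...]:
        if self.n == 0:
            return tuple(float("nan") for _ in self.item_counts)
        return tuple(100.0 * c / self.n for c in self.item_counts)

    def to_indicators(
        self,
        weights: Sequence[float],
        dimension_id: str = "acceptability",
        labels: Sequence[str] | None = None,
    ) -> list[Indicator]:
        """Turn per-item satisfied counts into acceptability indicators.

        E is the number of respondents, O the count at/above the agree
        threshold, W the supplied stakeholder weight per item.
        """
        if len(weights) != len(self.item_counts):
            raise InvalidConfigError(
                f"got {len(weights)} weights for {len(self.item_counts)} items"
            )
        labels = list(labels) if labels is not None else [
            f"item {i + 1}" for i in range(len(self.item_counts))
        ]
        return [
            Indicator(
                id=f"{dimension_id}_{i + 1:02d}",
                label=labels[i],
                dimension_id=dimension_id,
                expected=self.n,
                observed=count,
                weight=float(weights[i]),
            )
            for i, count in enumerate(self.item_counts)
        ]


def demarcation_cutoff(scale: LikertScaleSpec) -> float:
    """Midpoint of the attainable total-score range.

    ``(total highest - total lowest) / 2 + total lowest``; for 14 five-point
    items this is (70 - 14)/2 + 14 = 42.
    """
    return (scale.max_total - scale.min_total) / 2.0 + scale.min_total


def classify_total(total: float, scale: LikertScaleSpec) -> str:
    """Satisfied iff the total is strictly above the demarcation cutoff."""
    return SATISFIED if total > demarcation_cutoff(scale) else DISSATISFIED


def classify_respondent(rec: RespondentRecord, scale: LikertScaleSpec) -> str:
    """Classify one respondent, validating the response vector first."""
    responses = rec.item_responses
    if len(responses) != scale.n_items:
        raise InvalidRecordError(
            f"respondent {rec.id!r}: got {len(responses)} responses, "
            f"expected {scale.n_items}"
        )
    for r in responses:
        if not (scale.item_min <= r <= scale.item_max):
            raise InvalidRecordError(
                f"respondent {rec.id!r}: response {r} outside "
                f"[{scale.item_min}, {scale.item_max}]"
            )
    return classify_total(sum(responses), scale)


def classify_totals(totals: Sequence[float] | np.ndarray, scale: LikertScaleSpec) -> np.ndarray:
    """Vectorized classification; returns a boolean array (True = satisfied)."""
    return np.asarray(totals) > demarcation_cutoff(scale)


def _responses_matrix(
    records: Iterable[RespondentRecord] | pd.DataFrame, scale: LikertScaleSpec
) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        cols = [f"q{i + 1}" for i in range(scale.n_items)]
        missing = [c for c in cols if c not in records.columns]
        if missing:
            raise InvalidRecordError(f"missing item columns: {missing}")
        mat = records[cols].to_numpy(dtype=float)
    else:
        rows = []
        for rec in records:
            if len(rec.item_responses) != scale.n_items:
                raise InvalidRecordError(
                    f"respondent {rec.id!r}: got {len(rec.item_responses)} "
                    f"responses, expected {scale.n_items}"
                )
            rows.append(rec.item_responses)
        mat = np.asarray(rows, dtype=float).reshape(len(rows), scale.n_items)
    if mat.size and (
        np.isnan(mat).any() or (mat < scale.item_min).any() or (mat > scale.item_max).any()
    ):
        raise InvalidRecordError(
            f"item responses outside [{scale.item_min}, {scale.item_max}] or missing"
        )
    return mat


def item_satisfaction_counts(
    records: Iterable[RespondentRecord] | pd.DataFrame,
    scale: LikertScaleSpec,
    agree_threshold: int = 4,
) -> SatisfactionSummary:
    """Classify every respondent and count per-item top-box agreement.

    Parameters
    ----------
    records
        Either an iterable of :class:`RespondentRecord` or a DataFrame with
        item columns ``q1..qN``.
    scale
        The Likert instrument shape.
    agree_threshold
        Minimum response counting as satisfied with an item; must lie within
        the scale bounds.
    """
    if not (scale.item_min <= agree_threshold <= scale.item_max):
        raise InvalidConfigError(
            f"agree_threshold {agree_threshold} outside scale bounds "
            f"[{scale.item_min}, {scale.item_max}]"
        )
    mat = _responses_matrix(records, scale)
    totals = mat.sum(axis=1)
    satisfied = classify_totals(totals, scale)
    item_counts = (mat >= agree_threshold).sum(axis=0) if mat.size else np.zeros(
        scale.n_items, dtype=int
    )
    return SatisfactionSummary(
        cutoff=demarcation_cutoff(scale),
        n_satisfied=int(satisfied.sum()),
        n_dissatisfied=int((~satisfied).sum()),
        item_counts=tuple(int(c) for c in item_counts),
        agree_threshold=agree_threshold,
    )
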