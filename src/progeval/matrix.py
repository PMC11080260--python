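"""Weighted-indicator scoring and judgment-matrix aggregation.

The measurement model is the one used in participatory implementation
evaluations of community health programs: every checklist *indicator* has an
expected denominator ``E`` (how many units should show the feature), an
observed numerator ``O`` (how many did), and a stakeholder-assigned weight
``W`` expressed in points.  The indicator *score* is

    S = O * W / E        (points attained, between 0 and W)

and the indicator *achievement* is the percentage of its weight attained,

    A = 100 * S / W  =  100 * O / E.

Indicators are grouped into themed *dimensions* (availability of resources,
provider compliance with the clinical guideline, user acceptability).  A
dimension's achievement is the pooled ratio ``100 * sum(S) / sum(W)`` over its
indicators, and the overall program implementation is the weighted mean of
the dimension achievements using the nominal dimension weights agreed with
stakeholders (e.g. 35 / 40 / 25 points).  Every achievement percentage is
mapped to a verbal judgment by a band scale (the "judgment matrix"):
by default poor [0, 60), fair [60, 75), good [75, 85), very good [85, 100].

:class:`EvaluationMatrix` bundles dimensions, dimension weights and the
judgment scale; :meth:`EvaluationMatrix.evaluate` produces an
:class:`EvaluationReport` with per-indicator, per-dimension and overall rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import (
    InvalidConfigError,
    InvalidDimensionError,
    InvalidIndicatorError,
)

__all__ = [
    "Indicator",
    "DimensionSpec",
    "JudgmentScale",
    "DEFAULT_JUDGMENT_SCALE",
    "EvaluationMatrix",
    "EvaluationReport",
    "indicator_score",
    "indicator_achievement",
    "dimension_achievement",
    "overall_implementation",
    "judge",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (presentation rounding, not banker's)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Indicator:
    """One evaluation checklist item.

    Parameters
    ----------
    id : str
        Short unique identifier.
    label : str
        Free-text description of what the indicator measures.
    dimension_id : str
        The dimension this indicator belongs to.
    expected : float
        Denominator E: number of units that should exhibit the feature. > 0.
    observed : float
        Numerator O: number of units that did. 0 <= O <= E.
    weight : float
        Stakeholder-assigned weight W in points. > 0.
    score_override : float, optional
        If given, used as the indicator score S instead of O*W/E.  This exists
        for published summary tables whose printed score column is the
        authoritative record even where the printed counts disagree with it.
    """

    id: str
    label: str
    dimension_id: str
    expected: float
    observed: float
    weight: float
    score_override: float | None = None

    def __post_init__(self) -> None:
        if not self.expected > 0:
            raise InvalidIndicatorError(
                f"indicator {self.id!r}: expected count must be > 0, got {self.expected}"
            )
        if self.observed < 0:
            raise InvalidIndicatorError(
                f"indicator {self.id!r}: observed count must be >= 0, got {self.observed}"
            )
        if self.observed > self.expected:
            raise InvalidIndicatorError(
                f"indicator {self.id!r}: observed ({self.observed}) exceeds expected ({self.expected})"
            )
        if not self.weight > 0:
            raise InvalidIndicatorError(
                f"indicator {self.id!r}: weight must be > 0, got {self.weight}"
            )
        if self.score_override is not None and not (
            0 <= self.score_override <= self.weight
        ):
            raise InvalidIndicatorError(
                f"indicator {self.id!r}: score override {self.score_override} "
                f"outside [0, weight={self.weight}]"
            )

    @property
    def score(self) -> float:
        return indicator_score(self)

    @property
    def achievement(self) -> float:
        return indicator_achievement(self)


@dataclass(frozen=True)
class DimensionSpec:
    """A themed group of indicators with its overall-aggregation weight."""

    id: str
    name: str
    weight: float
    indicators: tuple[Indicator, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "indicators", tuple(self.indicators))
        if len(self.indicators) == 0:
            raise InvalidDimensionError(f"dimension {self.id!r} has no indicators")
        if not self.weight > 0:
            raise InvalidDimensionError(
                f"dimension {self.id!r}: weight must be > 0, got {self.weight}"
            )

    @property
    def achievement(self) -> float:
        return dimension_achievement(self)


@dataclass(frozen=True)
class JudgmentScale:
    """Ordered bands mapping achievement percentages to verbal labels.

    Bands are lower-inclusive half-open intervals ``[low, high)`` that must
    partition [0, 100] with no gaps or overlaps; the top band additionally
    includes its upper bound so that 100% is classified.
    """

    bands: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        bands = tuple((float(lo), float(hi), str(label)) for lo, hi, label in self.bands)
        object.__setattr__(self, "bands", bands)
        if not bands:
            raise InvalidConfigError("judgment scale needs at least one band")
        if bands[0][0] != 0.0 or bands[-1][1] != 100.0:
            raise InvalidConfigError("judgment bands must start at 0 and end at 100")
        for (lo, hi, label) in bands:
            if not lo < hi:
                raise InvalidConfigError(
                    f"judgment band {label!r}: lower bound {lo} not below upper {hi}"
                )
        for (_, hi, _), (lo2, _, _) in zip(bands, bands[1:]):
            if hi != lo2:
                raise InvalidConfigError(
                    f"judgment bands leave a gap or overlap between {hi} and {lo2}"
                )

    def classify(self, achievement: float) -> str:
        if not (0.0 <= achievement <= 100.0) or math.isnan(achievement):
            raise InvalidConfigError(
                f"achievement {achievement} outside [0, 100]; cannot be judged"
            )
        for lo, hi, label in self.bands[:-1]:
            if lo <= achievement < hi:
                return label
        return self.bands[-1][2]  # top band closed at 100

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, _, label in self.bands)


#: The four-band scale agreed during evaluability assessment:
#: poor below 60%, fair to 75%, good to 85%, very good to 100%.
DEFAULT_JUDGMENT_SCALE = JudgmentScale(
    bands=(
        (0.0, 60.0, "poor"),
        (60.0, 75.0, "fair"),
        (75.0, 85.0, "good"),
        (85.0, 100.0, "very good"),
    )
)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def indicator_score(ind: Indicator) -> float:
    """Points attained by an indicator: S = O * W / E (or its override)."""
    if ind.score_override is not None:
        return float(ind.score_override)
    return ind.observed * ind.weight / ind.expected


def indicator_achievement(ind: Indicator) -> float:
    """Percent of the indicator's weight attained: A = 100 * S / W."""
    return 100.0 * indicator_score(ind) / ind.weight


def dimension_achievement(dim: DimensionSpec | Iterable[Indicator]) -> float:
    """Pooled achievement of a dimension: 100 * sum(S) / sum(W).

    The denominator is the sum of the indicator weights actually present,
    not the dimension's nominal aggregation weight; the two can differ when
    elicited indicator weights do not add up exactly to the nominal total.
    """
    indicators = dim.indicators if isinstance(dim, DimensionSpec) else tuple(dim)
    if not indicators:
        raise InvalidDimensionError("cannot score a dimension with no indicators")
    total_w = sum(ind.weight for ind in indicators)
    total_s = sum(indicator_score(ind) for ind in indicators)
    return 100.0 * total_s / total_w


def overall_implementation(
    achievements: Sequence[float], weights: Sequence[float]
) -> float:
    """Weighted mean of dimension achievements using nominal dimension weights."""
    if len(achievements) == 0 or len(achievements) != len(weights):
        raise InvalidConfigError(
            "need equal, non-empty achievement and weight sequences"
        )
    if any(not w > 0 for w in weights):
        raise InvalidConfigError("dimension weights must all be positive")
    return float(
        sum(a * w for a, w in zip(achievements, weights)) / sum(weights)
    )


def judge(achievement: float, scale: JudgmentScale = DEFAULT_JUDGMENT_SCALE) -> str:
    """Verbal judgment for an achievement percentage on the given band scale."""
    return scale.classify(achievement)


# ---------------------------------------------------------------------------
# the matrix / report pair
# ---------------------------------------------------------------------------


@dataclass
class EvaluationMatrix:
    """Dimensions + weights + judgment scale; ``evaluate()`` yields the report.

    This is the package's model object for the scoring stage, mirroring the
    Model/Results split: the matrix holds the evaluation design (which
    indicators, which weights, which bands), :class:`EvaluationReport` holds
    the computed scores and judgments.
    """

    dimensions: list[DimensionSpec]
    scale: JudgmentScale = field(default_factory=lambda: DEFAULT_JUDGMENT_SCALE)
    precision: int = 1

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise InvalidConfigError("evaluation matrix needs at least one dimension")
        seen: set[str] = set()
        for dim in self.dimensions:
            for ind in dim.indicators:
                if ind.id in seen:
                    raise InvalidConfigError(f"duplicate indicator id {ind.id!r}")
                seen.add(ind.id)

    @classmethod
    def from_indicators(
        cls,
        indicators: Iterable[Indicator],
        dimension_weights: dict[str, float],
        scale: JudgmentScale = DEFAULT_JUDGMENT_SCALE,
        precision: int = 1,
    ) -> "EvaluationMatrix":
        """Group loose indicators by ``dimension_id`` and attach nominal weights."""
        by_dim: dict[str, list[Indicator]] = {}
        for ind in indicators:
            by_dim.setdefault(ind.dimension_id, []).append(ind)
        missing = set(by_dim) - set(dimension_weights)
        if missing:
            raise InvalidConfigError(
                f"no nominal weight configured for dimension(s): {sorted(missing)}"
            )
        dims = [
            DimensionSpec(id=d, name=d, weight=float(dimension_weights[d]),
                          indicators=tuple(inds))
            for d, inds in by_dim.items()
        ]
        return cls(dimensions=dims, scale=scale, precision=precision)

    def evaluate(self) -> "EvaluationReport":
        ind_rows = []
        dim_rows = []
        for dim in self.dimensions:
            for ind in dim.indicators:
                s = indicator_score(ind)
                a = indicator_achievement(ind)
                ind_rows.append(
                    {
                        "id": ind.id,
                        "label": ind.label,
                        "dimension": dim.id,
                        "expected": ind.expected,
                        "observed": ind.observed,
                        "weight": ind.weight,
                        "score": s,
                        "achievement": a,
                        "judgment": self.scale.classify(a),
                    }
                )
            a_d = dimension_achievement(dim)
            dim_rows.append(
                {
                    "dimension": dim.id,
                    "n_indicators": len(dim.indicators),
                    "weight_sum": sum(i.weight for i in dim.indicators),
                    "score_sum": sum(indicator_score(i) for i in dim.indicators),
                    "nominal_weight": dim.weight,
                    "achievement": a_d,
                    "judgment": self.scale.classify(a_d),
                }
            )
        overall = overall_implementation(
            [r["achievement"] for r in dim_rows],
            [r["nominal_weight"] for r in dim_rows],
        )
        return EvaluationReport(
            indicator_table=pd.DataFrame(ind_rows),
            dimension_table=pd.DataFrame(dim_rows),
            overall_achievement=overall,
            overall_judgment=self.scale.classify(overall),
            precision=self.precision,
        )


@dataclass
class EvaluationReport:
    """Computed scores, achievements and judgments for a whole evaluation."""

    indicator_table: pd.DataFrame
    dimension_table: pd.DataFrame
    overall_achievement: float
    overall_judgment: str
    precision: int = 1

    def summary(self) -> str:
        """Plain-text report mirroring the E/O/W/S/A checklist-table layout."""
        p = self.precision
        ind = self.indicator_table.copy()
        ind["score"] = ind["score"].map(lambda v: round_half_up(v, 2))
        ind["achievement"] = ind["achievement"].map(lambda v: round_half_up(v, p))
        dim = self.dimension_table.copy()
        for col in ("weight_sum", "score_sum"):
            dim[col] = dim[col].map(lambda v: round_half_up(v, 2))
        dim["achievement"] = dim["achievement"].map(lambda v: round_half_up(v, p))
        lines = [
            "Indicator scores",
            "----------------",
            ind.to_string(index=False),
            "",
            "Dimension achievements",
            "----------------------",
            dim.to_string(index=False),
            "",
            f"Overall implementation: {round_half_up(self.overall_achievement, p)}%"
            f" ({self.overall_judgment})",
        ]
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary()
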