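"""Model/Results front-end for the acceptability association analysis.

:class:`AcceptabilityModel` is built from respondent-level data (a DataFrame
with one row per caregiver) and a list of candidate covariates.  ``fit()``
runs the full published procedure — crude odds ratios per covariate level,
univariable screening at p < 0.25, multivariable logistic regression on the
retained covariates — and returns an :class:`AcceptabilityResults` whose
``summary_frame()`` mirrors the familiar COR/AOR reporting table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .association import (
    AssociationResult,
    LogisticModelFit,
    categorical_crude_ors,
    fit_logistic,
    screen_bivariable,
)
from .exceptions import InvalidConfigError
from .likert import (
    DISSATISFIED,
    SATISFIED,
    LikertScaleSpec,
    classify_totals,
)

__all__ = ["AcceptabilityModel", "AcceptabilityResults"]


class AcceptabilityModel:
    """Association analysis of a binary satisfaction outcome.

    Parameters
    ----------
    data
        One row per respondent; must contain the outcome column and every
        candidate covariate.
    outcome
        Name of the binary outcome column (bool, 0/1, "satisfied"/
        "dissatisfied" or "yes"/"no").
    candidates
        Covariates entering the univariable screen.  Defaults to every
        non-outcome, non-id column.
    reference_levels
        Per-covariate reference category; unlisted covariates use their first
        observed level.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str = "satisfied",
        candidates: Sequence[str] | None = None,
        reference_levels: Mapping[str, str] | None = None,
        confidence: float = 0.95,
    ) -> None:
        if outcome not in data.columns:
            raise InvalidConfigError(f"outcome column {outcome!r} not in data")
        if candidates is None:
            candidates = [
                c for c in data.columns
                if c != outcome and c != "id" and not c.startswith("q")
            ]
        missing = [c for c in candidates if c not in data.columns]
        if missing:
            raise InvalidConfigError(f"candidate column(s) not in data: {missing}")
        self.data = data
        self.outcome = outcome
        self.candidates = list(candidates)
        self.reference_levels = dict(reference_levels or {})
        self.confidence = confidence

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str = "satisfied",
        candidates: Sequence[str] | None = None,
        reference_levels: Mapping[str, str] | None = None,
        confidence: float = 0.95,
    ) -> "AcceptabilityModel":
        return cls(data, outcome, candidates, reference_levels, confidence)

    @classmethod
    def from_items(
        cls,
        data: pd.DataFrame,
        scale: LikertScaleSpec,
        candidates: Sequence[str] | None = None,
        reference_levels: Mapping[str, str] | None = None,
        confidence: float = 0.95,
        outcome: str = "satisfied",
    ) -> "AcceptabilityModel":
        """Derive the outcome from Likert item columns ``q1..qN`` first.

        Respondents whose item total exceeds the demarcation cutoff are
        labelled satisfied; the item columns are then dropped from the
        candidate set.
        """
        item_cols = [f"q{i + 1}" for i in range(scale.n_items)]
        missing = [c for c in item_cols if c not in data.columns]
        if missing:
            raise InvalidConfigError(f"missing item columns: {missing}")
        totals = data[item_cols].sum(axis=1)
        out = data.copy()
        out[outcome] = [
            SATISFIED if s else DISSATISFIED
            for s in classify_totals(totals.to_numpy(), scale)
        ]
        if candidates is None:
            candidates = [
                c for c in data.columns
                if c not in item_cols and c not in (outcome, "id")
            ]
        return cls(out, outcome, candidates, reference_levels, confidence)

    # -- fitting ------------------------------------------------------------

    def crude_table(self, variable: str) -> dict[str, tuple[int, int]]:
        """Level -> (satisfied, dissatisfied) counts for one covariate."""
        from .association import _outcome_vector  # shared outcome coding

        y = _outcome_vector(self.data, self.outcome)
        levels = self.data[variable].astype(str)
        out: dict[str, tuple[int, int]] = {}
        for level in pd.unique(levels):
            mask = (levels == level).to_numpy()
            out[str(level)] = (int(y[mask].sum()), int((1 - y[mask]).sum()))
        return out

    def fit(
        self,
        alpha_screen: float = 0.25,
        screen_method: str = "wald",
        continuity: bool = False,
    ) -> "AcceptabilityResults":
        crude: dict[str, list[AssociationResult]] = {}
        for var in self.candidates:
            counts = self.crude_table(var)
            ref = self.reference_levels.get(var, next(iter(counts)))
            crude[var] = categorical_crude_ors(
                counts,
                reference_level=str(ref),
                confidence=self.confidence,
                continuity=continuity,
                variable=var,
            )
        screening = screen_bivariable(
            self.data,
            self.outcome,
            self.candidates,
            alpha_screen=alpha_screen,
            reference_levels=self.reference_levels,
            method=screen_method,
        )
        retained = list(screening)
        adjusted = (
            fit_logistic(
                self.data,
                self.outcome,
                retained,
                reference_levels=self.reference_levels,
                confidence=self.confidence,
            )
            if retained
            else None
        )
        return AcceptabilityResults(
            model=self,
            crude=crude,
            screening_pvalues=screening,
            retained=retained,
            adjusted=adjusted,
            alpha_screen=alpha_screen,
        )


@dataclass
class AcceptabilityResults:
    """Crude ORs, screening outcome and the multivariable fit, with summary."""

    model: AcceptabilityModel
    crude: dict[str, list[AssociationResult]]
    screening_pvalues: dict[str, float]
    retained: list[str]
    adjusted: LogisticModelFit | None
    alpha_screen: float
    _adjusted_by_term: dict = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.adjusted is not None:
            for r in self.adjusted.association_results():
                self._adjusted_by_term[(r.variable, r.level_label)] = r

    def adjusted_result(self, variable: str, level: str) -> AssociationResult | None:
        return self._adjusted_by_term.get((variable, str(level)))

    def summary_frame(self) -> pd.DataFrame:
        """Table-style report: one row per covariate level, COR and AOR columns."""
        rows = []
        for var, results in self.crude.items():
            for r in results:
                adj = self.adjusted_result(var, r.level_label)
                rows.append(
                    {
                        "variable": var,
                        "level": r.level_label,
                        "satisfied": self.model.crude_table(var)[r.level_label][0],
                        "dissatisfied": self.model.crude_table(var)[r.level_label][1],
                        "is_reference": r.is_reference,
                        "COR": r.odds_ratio,
                        "COR_ci_low": r.ci_low,
                        "COR_ci_high": r.ci_high,
                        "COR_p": r.p_value,
                        "screened_in": var in self.retained,
                        "AOR": adj.odds_ratio if adj else (1.0 if r.is_reference and var in self.retained else None),
                        "AOR_ci_low": adj.ci_low if adj else None,
                        "AOR_ci_high": adj.ci_high if adj else None,
                        "AOR_p": adj.p_value if adj else None,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.summary_frame()
        shown = frame.copy()
        for col in ("COR", "COR_ci_low", "COR_ci_high", "AOR", "AOR_ci_low",
                    "AOR_ci_high"):
            shown[col] = shown[col].map(
                lambda v: f"{v:.2f}" if pd.notna(v) else ""
            )
        for col in ("COR_p", "AOR_p"):
            shown[col] = shown[col].map(
                lambda v: f"{v:.4f}" if pd.notna(v) else ""
            )
        lines = [
            "Acceptability association analysis",
            "----------------------------------",
            f"n = {len(self.model.data)}, outcome = {self.model.outcome!r}",
            f"screened in at p < {self.alpha_screen}: "
            + (", ".join(self.retained) if self.retained else "(none)"),
            "",
            shown.to_string(index=False),
        ]
        if self.adjusted is not None:
            lines.append("")
            lines.append(
                f"multivariable fit: converged={self.adjusted.converged} "
                f"in {self.adjusted.n_iterations} iterations, "
                f"log-likelihood {self.adjusted.log_likelihood:.2f}"
            )
            if self.adjusted.separation_suspected:
                lines.append("warning: separation suspected (|coef| > 15)")
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary()
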