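"""Crude and adjusted odds-ratio analysis for program acceptability.

The analytic chain is the standard epidemiological one:

* crude odds ratios from 2x2 tables with Woolf (log-normal) confidence
  intervals, ``OR = ad/bc`` and ``SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d)``;
* univariable screening of candidate covariates, retaining those with any
  level's p-value below a liberal threshold (0.25 by convention);
* a multivariable binary logistic regression on the retained covariates,
  reporting adjusted odds ratios ``exp(beta)`` with Wald 95% intervals.

The maximum-likelihood logistic fit itself is delegated to statsmodels
(Newton iterations); this module owns the table algebra, the screening rule
and the reference-level bookkeeping.  A single-proportion sample-size
calculator with non-response inflation rounds out the survey-planning side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    DegenerateOutcomeError,
    InvalidConfigError,
    ZeroCellError,
)

__all__ = [
    "TwoByTwoTable",
    "AssociationResult",
    "LogisticModelFit",
    "crude_odds_ratio",
    "categorical_crude_ors",
    "screen_bivariable",
    "fit_logistic",
    "sample_size_proportion",
    "SEPARATION_COEF_BOUND",
]

#: Absolute coefficient magnitude beyond which a logistic fit is flagged as
#: (quasi-)separated; e^15 ~ 3.3e6 is far outside any plausible odds ratio.
SEPARATION_COEF_BOUND = 15.0


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure x outcome counts.

    a = exposed & satisfied, b = exposed & dissatisfied,
    c = reference & satisfied, d = reference & dissatisfied.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise InvalidConfigError(f"negative cell in 2x2 table: {cells}")
        if sum(cells) <= 0:
            raise InvalidConfigError("2x2 table is empty")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def corrected(self) -> "TwoByTwoTable":
        """Haldane-Anscombe correction: add 0.5 to every cell."""
        return TwoByTwoTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class AssociationResult:
    """An odds ratio (crude or adjusted) with its Wald interval and p-value."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float | None
    level_label: str = ""
    reference_label: str = ""
    variable: str = ""
    kind: str = "crude"
    corrected: bool = False
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise InvalidConfigError(
                f"inconsistent interval: {self.ci_low} <= {self.odds_ratio} "
                f"<= {self.ci_high} fails"
            )
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise InvalidConfigError(f"p-value {self.p_value} outside [0, 1]")

    def __str__(self) -> str:  # pragma: no cover - convenience
        if self.is_reference:
            return f"{self.variable} {self.level_label}: 1 (reference)"
        return (
            f"{self.variable} {self.level_label}: "
            f"{self.odds_ratio:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f})"
        )


def crude_odds_ratio(
    table: TwoByTwoTable,
    confidence: float = 0.95,
    continuity: bool = False,
    variable: str = "",
    level_label: str = "",
    reference_label: str = "",
) -> AssociationResult:
    """Crude OR = ad/bc with a Woolf confidence interval and Wald p-value.

    A zero cell is an error unless ``continuity=True``, in which case the
    Haldane-Anscombe correction (0.5 added to every cell) is applied and the
    result flagged as corrected.
    """
    if not (0 < confidence < 1):
        raise InvalidConfigError(f"confidence must be in (0, 1), got {confidence}")
    corrected = False
    if any(x == 0 for x in table.cells):
        if not continuity:
            raise ZeroCellError(
                f"2x2 table {table.cells} has an empty cell; pass continuity=True "
                "to apply the Haldane-Anscombe correction"
            )
        table = table.corrected()
        corrected = True
    a, b, c, d = table.cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return AssociationResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p),
        variable=variable,
        level_label=level_label,
        reference_label=reference_label,
        corrected=corrected,
    )


def categorical_crude_ors(
    level_counts: Mapping[str, tuple[float, float]],
    reference_level: str,
    confidence: float = 0.95,
    continuity: bool = False,
    variable: str = "",
) -> list[AssociationResult]:
    """One crude OR per non-reference level of a categorical exposure.

    ``level_counts`` maps level -> (satisfied, dissatisfied).  The reference
    level is reported first with OR fixed at 1 and no p-value.
    """
    if reference_level not in level_counts:
        raise InvalidConfigError(
            f"reference level {reference_level!r} not among levels "
            f"{sorted(level_counts)}"
        )
    c_ref, d_ref = level_counts[reference_level]
    results = [
        AssociationResult(
            odds_ratio=1.0,
            ci_low=1.0,
            ci_high=1.0,
            p_value=None,
            variable=variable,
            level_label=reference_level,
            reference_label=reference_level,
            is_reference=True,
        )
    ]
    for level, (sat, dissat) in level_counts.items():
        if level == reference_level:
            continue
        results.append(
            crude_odds_ratio(
                TwoByTwoTable(sat, dissat, c_ref, d_ref),
                confidence=confidence,
                continuity=continuity,
                variable=variable,
                level_label=level,
                reference_label=reference_level,
            )
        )
    return results


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticModelFit:
    """A fitted binary logistic regression with per-term Wald inference.

    ``params`` etc. are indexed by term name; categorical covariates expand to
    ``variable[level]`` dummy terms against their declared reference level.
    Odds ratios are ``exp(coef)`` and interval bounds ``exp(coef +/- z*SE)``.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    converged: bool
    n_iterations: int
    log_likelihood: float
    nobs: int
    term_variables: dict[str, str] = field(default_factory=dict)
    term_levels: dict[str, str] = field(default_factory=dict)
    reference_levels: dict[str, str] = field(default_factory=dict)
    separation_suspected: bool = False
    confidence: float = 0.95

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def or_conf_int(self) -> pd.DataFrame:
        return np.exp(self.conf_int)

    def association_results(self) -> list[AssociationResult]:
        """Adjusted ORs for the non-intercept terms."""
        out = []
        for term in self.params.index:
            if term == "const":
                continue
            out.append(
                AssociationResult(
                    odds_ratio=float(np.exp(self.params[term])),
                    ci_low=float(np.exp(self.conf_int.loc[term, 0])),
                    ci_high=float(np.exp(self.conf_int.loc[term, 1])),
                    p_value=float(self.pvalues[term]),
                    variable=self.term_variables.get(term, term),
                    level_label=self.term_levels.get(term, ""),
                    reference_label=self.reference_levels.get(
                        self.term_variables.get(term, term), ""
                    ),
                    kind="adjusted",
                )
            )
        return out

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "odds_ratio": self.odds_ratios,
                "ci_low": np.exp(self.conf_int[0]),
                "ci_high": np.exp(self.conf_int[1]),
                "p_value": self.pvalues,
            }
        )


def _build_design(
    data: pd.DataFrame,
    variables: Sequence[str],
    reference_levels: Mapping[str, str] | None,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str], dict[str, str]]:
    """Dummy-code categorical covariates against their reference levels."""
    reference_levels = dict(reference_levels or {})
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    term_variables: dict[str, str] = {}
    term_levels: dict[str, str] = {}
    used_refs: dict[str, str] = {}
    for var in variables:
        if var not in data.columns:
            raise InvalidConfigError(f"variable {var!r} not in data")
        col = data[var]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            X[var] = col.astype(float)
            term_variables[var] = var
            term_levels[var] = ""
            continue
        levels = [str(v) for v in pd.unique(col.astype(str))]
        ref = str(reference_levels.get(var, levels[0]))
        if ref not in levels:
            raise InvalidConfigError(
                f"reference level {ref!r} for {var!r} absent from data "
                f"(levels: {sorted(levels)})"
            )
        used_refs[var] = ref
        for level in levels:
            if level == ref:
                continue
            term = f"{var}[{level}]"
            X[term] = (col.astype(str) == level).astype(float)
            term_variables[term] = var
            term_levels[term] = level
    return X, term_variables, term_levels, used_refs


def _outcome_vector(data: pd.DataFrame, outcome: str) -> np.ndarray:
    col = data[outcome]
    if col.dtype == bool:
        y = col.to_numpy(dtype=float)
    elif pd.api.types.is_numeric_dtype(col):
        y = col.to_numpy(dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise InvalidConfigError(f"outcome {outcome!r} is not binary 0/1")
    else:
        vals = set(col.astype(str).unique())
        if vals <= {"satisfied", "dissatisfied"}:
            y = (col.astype(str) == "satisfied").to_numpy(dtype=float)
        elif vals <= {"yes", "no"}:
            y = (col.astype(str) == "yes").to_numpy(dtype=float)
        else:
            raise InvalidConfigError(
                f"cannot interpret outcome {outcome!r} with values {sorted(vals)}"
            )
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError(f"outcome {outcome!r} is constant")
    return y


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    variables: Sequence[str],
    reference_levels: Mapping[str, str] | None = None,
    confidence: float = 0.95,
    maxiter: int = 50,
    tol: float = 1e-10,
) -> LogisticModelFit:
    """Maximum-likelihood binary logistic regression with Wald inference.

    Newton iterations, capped at ``maxiter``, declare convergence when the
    coefficient update falls below ``tol``.  Non-convergence is reported in
    the fit (``converged=False``) rather than raised; coefficients of
    magnitude above :data:`SEPARATION_COEF_BOUND` trigger a separation
    warning and set ``separation_suspected``.
    """
    y = _outcome_vector(data, outcome)
    X, term_variables, term_levels, used_refs = _build_design(
        data, variables, reference_levels
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels convergence chatter
        model = sm.Logit(y, X)
        res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=False,
                        warn_convergence=False)
    converged = bool(res.mle_retvals.get("converged", False))
    n_iter = int(res.mle_retvals.get("iterations", maxiter))
    params = pd.Series(res.params, index=X.columns)
    separation = bool(
        (params.drop(labels=["const"], errors="ignore").abs()
         > SEPARATION_COEF_BOUND).any()
    )
    if separation:
        warnings.warn(
            "logistic fit has |coef| > "
            f"{SEPARATION_COEF_BOUND}; complete or quasi-complete separation "
            "is likely and the Wald intervals are unreliable",
            UserWarning,
            stacklevel=2,
        )
    alpha = 1 - confidence
    ci = pd.DataFrame(
        np.asarray(res.conf_int(alpha=alpha)), index=X.columns, columns=[0, 1]
    )
    return LogisticModelFit(
        params=params,
        bse=pd.Series(res.bse, index=X.columns),
        pvalues=pd.Series(res.pvalues, index=X.columns),
        conf_int=ci,
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=float(res.llf),
        nobs=int(res.nobs),
        term_variables=term_variables,
        term_levels=term_levels,
        reference_levels=used_refs,
        separation_suspected=separation,
        confidence=confidence,
    )


def screen_bivariable(
    data: pd.DataFrame,
    outcome: str,
    candidate_variables: Sequence[str],
    alpha_screen: float = 0.25,
    reference_levels: Mapping[str, str] | None = None,
    method: str = "wald",
) -> dict[str, float]:
    """Univariable screening: keep covariates with any-level p < alpha_screen.

    ``method="wald"`` fits one univariable logistic model per candidate and
    takes the smallest Wald p-value over its levels; ``method="chi2"`` uses a
    Pearson chi-square test on the level x outcome contingency table instead.
    Constant covariates are excluded with a warning.  Returns an ordered
    mapping of retained variable -> screening p-value.
    """
    if method not in ("wald", "chi2"):
        raise InvalidConfigError(f"unknown screening method {method!r}")
    if not (0 < alpha_screen <= 1):
        raise InvalidConfigError(f"alpha_screen must be in (0, 1], got {alpha_screen}")
    _outcome_vector(data, outcome)  # raises if degenerate
    retained: dict[str, float] = {}
    for var in candidate_variables:
        if var not in data.columns:
            raise InvalidConfigError(f"candidate {var!r} not in data")
        if data[var].nunique() < 2:
            warnings.warn(
                f"candidate {var!r} is constant; excluded from screening",
                UserWarning,
                stacklevel=2,
            )
            continue
        p = _screening_pvalue(data, outcome, var, reference_levels, method)
        if p < alpha_screen:
            retained[var] = p
    return retained


def _screening_pvalue(
    data: pd.DataFrame,
    outcome: str,
    var: str,
    reference_levels: Mapping[str, str] | None,
    method: str,
) -> float:
    if method == "wald":
        try:
            fit = fit_logistic(data, outcome, [var], reference_levels)
            ps = fit.pvalues.drop(labels=["const"], errors="ignore")
            if fit.separation_suspected or not np.isfinite(ps).all():
                raise np.linalg.LinAlgError("unstable univariable fit")
            return float(ps.min())
        except (np.linalg.LinAlgError, ValueError):
            # singular/separated small-sample fit: fall back to chi-square
            pass
    table = pd.crosstab(data[var], _outcome_vector(data, outcome))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p, _, _ = stats.chi2_contingency(table.to_numpy())
    return float(p)


# ---------------------------------------------------------------------------
# survey planning
# ---------------------------------------------------------------------------


def sample_size_proportion(
    p: float,
    d: float,
    confidence: float = 0.95,
    nonresponse: float = 0.0,
) -> int:
    """Sample size for estimating a single proportion.

    ``n0 = z^2 p (1-p) / d^2`` rounded up, then inflated by the anticipated
    non-response fraction and rounded to the nearest integer.  With p = 0.74,
    d = 0.04, 95% confidence and 10% non-response this yields 508.
    """
    if not (0 < p < 1):
        raise InvalidConfigError(f"anticipated proportion must be in (0, 1), got {p}")
    if not (0 < d < 1):
        raise InvalidConfigError(f"margin of error must be in (0, 1), got {d}")
    if not (0 < confidence < 1):
        raise InvalidConfigError(f"confidence must be in (0, 1), got {confidence}")
    if not (0 <= nonresponse < 1):
        raise InvalidConfigError(
            f"non-response fraction must be in [0, 1), got {nonresponse}"
        )
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    n0 = math.ceil(z * z * p * (1 - p) / (d * d))
    return int(round(n0 * (1 + nonresponse)))
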