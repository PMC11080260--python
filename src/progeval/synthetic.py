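"""Synthetic exit-interview and indicator-table generators.

No public microdata exist for caregiver exit interviews of this kind, so the
package ships a generator that emulates their statistical structure end to
end, making every pipeline stage testable:

* covariates are drawn independently from configured categorical marginals
  (defaults follow the published sample of 484 caregivers: e.g. 52.1%
  illiterate, 85.7% rural, 84.5% received the prescribed drugs);
* a latent satisfaction indicator is drawn from a logistic model whose
  non-zero log-odds default to the published adjusted odds ratios for the
  significant factors (education, drug availability, arrival time, waiting
  time); the intercept is solved by bisection on the realized covariates so
  the expected satisfied fraction equals ``target_prevalence`` (default
  0.762, i.e. 369/484);
* 14 five-point Likert item responses are drawn conditional on the latent
  class, constrained so the item total exceeds the demarcation cutoff iff
  the respondent is latently satisfied — classification through the Likert
  stage therefore recovers the generator's truth exactly, and refitting the
  logistic model recovers the configured coefficients.

Indicator tables are emulated as independent binomials O ~ Bin(E, p) with
weights copied from the configuration.  A largest-remainder apportionment
helper reproduces proportional-to-caseload sample allocation across sites.

Randomness: one root seed is expanded into named substreams (one per
covariate, one for satisfaction, one for items) so adding a covariate to the
configuration does not perturb the draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import InvalidConfigError
from .likert import LikertScaleSpec, demarcation_cutoff
from .matrix import Indicator

__all__ = [
    "SurveyGeneratorConfig",
    "IndicatorGeneratorConfig",
    "DEFAULT_COVARIATE_DISTRIBUTIONS",
    "DEFAULT_EFFECT_SIZES",
    "DEFAULT_REFERENCE_LEVELS",
    "generate_exit_interviews",
    "generate_indicator_table",
    "allocate_samples_proportional",
    "solve_intercept",
]


def _normalized(dist: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(dist.values()))
    if total <= 0:
        raise InvalidConfigError(f"distribution {dist} has non-positive mass")
    return {k: v / total for k, v in dist.items()}


#: Default covariate marginals, matching the published descriptive table of
#: the 484 interviewed caregivers (proportions renormalized to sum to 1).
DEFAULT_COVARIATE_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "age_group": _normalized({"18-25": 0.161, "26-30": 0.386, "31-35": 0.241, ">=36": 0.211}),
    "sex": _normalized({"male": 0.07, "female": 0.93}),
    "family_size": _normalized({"<4": 0.347, "4-8": 0.587, "9-12": 0.066}),
    "residence": _normalized({"urban": 0.143, "rural": 0.857}),
    "income": _normalized({"<=500": 0.085, "501-1000": 0.378, "1001-2000": 0.415,
                           "2001-3000": 0.103, ">3000": 0.019}),
    "education": _normalized({"illiterate": 0.521, "read_write": 0.163,
                              "primary": 0.213, "secondary": 0.074, "college": 0.029}),
    "occupation": _normalized({"government": 0.045, "farmer": 0.205, "trader": 0.083,
                               "housewife": 0.626, "daily_laborer": 0.041}),
    "under_five_children": _normalized({"one": 0.550, "two": 0.422, "three": 0.029}),
    "counseling": _normalized({"yes": 0.886, "no": 0.114}),
    "prescribed_drugs": _normalized({"yes": 0.845, "no": 0.155}),
    "arrival_time": _normalized({"<60min": 0.864, ">=60min": 0.136}),
    "waiting_time": _normalized({"<30min": 0.934, ">=30min": 0.066}),
    "appointment": _normalized({"yes": 0.905, "no": 0.095}),
    "home_visit": _normalized({"yes": 0.932, "no": 0.068}),
    "information_source": _normalized({"health_professional": 0.789, "family": 0.079,
                                       "neighbor": 0.132}),
}

#: Default per-level log-odds: natural logs of the published adjusted odds
#: ratios for the factors that were significant in the multivariable model;
#: every other covariate has no effect.
DEFAULT_EFFECT_SIZES: dict[str, dict[str, float]] = {
    "education": {
        "primary": math.log(0.27),
        "secondary": math.log(0.16),
        "college": math.log(0.08),
    },
    "prescribed_drugs": {"yes": math.log(2.16)},
    "arrival_time": {"<60min": math.log(3.82)},
    "waiting_time": {"<30min": math.log(2.79)},
}

#: Reference categories implied by the effect-size defaults.
DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "education": "illiterate",
    "occupation": "government",
    "under_five_children": "three",
    "counseling": "no",
    "prescribed_drugs": "no",
    "arrival_time": ">=60min",
    "waiting_time": ">=30min",
    "appointment": "no",
    "home_visit": "no",
    "information_source": "neighbor",
}

# item-response category probabilities (scale positions item_min..item_max)
_SATISFIED_ITEM_PROBS = (0.01, 0.03, 0.08, 0.38, 0.50)
_DISSATISFIED_ITEM_PROBS = (0.20, 0.35, 0.25, 0.15, 0.05)


@dataclass
class SurveyGeneratorConfig:
    """Configuration for the exit-interview generator.

    The defaults reproduce the study conditions the analysis assumes: 484
    respondents, the published covariate marginals, effect sizes equal to the
    published significant adjusted odds ratios, and a satisfied fraction of
    0.762.
    """

    n_respondents: int = 484
    covariate_distributions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_COVARIATE_DISTRIBUTIONS.items()}
    )
    effect_sizes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_SIZES.items()}
    )
    target_prevalence: float = 0.762
    scale: LikertScaleSpec = field(default_factory=LikertScaleSpec)
    satisfied_item_probs: tuple[float, ...] = _SATISFIED_ITEM_PROBS
    dissatisfied_item_probs: tuple[float, ...] = _DISSATISFIED_ITEM_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 0:
            raise InvalidConfigError("n_respondents must be >= 0")
        if not (0 < self.target_prevalence < 1):
            raise InvalidConfigError(
                f"target_prevalence must be in (0, 1), got {self.target_prevalence}"
            )
        for var, dist in self.covariate_distributions.items():
            if any(p < 0 for p in dist.values()):
                raise InvalidConfigError(f"negative probability for {var!r}")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise InvalidConfigError(
                    f"probabilities for {var!r} sum to {sum(dist.values())}, not 1"
                )
        for var in self.effect_sizes:
            if var not in self.covariate_distributions:
                raise InvalidConfigError(
                    f"effect sizes given for unknown covariate {var!r}"
                )
        n_cat = self.scale.item_max - self.scale.item_min + 1
        for name, probs in (("satisfied", self.satisfied_item_probs),
                            ("dissatisfied", self.dissatisfied_item_probs)):
            if len(probs) != n_cat or abs(sum(probs) - 1.0) > 1e-9:
                raise InvalidConfigError(
                    f"{name}_item_probs must be {n_cat} probabilities summing to 1"
                )


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream: stable child generator keyed by (root seed, name)."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def _linear_predictor(
    covariates: pd.DataFrame, effect_sizes: Mapping[str, Mapping[str, float]]
) -> np.ndarray:
    eta = np.zeros(len(covariates))
    for var, level_effects in effect_sizes.items():
        col = covariates[var].astype(str).to_numpy()
        for level, beta in level_effects.items():
            eta += beta * (col == level)
    return eta


def solve_intercept(
    eta: np.ndarray, target_prevalence: float, tol: float = 1e-6
) -> float:
    """Bisection for b0 with mean(expit(b0 + eta)) = target_prevalence.

    The mean response probability is continuous and strictly increasing in
    the intercept, so bisection over a wide bracket converges; an unreachable
    target (possible only at degenerate tolerance) raises a config error.
    """
    lo, hi = -40.0, 40.0

    def prevalence(b0: float) -> float:
        return float(np.mean(expit(b0 + eta)))

    if not (prevalence(lo) <= target_prevalence <= prevalence(hi)):
        raise InvalidConfigError(
            f"target prevalence {target_prevalence} unreachable for this "
            "covariate configuration"
        )
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if prevalence(mid) < target_prevalence:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _draw_items(
    rng: np.random.Generator,
    satisfied: np.ndarray,
    scale: LikertScaleSpec,
    satisfied_probs: Sequence[float],
    dissatisfied_probs: Sequence[float],
    max_tries: int = 100,
) -> np.ndarray:
    """Draw item responses so that total > cutoff exactly when satisfied.

    Responses are iid categorical within each latent class; rows landing on
    the wrong side of the cutoff are redrawn, and after ``max_tries`` rounds
    the few stragglers are pinned to the scale extreme of their class.
    """
    n = len(satisfied)
    cutoff = demarcation_cutoff(scale)
    values = np.arange(scale.item_min, scale.item_max + 1)
    items = np.empty((n, scale.n_items), dtype=int)
    for cls, probs in ((True, satisfied_probs), (False, dissatisfied_probs)):
        idx = np.flatnonzero(satisfied == cls)
        if idx.size == 0:
            continue
        pending = idx
        for _ in range(max_tries):
            if pending.size == 0:
                break
            draw = rng.choice(values, size=(pending.size, scale.n_items), p=list(probs))
            items[pending] = draw
            totals = draw.sum(axis=1)
            ok = (totals > cutoff) if cls else (totals <= cutoff)
            pending = pending[~ok]
        if pending.size:
            items[pending] = scale.item_max if cls else scale.item_min
    return items


def generate_exit_interviews(cfg: SurveyGeneratorConfig) -> pd.DataFrame:
    """Generate respondent records: id, covariates, and q1..qN item columns.

    Fully reproducible for a fixed ``cfg.seed``; returns an empty (but
    correctly-shaped) frame for ``n_respondents = 0``.
    """
    item_cols = [f"q{i + 1}" for i in range(cfg.scale.n_items)]
    columns = ["id", *cfg.covariate_distributions.keys(), *item_cols]
    if cfg.n_respondents == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})

    data: dict[str, np.ndarray | list] = {}
    for var, dist in cfg.covariate_distributions.items():
        levels = list(dist.keys())
        probs = np.array([dist[k] for k in levels])
        rng = _stream(cfg.seed, f"covariate:{var}")
        data[var] = rng.choice(levels, size=cfg.n_respondents, p=probs)
    covariates = pd.DataFrame(data)

    eta = _linear_predictor(covariates, cfg.effect_sizes)
    b0 = solve_intercept(eta, cfg.target_prevalence)
    rng_sat = _stream(cfg.seed, "satisfaction")
    satisfied = rng_sat.random(cfg.n_respondents) < expit(b0 + eta)

    rng_items = _stream(cfg.seed, "items")
    items = _draw_items(
        rng_items, satisfied, cfg.scale,
        cfg.satisfied_item_probs, cfg.dissatisfied_item_probs,
    )

    out = covariates
    out.insert(0, "id", [f"r{i + 1:06d}" for i in range(cfg.n_respondents)])
    for j, col in enumerate(item_cols):
        out[col] = items[:, j]
    return out


# ---------------------------------------------------------------------------
# indicator tables
# ---------------------------------------------------------------------------


@dataclass
class IndicatorGeneratorConfig:
    """Binomial emulation of a registry-review indicator table."""

    expected: Sequence[int]
    weights: Sequence[float]
    probabilities: Sequence[float]
    ids: Sequence[str] | None = None
    labels: Sequence[str] | None = None
    dimension_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.expected)
        if not (len(self.weights) == len(self.probabilities) == n) or n == 0:
            raise InvalidConfigError(
                "expected, weights and probabilities must be equal-length, non-empty"
            )
        if any(not (0 <= p <= 1) for p in self.probabilities):
            raise InvalidConfigError("achievement probabilities must lie in [0, 1]")
        if self.ids is None:
            self.ids = [f"{self.dimension_id}_{i + 1:02d}" for i in range(n)]
        if self.labels is None:
            self.labels = [f"synthetic indicator {i + 1}" for i in range(n)]

    @classmethod
    def from_indicators(
        cls,
        indicators: Sequence[Indicator],
        probabilities: Sequence[float] | None = None,
        seed: int = 0,
    ) -> "IndicatorGeneratorConfig":
        """Copy E and W from real indicators; default p to the observed O/E."""
        if probabilities is None:
            probabilities = [i.observed / i.expected for i in indicators]
        return cls(
            expected=[int(i.expected) for i in indicators],
            weights=[i.weight for i in indicators],
            probabilities=list(probabilities),
            ids=[i.id for i in indicators],
            labels=[i.label for i in indicators],
            dimension_id=indicators[0].dimension_id if indicators else "synthetic",
            seed=seed,
        )


def generate_indicator_table(cfg: IndicatorGeneratorConfig) -> list[Indicator]:
    """Draw O ~ Binomial(E, p) per indicator; weights copied from config."""
    rng = _stream(cfg.seed, "indicators")
    observed = rng.binomial(np.asarray(cfg.expected, dtype=int),
                            np.asarray(cfg.probabilities, dtype=float))
    return [
        Indicator(
            id=str(cfg.ids[i]),
            label=str(cfg.labels[i]),
            dimension_id=cfg.dimension_id,
            expected=float(cfg.expected[i]),
            observed=float(observed[i]),
            weight=float(cfg.weights[i]),
        )
        for i in range(len(cfg.expected))
    ]


# ---------------------------------------------------------------------------
# sample allocation
# ---------------------------------------------------------------------------


def allocate_samples_proportional(
    site_caseloads: Sequence[float], total_n: int
) -> list[int]:
    """Largest-remainder (Hamilton) apportionment of total_n across sites.

    Each site receives floor of its exact proportional share; the remaining
    units go to the sites with the largest fractional remainders, ties broken
    deterministically by input order.  Allocations sum exactly to ``total_n``
    and never differ from the exact share by more than one unit.
    """
    caseloads = [float(c) for c in site_caseloads]
    if any(c < 0 for c in caseloads):
        raise InvalidConfigError("caseloads must be non-negative")
    total_load = sum(caseloads)
    if total_load <= 0:
        raise InvalidConfigError("at least one site must have a positive caseload")
    if total_n < 0:
        raise InvalidConfigError("total_n must be >= 0")
    quotas = [total_n * c / total_load for c in caseloads]
    base = [math.floor(q) for q in quotas]
    leftover = total_n - sum(base)
    order = sorted(range(len(quotas)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base
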