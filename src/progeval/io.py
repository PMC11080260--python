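"""CSV/YAML readers and writers and the full-evaluation pipeline driver.

Schemas
-------
Indicator CSV
    UTF-8, comma-delimited, header ``id,label,dimension,expected,observed,
    weight`` with an optional ``score`` column (printed-score override).
Respondent CSV
    Header ``id,<covariate columns>,q1..qN`` with integer item responses.
Count-table CSV
    Header ``variable,level,satisfied,dissatisfied,is_reference``.
Evaluation config YAML
    ``dimension_weights`` (name -> points), ``judgment_bands`` (list of
    ``[low, high, label]``), ``precision``, and a ``likert`` block
    (``n_items``, ``item_min``, ``item_max``, ``agree_threshold``).

Validation failures raise :class:`~progeval.exceptions.ParseError` carrying
the file and 1-based data row they occurred on.  ``run_full_evaluation``
computes every stage before writing any output file, so a failing stage
leaves no partial report behind.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .exceptions import ParseError
from .likert import LikertScaleSpec, item_satisfaction_counts
from .matrix import (
    DEFAULT_JUDGMENT_SCALE,
    DimensionSpec,
    EvaluationMatrix,
    EvaluationReport,
    Indicator,
    JudgmentScale,
    round_half_up,
)
from .model import AcceptabilityModel, AcceptabilityResults

__all__ = [
    "EvaluationConfig",
    "ModelSpec",
    "RunConfig",
    "FullEvaluationResult",
    "load_evaluation_config",
    "load_run_config",
    "read_indicator_csv",
    "write_indicator_csv",
    "read_respondent_csv",
    "write_respondent_csv",
    "read_count_table_csv",
    "write_report",
    "run_full_evaluation",
]

logger = logging.getLogger("progeval")

INDICATOR_COLUMNS = ["id", "label", "dimension", "expected", "observed", "weight"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class EvaluationConfig:
    """Dimension weights, judgment scale and Likert instrument settings."""

    dimension_weights: dict[str, float] = field(
        default_factory=lambda: {"availability": 35.0, "compliance": 40.0,
                                 "acceptability": 25.0}
    )
    scale: JudgmentScale = field(default_factory=lambda: DEFAULT_JUDGMENT_SCALE)
    precision: int = 1
    likert: LikertScaleSpec = field(default_factory=LikertScaleSpec)
    agree_threshold: int = 4


@dataclass
class ModelSpec:
    """Association-model settings: outcome, candidates, references, alphas."""

    outcome: str = "satisfied"
    candidates: list[str] | None = None
    reference_levels: dict[str, str] = field(default_factory=dict)
    alpha_screen: float = 0.25
    confidence: float = 0.95
    screen_method: str = "wald"


@dataclass
class RunConfig:
    """Paths and settings for a full pipeline run."""

    indicator_csv: str | Path
    respondent_csv: str | Path | None = None
    count_table_csv: str | Path | None = None
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    output_dir: str | Path = "progeval_out"
    verbose: bool = False


def load_evaluation_config(path: str | Path) -> EvaluationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return _evaluation_config_from_dict(raw, path)


def _evaluation_config_from_dict(raw: dict, path=None) -> EvaluationConfig:
    cfg = EvaluationConfig()
    if "dimension_weights" in raw:
        cfg.dimension_weights = {
            str(k): float(v) for k, v in raw["dimension_weights"].items()
        }
    if "judgment_bands" in raw:
        try:
            cfg.scale = JudgmentScale(
                bands=tuple((float(lo), float(hi), str(label))
                            for lo, hi, label in raw["judgment_bands"])
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"bad judgment_bands: {exc}", path=path) from exc
    if "precision" in raw:
        cfg.precision = int(raw["precision"])
    likert = raw.get("likert", {})
    cfg.likert = LikertScaleSpec(
        n_items=int(likert.get("n_items", 14)),
        item_min=int(likert.get("item_min", 1)),
        item_max=int(likert.get("item_max", 5)),
    )
    cfg.agree_threshold = int(likert.get("agree_threshold", 4))
    return cfg


def load_run_config(path: str | Path) -> RunConfig:
    base = Path(path).parent
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "indicator_csv" not in raw:
        raise ParseError("run config needs an indicator_csv entry", path=path)

    def _resolve(p):
        return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

    model_raw = raw.get("model", {})
    spec = ModelSpec(
        outcome=model_raw.get("outcome", "satisfied"),
        candidates=model_raw.get("candidates"),
        reference_levels={str(k): str(v) for k, v in
                          model_raw.get("reference_levels", {}).items()},
        alpha_screen=float(model_raw.get("alpha_screen", 0.25)),
        confidence=float(model_raw.get("confidence", 0.95)),
        screen_method=model_raw.get("screen_method", "wald"),
    )
    return RunConfig(
        indicator_csv=_resolve(raw["indicator_csv"]),
        respondent_csv=_resolve(raw.get("respondent_csv")),
        count_table_csv=_resolve(raw.get("count_table_csv")),
        evaluation=_evaluation_config_from_dict(raw.get("evaluation", raw), path),
        model=spec,
        output_dir=_resolve(raw.get("output_dir", "progeval_out")),
        verbose=bool(raw.get("verbose", False)),
    )


# ---------------------------------------------------------------------------
# indicator CSV
# ---------------------------------------------------------------------------


def read_indicator_csv(
    path: str | Path,
    dimension_weights: Mapping[str, float] | None = None,
    scale: JudgmentScale = DEFAULT_JUDGMENT_SCALE,
    drop_invalid: bool = False,
) -> list[DimensionSpec]:
    """Read and validate an indicator CSV, grouped into dimensions.

    Dimensions receive their nominal weight from ``dimension_weights`` (a
    weight of 1 if no mapping is supplied).  With ``drop_invalid=True``, rows
    violating indicator invariants are skipped with a logged warning instead
    of failing the parse.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap with location
        raise ParseError(f"cannot read CSV: {exc}", path=path) from exc
    missing = [c for c in INDICATOR_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"missing column(s): {missing}", path=path)
    has_score = "score" in frame.columns

    indicators: list[Indicator] = []
    seen: set[str] = set()
    for i, row in frame.iterrows():
        rownum = int(i) + 1
        if row["id"] in seen:
            raise ParseError(f"duplicate indicator id {row['id']!r}", path, rownum)
        try:
            override = None
            if has_score and str(row["score"]).strip() != "":
                override = float(row["score"])
            ind = Indicator(
                id=row["id"],
                label=row["label"],
                dimension_id=row["dimension"],
                expected=float(row["expected"]),
                observed=float(row["observed"]),
                weight=float(row["weight"]),
                score_override=override,
            )
        except (ValueError, TypeError) as exc:
            if drop_invalid:
                logger.warning("%s row %d dropped: %s", path, rownum, exc)
                continue
            raise ParseError(str(exc), path, rownum) from exc
        seen.add(ind.id)
        indicators.append(ind)

    by_dim: dict[str, list[Indicator]] = {}
    for ind in indicators:
        by_dim.setdefault(ind.dimension_id, []).append(ind)
    weights = dict(dimension_weights or {})
    return [
        DimensionSpec(id=d, name=d, weight=float(weights.get(d, 1.0)),
                      indicators=tuple(inds))
        for d, inds in by_dim.items()
    ]


def write_indicator_csv(indicators: Sequence[Indicator], path: str | Path) -> None:
    rows = []
    any_override = any(i.score_override is not None for i in indicators)
    for i in indicators:
        row = {
            "id": i.id,
            "label": i.label,
            "dimension": i.dimension_id,
            "expected": i.expected,
            "observed": i.observed,
            "weight": i.weight,
        }
        if any_override:
            row["score"] = "" if i.score_override is None else i.score_override
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# respondent CSV
# ---------------------------------------------------------------------------


def read_respondent_csv(
    path: str | Path,
    scale: LikertScaleSpec | None = None,
    drop_incomplete: bool = False,
) -> pd.DataFrame:
    """Read respondent records, validating item responses against the scale.

    Incomplete records (missing or out-of-range item responses) fail the
    parse unless ``drop_incomplete=True``, in which case they are dropped
    with a logged count.
    """
    path = Path(path)
    scale = scale or LikertScaleSpec()
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot read CSV: {exc}", path=path) from exc
    item_cols = [f"q{i + 1}" for i in range(scale.n_items)]
    missing = [c for c in item_cols if c not in frame.columns]
    if missing:
        raise ParseError(f"missing item column(s): {missing}", path=path)
    items = frame[item_cols].apply(pd.to_numeric, errors="coerce")
    bad = (
        items.isna().any(axis=1)
        | (items < scale.item_min).any(axis=1)
        | (items > scale.item_max).any(axis=1)
    )
    if bad.any():
        if drop_incomplete:
            logger.warning(
                "%s: dropped %d incomplete/out-of-range respondent record(s)",
                path, int(bad.sum()),
            )
            frame = frame.loc[~bad].reset_index(drop=True)
        else:
            first = int(bad.idxmax()) + 1
            raise ParseError(
                f"{int(bad.sum())} record(s) with missing or out-of-range item "
                "responses (pass drop_incomplete=True to skip them)",
                path, first,
            )
    frame[item_cols] = frame[item_cols].astype(int)
    return frame


def write_respondent_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def read_count_table_csv(
    path: str | Path,
) -> dict[str, tuple[dict[str, tuple[int, int]], str]]:
    """Read stratified counts: variable -> ({level: (sat, dissat)}, reference)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"cannot read CSV: {exc}", path=path) from exc
    needed = ["variable", "level", "satisfied", "dissatisfied", "is_reference"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ParseError(f"missing column(s): {missing}", path=path)
    out: dict[str, tuple[dict[str, tuple[int, int]], str]] = {}
    for var, group in frame.groupby("variable", sort=False):
        counts = {
            str(row["level"]): (int(row["satisfied"]), int(row["dissatisfied"]))
            for _, row in group.iterrows()
        }
        refs = group.loc[group["is_reference"].astype(int) == 1, "level"]
        if len(refs) != 1:
            raise ParseError(
                f"variable {var!r} must flag exactly one reference level",
                path=path,
            )
        out[str(var)] = (counts, str(refs.iloc[0]))
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class FullEvaluationResult:
    """Everything a full run produced."""

    report: EvaluationReport
    satisfaction: "object | None" = None  # SatisfactionSummary
    association: AcceptabilityResults | None = None


def write_report(
    report: EvaluationReport, outdir: str | Path, prefix: str = "evaluation"
) -> list[Path]:
    """Write indicator/dimension CSVs and the plain-text report; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = outdir / f"{prefix}_indicators.csv"
    report.indicator_table.to_csv(p, index=False)
    paths.append(p)
    p = outdir / f"{prefix}_dimensions.csv"
    report.dimension_table.to_csv(p, index=False)
    paths.append(p)
    p = outdir / f"{prefix}_report.txt"
    p.write_text(report.summary() + "\n", encoding="utf-8")
    paths.append(p)
    return paths


def run_full_evaluation(cfg: RunConfig) -> FullEvaluationResult:
    """Score -> judge -> likert -> association, then write all outputs.

    All stages are computed before the first file is written; any stage
    error therefore propagates without leaving a partial report.
    """
    t0 = time.perf_counter()
    dims = read_indicator_csv(
        cfg.indicator_csv,
        dimension_weights=cfg.evaluation.dimension_weights,
        scale=cfg.evaluation.scale,
    )
    matrix = EvaluationMatrix(
        dimensions=dims, scale=cfg.evaluation.scale,
        precision=cfg.evaluation.precision,
    )
    report = matrix.evaluate()
    logger.info(
        "scoring stage: %d indicators in %d dimensions (%.3fs)",
        len(report.indicator_table), len(dims), time.perf_counter() - t0,
    )

    satisfaction = None
    association: AcceptabilityResults | None = None
    if cfg.respondent_csv is not None:
        t1 = time.perf_counter()
        respondents = read_respondent_csv(cfg.respondent_csv, cfg.evaluation.likert)
        satisfaction = item_satisfaction_counts(
            respondents, cfg.evaluation.likert, cfg.evaluation.agree_threshold
        )
        model = AcceptabilityModel.from_items(
            respondents,
            cfg.evaluation.likert,
            candidates=cfg.model.candidates,
            reference_levels=cfg.model.reference_levels,
            confidence=cfg.model.confidence,
            outcome=cfg.model.outcome,
        )
        association = model.fit(
            alpha_screen=cfg.model.alpha_screen,
            screen_method=cfg.model.screen_method,
        )
        logger.info(
            "likert+association stage: %d respondents, %d candidates retained "
            "(%.3fs)", len(respondents), len(association.retained),
            time.perf_counter() - t1,
        )

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(report, outdir)
    if satisfaction is not None:
        pd.DataFrame(
            {
                "item": [f"q{i + 1}" for i in range(len(satisfaction.item_counts))],
                "satisfied_count": satisfaction.item_counts,
                "satisfied_percent": [
                    round_half_up(p, cfg.evaluation.precision)
                    for p in satisfaction.item_percents
                ],
            }
        ).to_csv(outdir / "item_satisfaction.csv", index=False)
    if association is not None:
        association.summary_frame().to_csv(outdir / "association_results.csv",
                                           index=False)
    logger.info("full evaluation finished in %.3fs", time.perf_counter() - t0)
    return FullEvaluationResult(report=report, satisfaction=satisfaction,
                                association=association)
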