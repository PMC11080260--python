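"""Bundled example data.

The package ships the indicator checklists and exit-interview count tables of
a 2022 implementation evaluation of an integrated community case management
(ICCM) program run through an Ethiopian urban health-post network: 17
resource-availability indicators observed across 14 health posts, 18
provider-compliance indicators from record review and observed consultations,
14 caregiver-acceptability items from 484 exit interviews, and the
satisfaction/dissatisfaction counts per covariate level feeding the
association analysis.

The acceptability checklist carries a ``score`` column: its published score
column is the authoritative record for that dimension (one row's printed
observed count disagrees with its own printed score), so the bundled file
preserves both and the scoring engine uses the score override where present.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .io import (
    EvaluationConfig,
    load_evaluation_config,
    read_count_table_csv,
    read_indicator_csv,
)
from .matrix import DimensionSpec, EvaluationMatrix

__all__ = [
    "data_path",
    "load_availability_indicators",
    "load_compliance_indicators",
    "load_acceptability_indicators",
    "load_exit_interview_counts",
    "load_example_config",
    "load_example_matrix",
]

_DIMENSION_FILES = {
    "availability": "availability_indicators.csv",
    "compliance": "compliance_indicators.csv",
    "acceptability": "acceptability_indicators.csv",
}


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(files("progeval.data").joinpath(name)))


def _load_dimension(name: str, config: EvaluationConfig) -> DimensionSpec:
    dims = read_indicator_csv(
        data_path(_DIMENSION_FILES[name]),
        dimension_weights=config.dimension_weights,
        scale=config.scale,
    )
    assert len(dims) == 1
    return dims[0]


def load_example_config() -> EvaluationConfig:
    return load_evaluation_config(data_path("evaluation_config.yaml"))


def load_availability_indicators(config: EvaluationConfig | None = None) -> DimensionSpec:
    """17 resource-availability indicators over 14 health posts."""
    return _load_dimension("availability", config or load_example_config())


def load_compliance_indicators(config: EvaluationConfig | None = None) -> DimensionSpec:
    """18 guideline-compliance indicators from record review and observation."""
    return _load_dimension("compliance", config or load_example_config())


def load_acceptability_indicators(config: EvaluationConfig | None = None) -> DimensionSpec:
    """14 caregiver-acceptability items (with printed-score overrides)."""
    return _load_dimension("acceptability", config or load_example_config())


def load_exit_interview_counts():
    """Satisfied/dissatisfied counts per covariate level (484 caregivers)."""
    return read_count_table_csv(data_path("exit_interview_counts.csv"))


def load_example_matrix() -> EvaluationMatrix:
    """The full three-dimension evaluation matrix with its 35/40/25 weights."""
    config = load_example_config()
    dims = [_load_dimension(name, config) for name in _DIMENSION_FILES]
    return EvaluationMatrix(
        dimensions=dims, scale=config.scale, precision=config.precision
    )
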