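"""Pydantic models defining the machine-readable report schemas.

Every JSON report the pipeline writes is validated against one of these
models first; the corresponding JSON Schema documents are shipped under
``trialaudit/schemas/`` (regenerate with ``python -m trialaudit.report_schemas``).
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field


class MethodReport(BaseModel):
    replicate_unit: str
    n_significant: int = Field(ge=0)
    n_timepoints: int = Field(gt=0)
    df: list[float]
    t: list[float]
    p: list[float]
    mask: list[bool]
    grand_mean: dict[str, list[float]]
    replicate_sd: dict[str, list[float]]


class AvgStatsReport(BaseModel):
    schema_version: int
    alpha: float = Field(gt=0, lt=1)
    correction: str
    methods: dict[str, MethodReport]
    time_axis_s: list[float]


class PermCheckReport(BaseModel):
    schema_version: int
    method: str
    scope: str
    n_permutations: int = Field(ge=0)
    audit_alpha: float = Field(gt=0, lt=1)
    seed: int
    significant_counts: list[int]
    flagged: list[bool]
    n_flagged: int = Field(ge=0)
    fraction_flagged: float | None


class FeatureSpecReport(BaseModel):
    representation: str
    baseline_window_s: list[float]
    response_window_s: list[float]
    baseline_correct: bool


class ClassifierReport(BaseModel):
    kernel: str
    c_grid: list[float]
    outer_folds: int = Field(ge=2)
    inner_folds: int = Field(ge=2)
    seed: int


class DayReport(BaseModel):
    day_id: str
    k: int = Field(ge=0)
    n: int = Field(ge=1)
    accuracy: float = Field(ge=0, le=1)
    fold_accuracies: list[float]
    selected_c: list[float]
    p_value: float = Field(ge=0, le=1)
    significant: bool
    warnings: list[str]


class ClassifyReport(BaseModel):
    schema_version: int
    chance: float = Field(gt=0, lt=1)
    alpha: float = Field(gt=0, lt=1)
    feature_spec: FeatureSpecReport
    classifier: ClassifierReport
    days: list[DayReport]
    mean_accuracy: float = Field(ge=0, le=1)
    n_significant_days: int = Field(ge=0)


class ChanceEntry(BaseModel):
    label: str
    k: int = Field(ge=0)
    n: int = Field(ge=1)
    chance: float = Field(gt=0, lt=1)
    accuracy: float = Field(ge=0, le=1)
    p_value: float = Field(ge=0, le=1)
    significant: bool
    ci: list[float]


class ChanceReport(BaseModel):
    schema_version: int
    alpha: float = Field(gt=0, lt=1)
    entries: list[ChanceEntry]


class RunManifest(BaseModel):
    schema_version: int
    package_version: str
    input: dict
    stages: list[str]
    seeds: dict[str, int]
    reports: dict[str, str]
    figures: dict[str, str]


STAGE_MODELS: dict[str, type[BaseModel]] = {
    "avgstats": AvgStatsReport,
    "permcheck": PermCheckReport,
    "classify": ClassifyReport,
    "chance": ChanceReport,
    "run_manifest": RunManifest,
}

SCHEMA_DIR = Path(__file__).parent / "schemas"


def validate_report(stage: str, payload: dict) -> dict:
    """Validate a report dict against its stage schema; returns the dict."""
    model = STAGE_MODELS.get(stage)
    if model is None:
        raise ValueError(f"no schema for stage {stage!r}")
    model.model_validate(payload)
    return payload


def export_schemas(out_dir: Path = SCHEMA_DIR) -> list[Path]:
    """Write the JSON Schema documents shipped with the package."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for stage, model in STAGE_MODELS.items():
        path = out_dir / f"{stage}.schema.json"
        path.write_text(json.dumps(model.model_json_schema(), indent=1, sort_keys=True))
        written.append(path)
    return written


if __name__ == "__main__":
    for p in export_schemas():
        print(p)
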