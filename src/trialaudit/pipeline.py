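"""End-to-end reanalysis pipeline with machine-readable reports.

A :class:`PipelineConfig` names the input (a dataset directory or a synthetic
preset + seed), the stages to run, and per-stage parameters; ``run_pipeline``
writes one validated JSON report per stage, optional figures, and a run
manifest recording every seed, so a rerun with the same config is
byte-identical.  Timings and warnings go to the stderr logger, never into
the reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path
from typing import Any

import yaml

from . import averaging, classify, permutation, simulate
from .chance import accuracy_binomial_test
from .data import TrialDataset, read_dataset
from .plotting import render_comparison_figure
from .report_schemas import validate_report

log = logging.getLogger("trialaudit")

STAGES = ("avgstats", "permcheck", "classify", "chance")


@dataclass
class PipelineConfig:
    """Input source, stage list and per-stage parameter blocks."""

    out_dir: Path
    dataset_dir: Path | None = None
    preset: str | None = None
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    avgstats: dict[str, Any] = field(default_factory=dict)
    permcheck: dict[str, Any] = field(default_factory=dict)
    classify: dict[str, Any] = field(default_factory=dict)
    chance: dict[str, Any] = field(default_factory=dict)
    figures: bool = True

    def validate(self) -> None:
        if (self.dataset_dir is None) == (self.preset is None):
            raise ValueError("exactly one of dataset_dir or preset must be given")
        if not self.stages:
            raise ValueError("at least one stage is required")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}; available: {STAGES}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        kwargs: dict[str, Any] = {}
        for key in ("out_dir", "dataset_dir"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        for key in ("preset", "seed", "figures", "avgstats", "permcheck", "classify", "chance"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        return cls(**kwargs)


def _load_input(config: PipelineConfig) -> TrialDataset:
    if config.dataset_dir is not None:
        return read_dataset(Path(config.dataset_dir) / "manifest.json")
    return simulate.generate_dataset(simulate.preset(config.preset, seed=config.seed))


def _write_report(out_dir: Path, stage: str, payload: dict) -> Path:
    validate_report(stage, payload)
    path = out_dir / f"{stage}.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the configured stages; return {stage: report path}.

    A stage failure halts the pipeline after writing the manifest for the
    stages that completed.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, Path] = {}
    figures: dict[str, Path] = {}
    seeds: dict[str, int] = {"input": config.seed}
    dataset = _load_input(config)
    log.info("input: %s (%d day(s), %d channels, %d timepoints)",
             config.preset or config.dataset_dir, len(dataset.days),
             dataset.n_channels, dataset.n_timepoints)
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            if stage == "avgstats":
                params = config.avgstats
                res = averaging.compare_methods(
                    dataset,
                    alpha=params.get("alpha", 0.05),
                    correction=params.get("correction", "none"),
                )
                reports[stage] = _write_report(out_dir, stage, res.to_dict())
                if config.figures:
                    figures[stage] = Path(
                        render_comparison_figure(res, out_dir / "avgstats_comparison.png")
                    )
            elif stage == "permcheck":
                params = config.permcheck
                seeds[stage] = int(params.get("seed", config.seed))
                res = permutation.audit(
                    dataset,
                    averaging.AveragingSpec.from_label(params.get("method", "A-flawed")),
                    n_perm=int(params.get("n_perm", 10)),
                    audit_alpha=float(params.get("audit_alpha", 0.0005)),
                    seed=seeds[stage],
                    scope=params.get("scope", "session"),
                )
                reports[stage] = _write_report(out_dir, stage, res.to_dict())
            elif stage == "classify":
                params = config.classify
                seeds[stage] = int(params.get("seed", config.seed))
                fspec = classify.FeatureSpec(
                    representation=params.get("features", "window_mean"),
                    baseline_window_s=tuple(params.get("baseline", (-5.0, 0.0))),
                    response_window_s=tuple(params.get("response", (2.0, 8.0))),
                    baseline_correct=bool(params.get("baseline_correct", True)),
                )
                cfg = classify.ClassifierConfig(
                    c_grid=tuple(params.get("c_grid", classify.ClassifierConfig().c_grid)),
                    outer_folds=int(params.get("outer_folds", 10)),
                    inner_folds=int(params.get("inner_folds", 10)),
                    seed=seeds[stage],
                )
                res = classify.run_offline_reanalysis(
                    dataset, fspec, cfg,
                    chance=float(params.get("chance", 0.5)),
                    alpha=float(params.get("alpha", 0.05)),
                )
                reports[stage] = _write_report(out_dir, stage, res.to_dict())
            elif stage == "chance":
                params = config.chance
                alpha = float(params.get("alpha", 0.05))
                entries = list(params.get("entries", []))
                if not entries and "classify" in reports:
                    payload = json.loads(reports["classify"].read_text())
                    entries = [
                        {"label": d["day_id"], "k": d["k"], "n": d["n"],
                         "chance": payload["chance"]}
                        for d in payload["days"]
                    ]
                if not entries:
                    raise ValueError(
                        "chance stage needs explicit entries (label,k,n[,chance]) or a "
                        "preceding classify stage"
                    )
                rows = []
                for e in entries:
                    r = accuracy_binomial_test(
                        int(e["k"]), int(e["n"]), chance=float(e.get("chance", 0.5)), alpha=alpha
                    )
                    rows.append(
                        {"label": str(e["label"]), "k": r.k, "n": r.n, "chance": r.chance,
                         "accuracy": r.accuracy, "p_value": r.p_value,
                         "significant": r.significant, "ci": list(r.ci)}
                    )
                reports[stage] = _write_report(
                    out_dir, stage,
                    {"schema_version": 1, "alpha": alpha, "entries": rows},
                )
            log.info("stage %s done in %.2f s -> %s", stage, time.perf_counter() - t0,
                     reports.get(stage))
    finally:
        manifest = {
            "schema_version": 1,
            "package_version": pkg_version("trialaudit"),
            "input": {
                "preset": config.preset,
                "dataset_dir": str(config.dataset_dir) if config.dataset_dir else None,
            },
            "stages": [s for s in config.stages if s in reports],
            "seeds": seeds,
            "reports": {s: p.name for s, p in reports.items()},
            "figures": {s: p.name for s, p in figures.items()},
        }
        _write_report(out_dir, "run_manifest", manifest)
    return reports
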