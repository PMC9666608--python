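"""End-to-end orchestration: simulate -> clean -> featurize -> screen ->
seed -> search -> evaluate -> report.

A run is fully reproducible from its :class:`RunConfig` (which embeds the
cohort design and one global seed); the global seed fans out to
independent per-stage child seeds so any stage can be re-run in
isolation.  Every stage's output is persisted as plain text (CSV/JSON)
under the run directory, and every number in the final report is
re-derivable from those intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import MODEL_NAMES, CVSpec, EvalResult, make_folds, make_models
from .features import FEATURE_NAMES, FeatureOptions, extract_feature_tables
from .selection import (
    Pattern,
    ScreeningGrid,
    greedy_pattern_search,
    preliminary_screen,
    seed_pattern,
)
from .synthetic import BAND_NAMES, CohortSpec, ERPRecord, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_cohort"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one full analysis run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    features: FeatureOptions = field(default_factory=FeatureOptions)
    cv: CVSpec = field(default_factory=CVSpec)
    models: tuple[str, ...] = MODEL_NAMES
    selection_threshold: float = 50.0
    artifact_threshold_uv: float = 100.0
    search_max_iter: int = 50
    tie_tolerance: float = 0.0
    dl_width: int = 16
    dl_max_iter: int = 200
    seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        unknown = [m for m in self.models if m not in MODEL_NAMES]
        if unknown:
            raise ValueError(f"unknown model name(s) {unknown}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for k in ("electrodes", "modalities"):
                if k in c:
                    c[k] = tuple(c[k])
            d["cohort"] = CohortSpec(**c)
        if "features" in d and isinstance(d["features"], dict):
            d["features"] = FeatureOptions(**d["features"])
        if "cv" in d and isinstance(d["cv"], dict):
            d["cv"] = CVSpec(**d["cv"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def write_cohort(records: list[ERPRecord], out_dir: Path) -> None:
    """Persist a cohort: one metadata CSV + packed per-record signals."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    signals = {}
    for i, rec in enumerate(records):
        key = f"{rec.subject_id}_{rec.modality}_{rec.electrode}"
        meta_rows.append(
            {
                "record": key,
                "subject_id": rec.subject_id,
                "group": rec.group_label,
                "modality": rec.modality,
                "electrode": rec.electrode,
                "sampling_rate": rec.sampling_rate,
                "gender": rec.gender,
                "first_child": int(rec.first_child),
            }
        )
        signals[key] = rec.signal.astype(np.float32)
    pd.DataFrame(meta_rows).to_csv(out_dir / "cohort_metadata.csv", index=False)
    np.savez_compressed(out_dir / "signals.npz", **signals)


def read_cohort(in_dir: Path | str) -> list[ERPRecord]:
    """Rebuild a cohort persisted by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "cohort_metadata.csv")
    with np.load(in_dir / "signals.npz") as signals:
        return [
            ERPRecord(
                subject_id=row.subject_id,
                group_label=row.group,
                modality=row.modality,
                electrode=row.electrode,
                sampling_rate=float(row.sampling_rate),
                signal=signals[row.record].astype(float),
                gender=row.gender,
                first_child=bool(row.first_child),
            )
            for row in meta.itertuples()
        ]


@dataclass
class PipelineResult:
    """In-memory handle on a completed run."""

    config: RunConfig
    tables: dict[str, pd.DataFrame]
    grid: ScreeningGrid
    seeds: dict[tuple[str, str], Pattern]
    patterns: dict[tuple[str, str], Pattern]
    results: dict[tuple[str, str], EvalResult]
    out_dir: Path | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for (model, band), res in self.results.items():
            m = res.metrics
            rows.append(
                {
                    "model": model,
                    "band": band,
                    "pattern": ", ".join(res.features),
                    "n_features": len(res.features),
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "classification_error": m.classification_error,
                    "auc": res.auc,
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig, out_dir: Path | str | None = None, write_signals: bool = False
) -> PipelineResult:
    """Execute every stage on one synthetic cohort and (optionally)
    persist all intermediates under ``out_dir``."""
    config.validate()
    cohort_seed, cv_seed, model_seed = _child_seeds(config.seed, 3)

    spec = dataclasses.replace(config.cohort, seed=cohort_seed)
    logger.info("simulating cohort: %d subjects", 2 * spec.n_per_group)
    records = generate_cohort(spec)

    logger.info("extracting feature tables (%d records)", len(records))
    tables = extract_feature_tables(
        records,
        options=config.features,
        artifact_threshold_uv=config.artifact_threshold_uv,
    )

    cv_spec = dataclasses.replace(config.cv, seed=cv_seed)
    models = make_models(
        seed=model_seed,
        names=config.models,
        dl_width=config.dl_width,
        dl_max_iter=config.dl_max_iter,
    )

    logger.info("screening %d x %d x %d grid", len(FEATURE_NAMES), len(models), 4)
    grid = preliminary_screen(tables, models, cv_spec)

    seeds: dict[tuple[str, str], Pattern] = {}
    patterns: dict[tuple[str, str], Pattern] = {}
    results: dict[tuple[str, str], EvalResult] = {}
    for band in BAND_NAMES:
        table = tables[band]
        folds = make_folds(
            table["group"].to_numpy(), table["subject_id"].to_numpy(), cv_spec
        )
        for model_name in config.models:
            seeded = seed_pattern(grid, model_name, band, config.selection_threshold)
            seeds[(model_name, band)] = seeded
            pattern, result, _trace = greedy_pattern_search(
                models[model_name],
                table,
                seeded,
                cv_spec,
                folds=folds,
                max_iter=config.search_max_iter,
                tie_tolerance=config.tie_tolerance,
            )
            patterns[(model_name, band)] = pattern
            results[(model_name, band)] = result
            logger.info(
                "searched %s/%s: %d features, accuracy %.2f%%",
                model_name,
                band,
                len(pattern.features),
                result.metrics.accuracy,
            )

    out = PipelineResult(
        config=config,
        tables=tables,
        grid=grid,
        seeds=seeds,
        patterns=patterns,
        results=results,
    )
    if out_dir is not None:
        out.out_dir = Path(out_dir)
        _write_outputs(out, records, write_signals)
    return out


def _write_outputs(
    result: PipelineResult, records: list[ERPRecord], write_signals: bool
) -> None:
    out_dir = result.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    if write_signals:
        write_cohort(records, out_dir / "cohort")
    else:
        meta = pd.DataFrame(
            sorted(
                {
                    (r.subject_id, r.group_label, r.gender, int(r.first_child))
                    for r in records
                }
            ),
            columns=["subject_id", "group", "gender", "first_child"],
        )
        meta.to_csv(out_dir / "cohort_metadata.csv", index=False)
    for band, table in result.tables.items():
        table.to_csv(out_dir / f"features_{band}.csv", index=False)
    result.grid.table.to_csv(out_dir / "screening_grid.csv", index=False)
    for band in BAND_NAMES:
        result.grid.wide(band).to_csv(out_dir / f"screening_grid_{band}.csv")
    result.summary().to_csv(out_dir / "results.csv", index=False)
    roc_rows = []
    for (model, band), res in result.results.items():
        for fpr, tpr in res.roc_points:
            roc_rows.append({"model": model, "band": band, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(roc_rows).to_csv(out_dir / "roc_points.csv", index=False)
    manifest = {
        "config": result.config.to_dict(),
        "n_records": int(sum(len(t) for t in result.tables.values()) // 4),
        "n_grid_cells": int(result.grid.n_cells),
        "n_patterns": len(result.patterns),
        "seeded_patterns": {
            f"{m}/{b}": list(p.features) for (m, b), p in result.seeds.items()
        },
        "searched_patterns": {
            f"{m}/{b}": list(p.features) for (m, b), p in result.patterns.items()
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
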