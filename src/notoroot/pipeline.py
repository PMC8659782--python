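"""End-to-end orchestration: synthesize/ingest -> preprocess -> extract ->
select -> tune -> train -> evaluate.

Every stochastic stage consumes a stage-specific sub-seed derived from the
master seed by a fixed CRC32 hash of ``"{master}:{stage}"``, so adding or
removing a stage never perturbs the randomness of the others and a run is
byte-reproducible from its config.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import (
    BpConfig,
    evaluate,
    split_features,
    stratified_split,
    train_bp,
    train_elm,
    train_svm,
)
from .exceptions import InputError, SpecError, StageError
from .features import (
    ALL_FEATURE_NAMES,
    FUSION_SUBSETS,
    ExtractionConfig,
    extract_feature_table,
    read_feature_csv,
)
from .optimizers import TuneConfig, tune_svm
from .preprocessing import PreprocessConfig
from .selection import select_features
from .synthetic import SyntheticImageSpec, generate_image_dataset

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "compare_fusions", "stage_seed"]

logger = logging.getLogger("notoroot.pipeline")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    return zlib.crc32(f"{master}:{stage}".encode()) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """One end-to-end run.

    ``source`` is ``"synthetic"`` (render a balanced image set) or a path to
    a feature CSV. ``fusion`` picks the feature column group:
    shape (9), shape+texture (16), shape+color (33), or all (40).
    """

    source: str = "synthetic"
    n_per_grade: int = 100
    image_spec: SyntheticImageSpec = field(default_factory=SyntheticImageSpec)
    fusion: str = "all"
    selection: str = "none"  # none | iriv | vissa | sra
    classifier: str = "svm"  # svm | elm | bp
    tuner: str = "none"  # none | gwo | ga | pso
    split_fraction: float = 0.7
    svm_c: float = 1.0
    svm_g: float | None = None  # None: 1 / n_features
    seed: int = 0
    out_dir: str | None = None
    # synthetic images are already small; keep native resolution by default
    extraction: ExtractionConfig = field(
        default_factory=lambda: ExtractionConfig(
            preprocess=PreprocessConfig(resize_to=None)
        )
    )
    tune: TuneConfig = field(default_factory=TuneConfig)

    def __post_init__(self) -> None:
        if self.fusion not in FUSION_SUBSETS:
            raise SpecError(f"unknown fusion subset {self.fusion!r}")
        if self.selection not in ("none", "iriv", "vissa", "sra"):
            raise SpecError(f"unknown selection method {self.selection!r}")
        if self.classifier not in ("svm", "elm", "bp"):
            raise SpecError(f"unknown classifier {self.classifier!r}")
        if self.tuner not in ("none", "gwo", "ga", "pso"):
            raise SpecError(f"unknown tuner {self.tuner!r}")


@dataclass
class RunReport:
    """Everything a finished run produced (timings excluded from identity)."""

    config: dict
    n_features_before: int
    n_features_after: int
    selected: list[str]
    tuned_c: float | None
    tuned_g: float | None
    train_report: dict
    test_report: dict
    timings_s: dict
    version: str = __version__

    def to_dict(self, include_timings: bool = True) -> dict:
        out = {
            "config": self.config,
            "n_features_before": self.n_features_before,
            "n_features_after": self.n_features_after,
            "selected": self.selected,
            "tuned_c": self.tuned_c,
            "tuned_g": self.tuned_g,
            "train_report": self.train_report,
            "test_report": self.test_report,
            "version": self.version,
        }
        if include_timings:
            out["timings_s"] = self.timings_s
        return out

    def to_json(self, include_timings: bool = True) -> str:
        return json.dumps(self.to_dict(include_timings), indent=2, sort_keys=True)


def _config_echo(cfg: PipelineConfig) -> dict:
    return {
        "source": cfg.source,
        "n_per_grade": cfg.n_per_grade,
        "fusion": cfg.fusion,
        "selection": cfg.selection,
        "classifier": cfg.classifier,
        "tuner": cfg.tuner,
        "split_fraction": cfg.split_fraction,
        "seed": cfg.seed,
    }


def _load_table(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.source == "synthetic":
        records = generate_image_dataset(
            cfg.image_spec, cfg.n_per_grade, stage_seed(cfg.seed, "synth")
        )
        return extract_feature_table(records, config=cfg.extraction)
    return read_feature_csv(cfg.source)


def _run_stage(name: str, fn, *args, **kwargs):
    logger.info("stage %s: start", name)
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # annotate with the failing stage
        raise StageError(name, exc) from exc
    dt = time.perf_counter() - t0
    logger.info("stage %s: done in %.2f s", name, dt)
    return out, dt


def _train_and_eval(cfg, train, test, columns, c, g):
    Xtr, ytr = split_features(train[columns + ["grade"]])
    Xte, yte = split_features(test[columns + ["grade"]])
    if cfg.classifier == "svm":
        model = train_svm(Xtr, ytr, c=c, g=g if g is not None else 1.0 / Xtr.shape[1])
    elif cfg.classifier == "elm":
        model = train_elm(Xtr, ytr, seed=stage_seed(cfg.seed, "elm"))
    else:
        model = train_bp(Xtr, ytr, BpConfig(), seed=stage_seed(cfg.seed, "bp"))
    return model, evaluate(model, Xtr, ytr), evaluate(model, Xte, yte)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every configured stage in order and return the run report."""
    cfg = config
    timings: dict[str, float] = {}

    table, timings["extract"] = _run_stage("extract", _load_table, cfg)
    columns = [c for c in FUSION_SUBSETS[cfg.fusion] if c in table.columns]
    if cfg.source != "synthetic" and not columns:
        # CSV tables (e.g. planted fixtures) may not use the canonical names
        columns = [c for c in table.columns if c != "grade"]
    if not columns:
        raise StageError("fusion", InputError("no feature columns to use"))
    n_before = len(columns)
    table = table[columns + ["grade"]]

    (train, test), timings["split"] = _run_stage(
        "split", stratified_split, table, cfg.split_fraction,
        stage_seed(cfg.seed, "split"),
    )

    selected = list(columns)
    if cfg.selection != "none":
        sel, timings["select"] = _run_stage(
            "select", select_features, train, cfg.selection,
            stage_seed(cfg.seed, "select"),
        )
        if sel.selected:
            selected = sel.selected

    tuned_c = tuned_g = None
    c, g = cfg.svm_c, cfg.svm_g
    if cfg.tuner != "none":
        if cfg.classifier != "svm":
            raise StageError("tune", InputError("tuning is defined for the SVM only"))
        opt, timings["tune"] = _run_stage(
            "tune", tune_svm, train[selected + ["grade"]], cfg.tuner, cfg.tune,
            stage_seed(cfg.seed, "tune"),
        )
        tuned_c, tuned_g = opt.best_c, opt.best_g
        c, g = tuned_c, tuned_g

    (model, train_rep, test_rep), timings["train"] = _run_stage(
        "train", _train_and_eval, cfg, train, test, selected, c, g
    )

    report = RunReport(
        config=_config_echo(cfg),
        n_features_before=n_before,
        n_features_after=len(selected),
        selected=selected,
        tuned_c=tuned_c,
        tuned_g=tuned_g,
        train_report=train_rep.to_dict(),
        test_report=test_rep.to_dict(),
        timings_s=timings,
    )
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_report.json").write_text(report.to_json())
    return report


def compare_fusions(config: PipelineConfig, subsets: list[str]) -> pd.DataFrame:
    """Evaluate several fusion subsets on one shared seeded split.

    Every subset sees identical train/test membership, so accuracy differences
    are attributable to the feature groups alone.
    """
    if len(subsets) < 1:
        raise InputError("need at least one subset")
    for s in subsets:
        if s not in FUSION_SUBSETS:
            raise InputError(f"unknown fusion subset {s!r}")
    cfg = config
    table, _ = _run_stage("extract", _load_table, cfg)
    train, test = stratified_split(
        table, cfg.split_fraction, stage_seed(cfg.seed, "split")
    )
    rows = []
    for subset in subsets:
        columns = [c for c in FUSION_SUBSETS[subset] if c in table.columns]
        _, train_rep, test_rep = _train_and_eval(
            cfg, train, test, columns, cfg.svm_c, cfg.svm_g
        )
        rows.append(
            {
                "fusion": subset,
                "n_features": len(columns),
                "train_accuracy_pct": train_rep.accuracy_pct,
                "test_accuracy_pct": test_rep.accuracy_pct,
            }
        )
    return pd.DataFrame(rows)
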