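"""End-to-end pipeline: crop -> preprocess -> select -> train -> evaluate.

A single :class:`PipelineConfig` names one preprocessing method, one
selection method, and one classifier, plus the seed; :func:`run_pipeline`
executes the stages, writes all artifacts (selection report, model file,
metrics report, run manifest) and returns the evaluation report. Rerunning
with the same manifest reproduces all numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from ovotrace.classify import (
    RFConfig,
    SVMConfig,
    TrainConfig,
    predict,
    save_classifier,
    train_cnn,
    train_rf,
    train_svm,
)
from ovotrace.core import (
    DEFAULT_WINDOW,
    SpectraTable,
    WavelengthWindow,
    crop_wavelengths,
    read_spectra,
)
from ovotrace.errors import OvotraceError, ParameterError
from ovotrace.metrics import ClassReport, class_report, confusion, format_report
from ovotrace.preprocess import MSCReference, SGParams, msc, savitzky_golay, snv
from ovotrace.selection import cars_select, spa_select
from ovotrace.synthetic import GeneratorConfig, make_benchmark

log = logging.getLogger("ovotrace")

PREPROCESS_METHODS = ("snv", "msc", "sg", "none")
SELECT_METHODS = ("spa", "cars", "none")
MODELS = ("rf", "svm", "cnn")


@dataclass
class PipelineConfig:
    """One full run: method names, their parameters, paths, and the seed."""

    preprocess: str = "snv"
    sg_window: int = 11
    sg_polyorder: int = 2
    sg_deriv: int = 0
    select: str = "spa"
    max_vars: int = 15
    n_runs: int = 100
    cv_folds: int = 10
    model: str = "cnn"
    epochs: int = 300
    learning_rate: float = 1e-4
    batch_size: int = 4
    window_low_nm: float = DEFAULT_WINDOW.low_nm
    window_high_nm: float = DEFAULT_WINDOW.high_nm
    seed: int = 0
    train_path: str | None = None
    test_path: str | None = None
    output_dir: str = "ovotrace_run"
    noise_sd: float | None = None  # synthetic benchmark noise override

    def __post_init__(self) -> None:
        if self.preprocess not in PREPROCESS_METHODS:
            raise ParameterError(
                f"unknown preprocessing {self.preprocess!r}; "
                f"choose from {PREPROCESS_METHODS}"
            )
        if self.select not in SELECT_METHODS:
            raise ParameterError(
                f"unknown selection {self.select!r}; choose from {SELECT_METHODS}"
            )
        if self.model not in MODELS:
            raise ParameterError(
                f"unknown model {self.model!r}; choose from {MODELS}"
            )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _load_tables(cfg: PipelineConfig) -> tuple[SpectraTable, SpectraTable]:
    if cfg.train_path and cfg.test_path:
        return read_spectra(cfg.train_path), read_spectra(cfg.test_path)
    if cfg.train_path or cfg.test_path:
        raise ParameterError("train_path and test_path must be given together")
    gen = GeneratorConfig(seed=cfg.seed) if cfg.noise_sd is None else GeneratorConfig(
        seed=cfg.seed, noise_sd=cfg.noise_sd
    )
    train, test, _ = make_benchmark(gen)
    return train, test


def _preprocess(
    cfg: PipelineConfig, train: SpectraTable, test: SpectraTable
) -> tuple[SpectraTable, SpectraTable]:
    if cfg.preprocess == "snv":
        return snv(train), snv(test)
    if cfg.preprocess == "msc":
        ref = MSCReference.from_table(train)  # fitted on training only
        return msc(train, ref), msc(test, ref)
    if cfg.preprocess == "sg":
        params = SGParams(cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
        return savitzky_golay(train, params), savitzky_golay(test, params)
    return train, test


def _select(cfg: PipelineConfig, train: SpectraTable) -> tuple[list[int], dict]:
    if cfg.select == "spa":
        res = spa_select(train, max_vars=cfg.max_vars, cv_folds=cfg.cv_folds,
                         seed=cfg.seed)
        report = {
            "method": "spa",
            "selected_indices": res.selected_indices,
            "selected_wavelengths_nm": res.selected_wavelengths_nm.tolist(),
            "rmse_by_size": {str(k): v for k, v in res.rmse_by_size.items()},
            "chosen_size": res.chosen_size,
        }
        return res.selected_indices, report
    if cfg.select == "cars":
        res = cars_select(train, n_runs=cfg.n_runs, cv_folds=cfg.cv_folds,
                          seed=cfg.seed)
        report = {
            "method": "cars",
            "selected_indices": res.selected_indices,
            "selected_wavelengths_nm": train.wavelengths_nm[
                np.array(res.selected_indices)
            ].tolist(),
            "rmsecv_by_run": res.rmsecv_by_run.tolist(),
            "best_run": res.best_run,
            "retained_counts": res.retained_counts,
        }
        return res.selected_indices, report
    idx = list(range(train.n_wavelengths))
    return idx, {"method": "none", "selected_indices": idx}


def _train(cfg: PipelineConfig, train: SpectraTable):
    if cfg.model == "rf":
        return train_rf(train, RFConfig(), seed=cfg.seed)
    if cfg.model == "svm":
        return train_svm(train, SVMConfig())
    tc = TrainConfig(
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.epochs,
        seed=cfg.seed,
    )
    return train_cnn(train, cfg=tc)


@dataclass
class PipelineResult:
    report: ClassReport
    selected_indices: list[int]
    output_dir: Path
    manifest: dict[str, Any] = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write artifacts to ``cfg.output_dir``."""
    t0 = time.perf_counter()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = cfg.config_hash()
    timings: dict[str, float] = {}

    def tic(stage: str) -> None:
        timings[stage] = time.perf_counter() - t0

    try:
        train, test = _load_tables(cfg)
        tic("load")
        window = WavelengthWindow(cfg.window_low_nm, cfg.window_high_nm)
        train, test = crop_wavelengths(train, window), crop_wavelengths(test, window)
        tic("crop")
        train, test = _preprocess(cfg, train, test)
        tic("preprocess")
        selected, sel_report = _select(cfg, train)
        log.info("selected %d variables with %s", len(selected), cfg.select)
        tic("select")
        train_sel = train.subset_columns(selected)
        test_sel = test.subset_columns(selected)
        clf = _train(cfg, train_sel)
        tic("train")
        y_pred = predict(clf, test_sel)
        assert test_sel.y is not None
        report = class_report(confusion(test_sel.y, y_pred))
        tic("evaluate")
    except OvotraceError as exc:
        raise type(exc)(f"pipeline stage failed: {exc}") from exc

    sel_report["seed"] = cfg.seed
    sel_report["config_hash"] = tag
    (out / f"selection_{tag}.json").write_text(json.dumps(sel_report, indent=2))
    save_classifier(clf, out / f"model_{tag}_seed{cfg.seed}.pkl")
    metrics = {
        "config_hash": tag,
        "seed": cfg.seed,
        "n_selected": len(selected),
        "accuracy": report.accuracy,
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
        "error": report.error,
        "support": report.support,
    }
    (out / f"metrics_{tag}.json").write_text(json.dumps(metrics, indent=2))
    manifest = {
        "config": asdict(cfg),
        "config_hash": tag,
        "seed": cfg.seed,
        "n_selected": len(selected),
        "timings_s": timings,
        "versions": {"numpy": np.__version__},
    }
    (out / f"manifest_{tag}.json").write_text(json.dumps(manifest, indent=2))
    log.info("run %s complete:\n%s", tag, format_report(report))
    return PipelineResult(
        report=report,
        selected_indices=list(selected),
        output_dir=out,
        manifest=manifest,
    )
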