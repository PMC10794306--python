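"""One-command orchestration of the full analysis.

simulate -> preprocess -> extract-tda -> stats -> project -> evaluate,
with a YAML config, per-stage resume, sidecar JSONs and a reproducibility
manifest. All stage seeds derive deterministically from ``master_seed``,
so any stage can be re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import chance_level, classify_loso, regress_loso
from .io import read_epochs, read_study, write_epochs, write_study
from .plotting import feature_boxplots, metric_boxplots, projection_scatter
from .preprocess import preprocess_recording
from .projection import project
from .stats import CONDITIONS, compare_all
from .synthetic import ConfigurationError, StudyConfig, generate_study
from .tda import feature_table

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "extract-tda", "stats", "project",
          "evaluate")

_DEFAULTS = {
    "preprocess": {"low_hz": 1.0, "high_hz": 40.0, "epoch_length_s": 2.0,
                   "threshold_uv": 100.0, "cue_as_target": True},
    "tda": {"zscore": False},
    "stats": {"aggregate": "epoch"},
    "projection": {"methods": ["umap"], "conditions": ["ALL"]},
    "evaluation": {"n_trees": 200, "conditions": list(CONDITIONS),
                   "per_subject_vote": False},
}


class PipelineConfig:
    """Validated nested configuration.

    Defaults are the analysis conventions: 1-40 Hz band, 2-s epochs,
    250 Hz sampling, 100 uV EMD threshold, 200 trees, 8 channels,
    8 sessions.
    """

    def __init__(self, mapping: dict | None = None, out_dir="pipeline_out",
                 master_seed: int = 0):
        mapping = dict(mapping or {})
        self.out_dir = Path(mapping.pop("out_dir", out_dir))
        self.master_seed = int(mapping.pop("master_seed", master_seed))
        study_cfg = dict(mapping.pop("study", {}))
        study_cfg.setdefault("master_seed", self.master_seed)
        try:
            self.study = StudyConfig(**study_cfg)
        except TypeError as exc:
            raise ConfigurationError(f"bad study section: {exc}") from exc
        for section, defaults in _DEFAULTS.items():
            given = dict(mapping.pop(section, {}))
            unknown = set(given) - set(defaults)
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in [{section}]: {sorted(unknown)}")
            setattr(self, section.replace("-", "_"),
                    {**defaults, **given})
        if mapping:
            raise ConfigurationError(f"unknown config sections: "
                                     f"{sorted(mapping)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(data)

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the master seed."""
        ss = np.random.SeedSequence(
            [self.master_seed, STAGES.index(stage) + 1])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "master_seed": self.master_seed,
            "study": dataclasses.asdict(self.study),
            "preprocess": self.preprocess,
            "tda": self.tda,
            "stats": self.stats,
            "projection": self.projection,
            "evaluation": self.evaluation,
        }


def _write_manifest(config: PipelineConfig, completed: list):
    manifest = {
        "eegtda_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "completed_stages": completed,
    }
    (config.out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2))


def _stage_done(config: PipelineConfig, stage: str) -> bool:
    marker = {
        "simulate": config.out_dir / "study" / "participants.csv",
        "preprocess": config.out_dir / "epochs" / ".complete",
        "extract-tda": config.out_dir / "features.csv",
        "stats": config.out_dir / "stats.csv",
        "project": config.out_dir / "projections" / ".complete",
        "evaluate": config.out_dir / "metrics.json",
    }[stage]
    return marker.exists()


def run_pipeline(config: PipelineConfig, stages=STAGES,
                 resume: bool = True) -> Path:
    """Run the requested stages; skips already-completed ones on resume."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    completed = []
    for stage in STAGES:
        if stage not in stages:
            continue
        if resume and _stage_done(config, stage):
            logger.info("stage %s already complete; skipping", stage)
            completed.append(stage)
            continue
        logger.info("running stage %s", stage)
        _RUNNERS[stage](config)
        completed.append(stage)
        _write_manifest(config, completed)
    return config.out_dir


def _run_simulate(config: PipelineConfig):
    study = generate_study(config.study)
    write_study(study, config.out_dir / "study")


def _run_preprocess(config: PipelineConfig):
    study = read_study(config.out_dir / "study")
    out = config.out_dir / "epochs"
    for _, rec in study:
        es = preprocess_recording(rec, **config.preprocess)
        write_epochs(es, out, params=dict(config.preprocess))
    (out / ".complete").write_text("")


def _iter_epoch_sets(config: PipelineConfig):
    participants = pd.read_csv(config.out_dir / "study" / "participants.csv")
    for sid in participants["subject_id"]:
        yield read_epochs(config.out_dir / "epochs", sid)


def _run_extract_tda(config: PipelineConfig):
    table = feature_table(_iter_epoch_sets(config),
                          zscore=config.tda["zscore"])
    table.to_csv(config.out_dir / "features.csv", index=False)


def _features(config: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(config.out_dir / "features.csv")


def _run_stats(config: PipelineConfig):
    features = _features(config)
    stats = compare_all(features, aggregate=config.stats["aggregate"])
    stats.to_csv(config.out_dir / "stats.csv", index=False)
    feature_boxplots(features, stats,
                     path=config.out_dir / "feature_boxplots.png")


def _run_project(config: PipelineConfig):
    features = _features(config)
    out = config.out_dir / "projections"
    out.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seed("project")
    for method in config.projection["methods"]:
        for condition in config.projection["conditions"]:
            proj = project(features, method=method, condition=condition,
                           seed=seed)
            df = pd.DataFrame(proj.coordinates, columns=["x", "y"])
            df = pd.concat([proj.labels, df], axis=1)
            stem = f"{method}_{condition}"
            df.to_csv(out / f"{stem}.csv", index=False)
            projection_scatter(proj, path=out / f"{stem}.png")
    (out / ".complete").write_text("")


def _run_evaluate(config: PipelineConfig):
    features = _features(config)
    seed = config.stage_seed("evaluate")
    n_trees = config.evaluation["n_trees"]
    subject_labels = features.drop_duplicates("subject_id")["group"]
    panels = {"chance_level_percent": chance_level(subject_labels)}
    fold_rows = []
    cls_folds, reg_folds = {}, {}
    for condition in config.evaluation["conditions"]:
        cpanel, cfolds = classify_loso(
            features, condition=condition, n_trees=n_trees, seed=seed,
            per_subject_vote=config.evaluation["per_subject_vote"])
        rpanel, rfolds = regress_loso(
            features, condition=condition, n_trees=n_trees, seed=seed)
        cls_folds[condition] = cfolds
        reg_folds[condition] = rfolds
        panels[condition] = {
            "classification": {"median": cpanel.median,
                               "interval": cpanel.interval,
                               "pooled": cpanel.pooled},
            "regression": {"median": rpanel.median,
                           "interval": rpanel.interval,
                           "pooled": rpanel.pooled},
        }
        for kind, folds in (("classification", cfolds), ("regression", rfolds)):
            for f in folds:
                fold_rows.append({"condition": condition, "task": kind,
                                  "subject_id": f.held_out_subject,
                                  **f.metrics})
    (config.out_dir / "metrics.json").write_text(json.dumps(panels, indent=2))
    pd.DataFrame(fold_rows).to_csv(config.out_dir / "folds.csv", index=False)
    metric_boxplots(cls_folds, ["accuracy", "f1"],
                    path=config.out_dir / "classification_folds.png",
                    chance=panels["chance_level_percent"])
    metric_boxplots(reg_folds, ["median_error", "mape", "mae", "mse"],
                    path=config.out_dir / "regression_folds.png")


_RUNNERS = {
    "simulate": _run_simulate,
    "preprocess": _run_preprocess,
    "extract-tda": _run_extract_tda,
    "stats": _run_stats,
    "project": _run_project,
    "evaluate": _run_evaluate,
}
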