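"""End-to-end run orchestration: config resolution, execution, artifacts.

A run loads (or synthesizes) epochs, applies the preprocessing chain, and
hands off to the cross-validated pipeline evaluator.  The output directory
always contains the resolved config, the seed, and the report JSON, which
is sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .branches import EEGCNNConfig, TFCNNConfig, TrainConfig
from .data import EEGEpochSet
from .evaluate import EvalReport, PipelineConfig, five_fold_cv
from .fusion import SVMConfig
from .io import load_epochs
from .preprocess import PreprocConfig, preprocess
from .synth import SynthConfig, generate_mi_dataset
from .tfmap import CWTConfig

__all__ = ["RunConfig", "run", "desk_profile", "load_run_config",
           "dump_run_config"]

log = logging.getLogger("eegfusion")


@dataclass
class RunConfig:
    data: str | None = None          # epoch container path, or None for synth
    synth: SynthConfig | None = None
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    skip_preprocess: bool = False
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    folds: int = 5
    seed: int = 0
    profile: str = "full"            # or "desk"

    def __post_init__(self):
        if self.profile not in ("full", "desk"):
            raise ValueError("profile must be 'full' or 'desk'")


def desk_profile(config: RunConfig) -> RunConfig:
    """Shrink network widths and training length for single-CPU runs."""
    cfg = dataclasses.replace(config)
    cfg.pipeline = dataclasses.replace(
        config.pipeline,
        eeg_cnn=dataclasses.replace(config.pipeline.eeg_cnn,
                                    filters=(8, 16), fc_units=64),
        tf_cnn=dataclasses.replace(config.pipeline.tf_cnn,
                                   width_multiplier=0.125, fc_units=None),
        train_eeg=TrainConfig(learning_rate=1e-3, epochs=10, batch_size=16),
        train_tf=TrainConfig(learning_rate=3e-4, epochs=8, batch_size=8),
    )
    cfg.profile = "desk"
    return cfg


def _load_data(config: RunConfig) -> EEGEpochSet:
    if config.data is not None:
        return load_epochs(config.data)
    if config.synth is None:
        raise ValueError("config must provide either a data path or a synth spec")
    return generate_mi_dataset(config.synth)


def run(config: RunConfig, out_dir=None) -> EvalReport:
    if config.profile == "desk":
        config = desk_profile(config)
    epochs = _load_data(config)
    log.info("loaded %d trials, %d channels, %d samples at %g Hz",
             epochs.n_trials, epochs.n_channels, epochs.n_samples, epochs.fs)
    if not config.skip_preprocess:
        epochs = preprocess(epochs, config.preproc)
        log.info("preprocessed to %d samples at %g Hz",
                 epochs.n_samples, epochs.fs)
    report = five_fold_cv(epochs, config.pipeline, seed=config.seed,
                          n_folds=config.folds)
    report.config_snapshot = _config_dict(config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.yaml").write_text(dump_run_config(config))
        (out_dir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True))
        _write_summary_csv(report, out_dir / "summary.csv")
        _write_confusion_pngs(report, out_dir)
        (out_dir / "run.log").write_text(
            f"pipeline={report.pipeline} seed={report.seed} "
            f"folds={len(report.per_fold)} n_classes={report.n_classes}\n"
            f"mean_accuracy={report.mean_accuracy:.6f} "
            f"mean_kappa={report.mean_kappa:.6f}\n")
        log.info("report written to %s", out_dir)
    return report


def _write_confusion_pngs(report: EvalReport, out_dir: Path) -> None:
    from .evaluate import ConfusionMatrix, save_confusion_png
    total = None
    for fold in report.per_fold:
        cm = np.asarray(fold["confusion"])
        total = cm if total is None else total + cm
    if total is not None:
        save_confusion_png(ConfusionMatrix(total),
                           out_dir / "confusion_pooled.png")


def _write_summary_csv(report: EvalReport, path: Path) -> None:
    lines = ["fold,accuracy,kappa"]
    for f in report.per_fold:
        lines.append(f"{f['fold']},{f['accuracy']:.6f},{f['kappa']:.6f}")
    lines.append(f"mean,{report.mean_accuracy:.6f},{report.mean_kappa:.6f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# YAML serialization (round-trip stable: dump(load(dump(c))) == dump(c))

def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("pipeline", {}).get("cwt", {}).get("freqs") is not None:
        d["pipeline"]["cwt"]["freqs"] = np.asarray(
            d["pipeline"]["cwt"]["freqs"]).tolist()
    return _plain(d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def dump_run_config(config: RunConfig) -> str:
    return yaml.safe_dump(_config_dict(config), sort_keys=True)


def load_run_config(text: str) -> RunConfig:
    d = yaml.safe_load(text)
    synth = SynthConfig(**_retuple(d["synth"], ("source_freq_band",))) \
        if d.get("synth") else None
    pre = PreprocConfig(**_retuple(d.get("preproc", {}),
                                   ("channels", "band")))
    p = d.get("pipeline", {})
    pipeline = PipelineConfig(
        pipeline=p.get("pipeline", "fusion"),
        csp_m=p.get("csp_m", 1),
        shrinkage=p.get("shrinkage", 1e-6),
        cwt=CWTConfig(**p.get("cwt", {})),
        eeg_cnn=EEGCNNConfig(**_retuple(p.get("eeg_cnn", {}),
                                        ("filters", "kernel", "pool"))),
        tf_cnn=TFCNNConfig(**p.get("tf_cnn", {})),
        train=TrainConfig(**p.get("train", {})),
        train_eeg=TrainConfig(**p["train_eeg"]) if p.get("train_eeg") else None,
        train_tf=TrainConfig(**p["train_tf"]) if p.get("train_tf") else None,
        svm=SVMConfig(**p.get("svm", {})),
    )
    return RunConfig(data=d.get("data"), synth=synth, preproc=pre,
                     skip_preprocess=d.get("skip_preprocess", False),
                     pipeline=pipeline, folds=d.get("folds", 5),
                     seed=d.get("seed", 0), profile=d.get("profile", "full"))


def _retuple(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d
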