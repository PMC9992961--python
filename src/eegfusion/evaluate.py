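"""Cross-validated evaluation: accuracy, chance-corrected kappa, confusion
matrices, paired t-tests, and the four pipelines (fusion / raw-EEG branch /
image branch / CSP log-variance baseline).

Leakage discipline: all supervised fitting (CSP, branch networks, feature
scaler, SVM) happens inside ``fit_fold`` on the training fold only; the
test fold is touched exclusively by ``score_fold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .branches import (EEGCNNConfig, TFCNNConfig, TrainConfig, TrainedBranch,
                       build_eeg_cnn, build_tf_cnn, extract_features,
                       predict_labels, train_branch)
from .csp import CSPModel, extract_virtual_channels, fit_csp_ovr
from .data import EEGEpochSet
from .fusion import (FusionClassifier, SVMConfig, fit_fusion_classifier,
                     fuse_matrix, predict)
from .tfmap import CWTConfig, epochs_to_images

__all__ = ["ConfusionMatrix", "EvalReport", "PipelineConfig", "accuracy",
           "kappa", "kappa_from_confusion", "confusion", "paired_t_test",
           "five_fold_cv", "csp_baseline", "fit_fold", "score_fold",
           "FoldModels"]

PIPELINES = ("fusion", "eeg", "tf", "csp")


# ---------------------------------------------------------------------------
# metrics

@dataclass
class ConfusionMatrix:
    """counts[predicted][true] (rows = predicted label, columns = true)."""
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def accuracy(cm: ConfusionMatrix) -> float:
    """trace / total — the two-class TP+TN over everything, generalized."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def kappa(p0: float, n_classes: int) -> float:
    """(p0 - pe) / (1 - pe) with fixed chance level pe = 1/n_classes."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be a fraction in [0, 1]")
    pe = 1.0 / n_classes
    return (p0 - pe) / (1.0 - pe)


def kappa_from_confusion(cm: ConfusionMatrix, chance: str = "uniform") -> float:
    """Kappa from a confusion matrix; ``chance='marginal'`` uses Cohen's
    marginal-product pe instead of the fixed 1/K."""
    p0 = accuracy(cm)
    if chance == "uniform":
        return kappa(p0, cm.counts.shape[0])
    if chance == "marginal":
        n = cm.total
        pe = float((cm.counts.sum(axis=1) / n) @ (cm.counts.sum(axis=0) / n))
        return (p0 - pe) / (1.0 - pe)
    raise ValueError(f"unknown chance model {chance!r}")


def confusion(y_true, y_pred, n_classes: int | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    k = n_classes if n_classes is not None else int(max(y_true.max(), y_pred.max())) + 1
    if y_true.min() < 0 or y_pred.min() < 0 or y_true.max() >= k or y_pred.max() >= k:
        raise ValueError("label outside the class set")
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[p, t] += 1
    return ConfusionMatrix(counts)


def paired_t_test(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-unit accuracies."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 accuracies")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("degenerate paired t-test: difference variance is zero")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# pipeline configuration and reporting

@dataclass
class PipelineConfig:
    pipeline: str = "fusion"
    csp_m: int = 1
    shrinkage: float = 1e-6
    cwt: CWTConfig = field(default_factory=CWTConfig)
    eeg_cnn: EEGCNNConfig = field(default_factory=EEGCNNConfig)
    tf_cnn: TFCNNConfig = field(default_factory=lambda: TFCNNConfig(width_multiplier=0.125))
    train: TrainConfig = field(default_factory=TrainConfig)
    train_eeg: TrainConfig | None = None  # per-branch overrides of `train`
    train_tf: TrainConfig | None = None
    svm: SVMConfig = field(default_factory=SVMConfig)

    def __post_init__(self):
        if self.pipeline not in PIPELINES:
            raise ValueError(f"pipeline must be one of {PIPELINES}")


@dataclass
class EvalReport:
    per_fold: list[dict]
    mean_accuracy: float
    mean_kappa: float
    n_classes: int
    pipeline: str
    seed: int
    comparisons: list[dict] = field(default_factory=list)
    config_snapshot: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        for fold in d["per_fold"]:
            fold["confusion"] = np.asarray(fold["confusion"]).tolist()
        return d

    @property
    def branch_mean_accuracy(self) -> dict:
        """Mean softmax accuracy per branch (fusion runs only)."""
        out = {}
        for key in ("eeg_branch_accuracy", "tf_branch_accuracy"):
            vals = [f[key] for f in self.per_fold if key in f]
            if vals:
                out[key] = float(np.mean(vals))
        return out


# ---------------------------------------------------------------------------
# per-fold fitting and scoring

@dataclass
class FoldModels:
    pipeline: str
    n_classes: int
    csp_models: list[CSPModel] | None = None
    eeg_branch: TrainedBranch | None = None
    tf_branch: TrainedBranch | None = None
    eeg_scale: float = 1.0
    svm: FusionClassifier | None = None

    def state_bytes(self) -> bytes:
        """Deterministic serialization of every fitted component (used by
        the no-leakage contract tests)."""
        chunks = [self.pipeline.encode(), np.float64(self.eeg_scale).tobytes()]
        if self.csp_models is not None:
            for m in self.csp_models:
                chunks += [m.W.tobytes(), m.eigenvalues.tobytes()]
        for br in (self.eeg_branch, self.tf_branch):
            if br is not None:
                chunks.append(br.net.state_bytes())
        if self.svm is not None:
            svc = self.svm.pipeline.named_steps["svm"]
            scale = self.svm.pipeline.named_steps["scale"]
            chunks += [np.ascontiguousarray(scale.mean_).tobytes(),
                       np.ascontiguousarray(scale.scale_).tobytes(),
                       np.ascontiguousarray(svc.dual_coef_).tobytes(),
                       np.ascontiguousarray(svc.intercept_).tobytes()]
        return b"".join(chunks)


def _log_variance_features(epochs: EEGEpochSet, models, m: int) -> np.ndarray:
    vc = extract_virtual_channels(models, epochs, m=m)
    var = vc.var(axis=2, ddof=0)
    return np.log(np.maximum(var, 1e-300))


def _eeg_inputs(epochs: EEGEpochSet, scale: float) -> np.ndarray:
    return (epochs.data * scale).astype(np.float32)


def fit_fold(train: EEGEpochSet, config: PipelineConfig, seed: int) -> FoldModels:
    """Fit every supervised component of the selected pipeline on ``train``."""
    n_classes = len(np.unique(train.labels))
    models = FoldModels(pipeline=config.pipeline, n_classes=n_classes)
    needs_csp = config.pipeline in ("fusion", "tf", "csp")
    if needs_csp:
        models.csp_models = fit_csp_ovr(train, shrinkage=config.shrinkage)
    if config.pipeline == "csp":
        feats = _log_variance_features(train, models.csp_models, config.csp_m)
        models.svm = fit_fusion_classifier(feats, train.labels, config.svm)
        return models

    models.eeg_scale = 1.0 / max(float(train.data.std()), 1e-12)
    if config.pipeline in ("fusion", "eeg"):
        tcfg = config.train_eeg or config.train
        cfg = EEGCNNConfig(**{**asdict(config.eeg_cnn), "n_classes": n_classes})
        net = build_eeg_cnn(cfg, (train.n_channels, train.n_samples), seed=seed)
        models.eeg_branch = train_branch(
            net, (_eeg_inputs(train, models.eeg_scale), train.labels),
            TrainConfig(**{**asdict(tcfg), "seed": seed}))
    if config.pipeline in ("fusion", "tf"):
        tcfg = config.train_tf or config.train
        cfg = TFCNNConfig(**{**asdict(config.tf_cnn), "n_classes": n_classes,
                             "fc_units": config.tf_cnn.fc_units})
        net = build_tf_cnn(cfg, image_size=config.cwt.image_size, seed=seed + 1)
        images = epochs_to_images(train, models.csp_models, config.csp_m,
                                  config.cwt)
        models.tf_branch = train_branch(
            net, (images, train.labels),
            TrainConfig(**{**asdict(tcfg), "seed": seed + 1}))
    if config.pipeline == "fusion":
        a = extract_features(models.eeg_branch,
                             _eeg_inputs(train, models.eeg_scale))
        b = extract_features(models.tf_branch, images)
        models.svm = fit_fusion_classifier(fuse_matrix(a, b), train.labels,
                                           config.svm)
    return models


def score_fold(models: FoldModels, test: EEGEpochSet,
               config: PipelineConfig) -> dict:
    """Score the held-out fold; returns the per-fold report entry."""
    n_classes = models.n_classes
    extras = {}
    if models.pipeline == "csp":
        feats = _log_variance_features(test, models.csp_models, config.csp_m)
        y_pred = predict(models.svm, feats)
    elif models.pipeline == "eeg":
        y_pred = predict_labels(models.eeg_branch,
                                _eeg_inputs(test, models.eeg_scale))
    elif models.pipeline == "tf":
        images = epochs_to_images(test, models.csp_models, config.csp_m,
                                  config.cwt)
        y_pred = predict_labels(models.tf_branch, images)
    else:  # fusion
        x_eeg = _eeg_inputs(test, models.eeg_scale)
        images = epochs_to_images(test, models.csp_models, config.csp_m,
                                  config.cwt)
        a = extract_features(models.eeg_branch, x_eeg)
        b = extract_features(models.tf_branch, images)
        y_pred = predict(models.svm, fuse_matrix(a, b))
        eeg_pred = predict_labels(models.eeg_branch, x_eeg)
        tf_pred = predict_labels(models.tf_branch, images)
        extras["eeg_branch_accuracy"] = float(np.mean(eeg_pred == test.labels))
        extras["tf_branch_accuracy"] = float(np.mean(tf_pred == test.labels))
    cm = confusion(test.labels, y_pred, n_classes=n_classes)
    acc = accuracy(cm)
    return {"accuracy": acc, "kappa": kappa(acc, n_classes),
            "confusion": cm.counts, **extras}


def five_fold_cv(epochs: EEGEpochSet, config: PipelineConfig, seed: int,
                 n_folds: int = 5) -> EvalReport:
    """Stratified k-fold evaluation; every supervised fit is train-only."""
    labels = epochs.labels
    counts = np.bincount(labels)
    if counts[counts > 0].min() < n_folds:
        raise ValueError(
            f"need >= {n_folds} trials per class for {n_folds}-fold CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        models = fit_fold(epochs.subset(tr), config, seed=seed * 1000 + fold)
        entry = score_fold(models, epochs.subset(te), config)
        entry["fold"] = fold
        per_fold.append(entry)
    mean_acc = float(np.mean([f["accuracy"] for f in per_fold]))
    n_classes = len(np.unique(labels))
    return EvalReport(
        per_fold=per_fold,
        mean_accuracy=mean_acc,
        mean_kappa=kappa(mean_acc, n_classes),
        n_classes=n_classes,
        pipeline=config.pipeline,
        seed=seed,
        config_snapshot=_snapshot(config),
    )


def csp_baseline(epochs: EEGEpochSet, m: int = 1, seed: int = 0,
                 n_folds: int = 5) -> EvalReport:
    """Classical CSP: log-variance of 2m virtual channels + linear SVM."""
    cfg = PipelineConfig(pipeline="csp", csp_m=m)
    return five_fold_cv(epochs, cfg, seed=seed, n_folds=n_folds)


def save_confusion_png(cm: ConfusionMatrix, path, class_names=None) -> None:
    """Heatmap of a confusion matrix (rows = predicted, columns = true)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = cm.counts.shape[0]
    names = class_names or [str(i) for i in range(k)]
    fig, ax = plt.subplots(figsize=(3 + 0.4 * k, 3 + 0.4 * k))
    im = ax.imshow(cm.counts, cmap="Blues")
    for i in range(k):
        for j in range(k):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
    ax.set_xticks(range(k), names)
    ax.set_yticks(range(k), names)
    ax.set_xlabel("true label")
    ax.set_ylabel("predicted label")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _snapshot(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["cwt"]["freqs"] = np.asarray(d["cwt"]["freqs"]).tolist()
    return d
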