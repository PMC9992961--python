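"""Feature-level fusion: concatenate branch features, standardize, SVM."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["SVMConfig", "FusionClassifier", "fuse", "fit_fusion_classifier",
           "predict"]


@dataclass
class SVMConfig:
    kernel: str = "linear"
    C: float = 1.0


@dataclass
class FusionClassifier:
    pipeline: Pipeline
    n_features: int
    classes: np.ndarray


def fuse(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """C = [a1..am, b1..bn]; order-preserving concatenation."""
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite feature entries")
    return np.concatenate([A, B])


def fuse_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise fusion of two feature matrices with equal trial counts."""
    A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("feature matrices disagree on trial count")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
        raise ValueError("non-finite feature entries")
    return np.hstack([A, B])


def fit_fusion_classifier(features: np.ndarray, labels,
                          svm_config: SVMConfig | None = None) -> FusionClassifier:
    """Per-dimension z-scoring (fit on these rows only) then an SVM;
    one-vs-rest decision shape for multiclass."""
    svm_config = svm_config or SVMConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to fit the classifier")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=svm_config.kernel, C=svm_config.C,
                    decision_function_shape="ovr")),
    ])
    pipe.fit(features, labels)
    return FusionClassifier(pipeline=pipe, n_features=features.shape[1],
                            classes=classes)


def predict(classifier: FusionClassifier, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[None, :]
    if features.shape[1] != classifier.n_features:
        raise ValueError(
            f"feature width {features.shape[1]} != fitted width "
            f"{classifier.n_features}")
    return classifier.pipeline.predict(features)
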