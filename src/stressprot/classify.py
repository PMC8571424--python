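"""The three classifier harnesses: random forest, neural net, linear SVM.

Hyperparameter defaults follow the study configuration: a 50-tree random
forest; a single-hidden-layer network (50 ReLU units, two-class output)
trained by stochastic gradient descent at learning rate 0.001; a
linear-kernel SVM at the default margin penalty. The network is realised
with scikit-learn's MLPClassifier, whose binary logistic output is
decision-equivalent to a two-unit one-hot sigmoid head.

Raw moment features span many orders of magnitude, so per-feature
standardization (fitted on training rows only) defaults to on for the
scale-sensitive models (neural net, SVM) and off for the scale-invariant
forest. The choice is recorded in the model file.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES, feature_fingerprint

MODEL_KINDS = ("random_forest", "neural_net", "linear_svm")


@dataclass
class ModelSpec:
    """Classifier kind, hyperparameters, and the training seed."""

    kind: str = "random_forest"
    n_trees: int = 50
    hidden_units: int = 50
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    standardize: bool | None = None  # None: auto (on for nn/svm, off for rf)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")

    @property
    def effective_standardize(self) -> bool:
        if self.standardize is None:
            return self.kind in ("neural_net", "linear_svm")
        return self.standardize

    def build_estimator(self):
        if self.kind == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.seed
            )
        if self.kind == "neural_net":
            return MLPClassifier(
                hidden_layer_sizes=(self.hidden_units,),
                activation="relu",
                solver="sgd",
                learning_rate_init=self.learning_rate,
                max_iter=self.epochs,
                batch_size=self.batch_size,
                random_state=self.seed,
            )
        return SVC(kernel="linear", random_state=self.seed)


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it honestly."""

    spec: ModelSpec
    estimator: object
    scaler: StandardScaler | None
    fingerprint: str
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))


def train(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ModelSpec,
    feature_names: list[str] | None = None,
) -> TrainedModel:
    """Fit the classifier described by ``spec``.

    Standardization statistics, when enabled, are computed from the
    training rows only and stored with the model.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError(
            f"feature/label shape mismatch: {features.shape} vs {labels.shape}"
        )
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class training set: both classes must be present")

    names = list(FEATURE_NAMES) if feature_names is None else list(feature_names)
    if features.shape[1] != len(names):
        raise ValueError(
            f"feature matrix has {features.shape[1]} columns but "
            f"{len(names)} feature names were given"
        )

    scaler = None
    x = features
    if spec.effective_standardize:
        scaler = StandardScaler()
        x = scaler.fit_transform(features)

    est = spec.build_estimator()
    with warnings.catch_warnings():
        # the epoch count is a fixed training budget, not a convergence tol
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(x, labels)
    return TrainedModel(
        spec=spec,
        estimator=est,
        scaler=scaler,
        fingerprint=feature_fingerprint(names),
        feature_names=names,
    )


def predict(
    model: TrainedModel,
    features: np.ndarray,
    feature_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and [0, 1] scores for ROC analysis.

    Scores are class-1 probabilities for the forest and the network, and a
    logistic squashing of the signed margin for the SVM (monotone in the
    margin, hence ROC-equivalent).
    """
    features = np.asarray(features, dtype=float)
    if feature_names is not None and feature_fingerprint(list(feature_names)) != model.fingerprint:
        raise ValueError(
            "feature fingerprint mismatch: the feature order of this input "
            "does not match the order the model was trained with"
        )
    if features.ndim != 2 or features.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} feature columns, "
            f"got {features.shape[1] if features.ndim == 2 else 'non-matrix input'}"
        )
    x = features if model.scaler is None else model.scaler.transform(features)
    labels = np.asarray(model.estimator.predict(x))
    if hasattr(model.estimator, "predict_proba"):
        scores = model.estimator.predict_proba(x)[:, 1]
    else:
        margin = model.estimator.decision_function(x)
        scores = 1.0 / (1.0 + np.exp(-margin))
    return labels, scores


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist spec + fitted parameters; predictions round-trip exactly."""
    payload = {
        "spec_json": json.dumps(asdict(model.spec)),
        "estimator": model.estimator,
        "scaler": model.scaler,
        "fingerprint": model.fingerprint,
        "feature_names": model.feature_names,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    payload = joblib.load(path)
    return TrainedModel(
        spec=ModelSpec(**json.loads(payload["spec_json"])),
        estimator=payload["estimator"],
        scaler=payload["scaler"],
        fingerprint=payload["fingerprint"],
        feature_names=payload["feature_names"],
    )
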