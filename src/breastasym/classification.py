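"""RBF-SVM base classifier, bootstrap ensembles, and the repeated-split
experiment protocol.

The base classifier is a support vector machine with a radial-basis-function
kernel at C = 2 and gamma = 2, with per-feature z-score standardization
fitted on the training fold only.  Soft class supports are obtained from the
signed SVM margin through a unit-slope logistic link and renormalized, so
ensemble combiners receive row-stochastic decision profiles whose argmax
always agrees with the SVM's hard decision.

The ensemble trains L base learners on bootstrap resamples of the training
set and fuses their supports with one of the nine combination rules of
:mod:`breastasym.combiners`.

``run_experiment`` repeats stratified random train/test splits, scoring each
iteration with :mod:`breastasym.metrics` and aggregating across iterations.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import joblib
import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import combiners
from .errors import ContractError
from .metrics import AggregateReport, MetricsReport, aggregate, compute_metrics, confusion_matrix

__all__ = [
    "ClassifierConfig",
    "EnsembleConfig",
    "ExperimentProtocol",
    "SVMModel",
    "EnsembleModel",
    "train_base_classifier",
    "predict_supports",
    "train_ensemble",
    "run_experiment",
    "save_model",
    "load_model",
]

ARCHIVE_VERSION = 1


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """RBF-SVM settings.

    The published operating point is C = 2, gamma = 2, applied to the raw
    asymmetry-energy features, whose natural magnitude (about 1e-3 to 1e-1)
    keeps gamma * ||x - x'||^2 in a useful range.  ``standardize`` therefore
    defaults to False: z-scoring d features to unit variance puts typical
    squared distances near 2d, which collapses exp(-2 ||x - x'||^2) to zero
    and the classifier to a majority rule.  For feature families on other
    scales (e.g. Haralick statistics), standardize and use gamma="scale"
    (1 / (d * var), as in scikit-learn).
    """

    kernel: str = "rbf"
    C: float = 2.0
    gamma: float | str = 2.0
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ContractError("only the RBF kernel is supported")
        if self.C <= 0:
            raise ContractError("C must be positive")
        if isinstance(self.gamma, str):
            if self.gamma not in ("scale", "auto"):
                raise ContractError("gamma must be positive or 'scale'/'auto'")
        elif self.gamma <= 0:
            raise ContractError("gamma must be positive")


@dataclasses.dataclass(frozen=True)
class EnsembleConfig:
    rule: str = "majority"
    n_learners: int = 3
    base: ClassifierConfig = ClassifierConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in combiners.ALL_RULES:
            raise ContractError(f"unknown rule {self.rule!r}; valid: {combiners.ALL_RULES}")
        if self.n_learners < 1:
            raise ContractError("n_learners must be >= 1")


@dataclasses.dataclass(frozen=True)
class ExperimentProtocol:
    n_iterations: int = 6
    test_fraction: float = 0.3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ContractError("n_iterations must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ContractError("test_fraction must be in (0, 1)")


@dataclasses.dataclass
class SVMModel:
    svc: SVC
    scaler: StandardScaler | None
    classes: np.ndarray
    config: ClassifierConfig

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ContractError("feature matrix must be 2D")
        if X.shape[1] != self.svc.n_features_in_:
            raise ContractError(
                f"feature dimension {X.shape[1]} does not match model "
                f"({self.svc.n_features_in_})"
            )
        return self.scaler.transform(X) if self.scaler is not None else X

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._transform(X))


def train_base_classifier(
    X: np.ndarray, y: Sequence, config: ClassifierConfig | None = None
) -> SVMModel:
    """Fit the standardizer (training data only) and the RBF-SVM."""
    config = config or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ContractError("X must be 2D with one label per row")
    if not np.all(np.isfinite(X)):
        raise ContractError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ContractError("training set must contain at least two classes")
    scaler = None
    Xs = X
    if config.standardize:
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
    svc = SVC(kernel="rbf", C=config.C, gamma=config.gamma, random_state=config.seed)
    svc.fit(Xs, y)
    return SVMModel(svc=svc, scaler=scaler, classes=svc.classes_, config=config)


def predict_supports(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Soft class supports in class order, one row per sample, rows summing to 1.

    The binary signed margin d maps to support (1-s, s) with s = logistic(d)
    (unit slope), so a sample on the boundary gets (0.5, 0.5) and the argmax
    equals the hard prediction.  Multi-class uses one-vs-one vote-weighted
    margins the same way.
    """
    Xs = model._transform(X)
    d = model.svc.decision_function(Xs)
    if d.ndim == 1:  # binary: positive d favors classes_[1]
        s = 1.0 / (1.0 + np.exp(-d))
        supports = np.column_stack([1.0 - s, s])
    else:
        s = 1.0 / (1.0 + np.exp(-d))
        supports = s / s.sum(axis=1, keepdims=True)
    return supports


@dataclasses.dataclass
class EnsembleModel:
    learners: list[SVMModel]
    classes: np.ndarray
    config: EnsembleConfig
    fitted_combiner: combiners.DecisionTemplates | None

    def decision_profiles(self, X: np.ndarray) -> np.ndarray:
        """n x L x c stack of per-learner supports."""
        return np.stack([predict_supports(m, X) for m in self.learners], axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        profiles = self.decision_profiles(X)
        idx = [
            combiners.combine(dp, self.config.rule, self.fitted_combiner)[0] for dp in profiles
        ]
        return self.classes[np.asarray(idx, dtype=int)]


def train_ensemble(
    X: np.ndarray, y: Sequence, config: EnsembleConfig | None = None
) -> EnsembleModel:
    """Train L base SVMs on bootstrap resamples; fit the combiner if trainable.

    Each resample is drawn with replacement but redrawn (bounded retries)
    until it contains every class, so every learner sees a two-class problem.
    """
    config = config or EnsembleConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ContractError("training set must contain at least two classes")
    rng = np.random.default_rng(config.seed)
    learners: list[SVMModel] = []
    n = len(y)
    for l in range(config.n_learners):
        for _ in range(50):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == len(classes):
                break
        else:
            raise ContractError("could not draw a bootstrap resample containing every class")
        base_cfg = dataclasses.replace(config.base, seed=config.base.seed + l)
        learners.append(train_base_classifier(X[idx], y[idx], base_cfg))
    model = EnsembleModel(
        learners=learners, classes=classes, config=config, fitted_combiner=None
    )
    if config.rule in combiners.TRAINABLE_RULES:
        profiles = model.decision_profiles(X)
        label_idx = np.searchsorted(classes, y)
        model.fitted_combiner = combiners.fit_trainable_combiner(
            list(profiles), list(label_idx), n_classes=len(classes)
        )
    return model


def _fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: ClassifierConfig | EnsembleConfig,
) -> np.ndarray:
    if isinstance(config, EnsembleConfig):
        return train_ensemble(X_train, y_train, config).predict(X_test)
    return train_base_classifier(X_train, y_train, config).predict(X_test)


def run_experiment(
    X: np.ndarray,
    y: Sequence,
    config: ClassifierConfig | EnsembleConfig | None = None,
    protocol: ExperimentProtocol | None = None,
    positive=None,
) -> tuple[list[MetricsReport], AggregateReport]:
    """Repeated stratified random train/test splits, scored per iteration.

    ``positive`` names the positive (disease) class for the confusion matrix.
    By default "normal" or "benign" is treated as the negative class when
    present; otherwise the last label in sorted order is positive.
    """
    config = config or ClassifierConfig()
    protocol = protocol or ExperimentProtocol()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ContractError("run_experiment handles binary tasks")
    if positive is None:
        negatives = [c for c in classes if str(c) in ("normal", "benign")]
        positive = next(c for c in classes[::-1] if c not in negatives[:1])
    ss = np.random.SeedSequence(protocol.seed)
    iter_seeds = ss.generate_state(protocol.n_iterations)
    reports: list[MetricsReport] = []
    for it in range(protocol.n_iterations):
        split_seed = int(iter_seeds[it] % (2**31 - 1))
        stratify = y if protocol.stratified else None
        for attempt in range(2):
            X_tr, X_te, y_tr, y_te = train_test_split(
                X,
                y,
                test_size=protocol.test_fraction,
                stratify=stratify,
                random_state=split_seed + attempt,
            )
            if len(np.unique(y_te)) == 2 and len(np.unique(y_tr)) == 2:
                break
        else:
            raise ContractError(f"iteration {it}: test split missing a class after redraw")
        iter_config = _reseed(config, split_seed)
        y_pred = _fit_predict(X_tr, y_tr, X_te, iter_config)
        reports.append(compute_metrics(confusion_matrix(y_te, y_pred, positive)))
    return reports, aggregate(reports)


def _reseed(config: ClassifierConfig | EnsembleConfig, seed: int):
    if isinstance(config, EnsembleConfig):
        return dataclasses.replace(config, seed=seed)
    return dataclasses.replace(config, seed=seed)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: SVMModel | EnsembleModel, path) -> None:
    """Persist a trained model as a versioned joblib archive."""
    joblib.dump({"version": ARCHIVE_VERSION, "model": model}, path)


def load_model(path) -> SVMModel | EnsembleModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("version") != ARCHIVE_VERSION:
        raise ContractError(f"unrecognized model archive {path}")
    return payload["model"]
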