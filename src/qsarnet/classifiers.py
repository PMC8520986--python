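"""Binary ADME property classifiers behind one train/predict contract.

Five algorithm families are exposed: k-nearest neighbours (KNN), support
vector machine with radial kernel (SVM), random forest (RF), partial least
squares discriminant analysis (PLSDA) and an error-back-propagation
feed-forward network (EBPT). KNN/SVM/RF/EBPT are backed by scikit-learn;
PLS-DA is implemented here from the NIPALS recursion so that its decision
rule (predicted dummy response > 0.5 → "+") is fully specified.

Class coding: ``"+"`` is the positive/large category of a property,
``"-"`` the negative one. The Unicode minus sign is accepted on input and
normalised to ASCII ``"-"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .prep import DescriptorMatrix

POS = "+"
NEG = "-"

#: canonical ADME property names and the column order used for call tables
PROPERTIES = ("Caco2", "PGPS", "PGPI", "OB", "HIA")

ALGORITHMS = ("KNN", "SVM", "RF", "PLSDA", "EBPT")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "KNN": {"k": 5},
    "SVM": {"cost": 1.0, "gamma": None},  # None -> 1/p
    "RF": {"n_trees": 500, "max_features": "sqrt"},
    "PLSDA": {"n_components": 2, "threshold": 0.5},
    "EBPT": {"hidden_units": 10, "learning_rate": 0.01, "epochs": 500},
}

MODEL_FORMAT_VERSION = 1


def normalize_class(c: str) -> str:
    c = str(c).strip().replace("−", NEG)
    if c not in (POS, NEG):
        raise ValueError(f"class label must be '+' or '-', got {c!r}")
    return c


@dataclass
class PropertyLabels:
    """Per-compound binary class calls for one ADME property."""

    compound_ids: list[str]
    property: str
    classes: list[str]

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.classes = [normalize_class(c) for c in self.classes]
        if len(self.compound_ids) != len(self.classes):
            raise ValueError("compound_ids and classes differ in length")

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def y(self) -> np.ndarray:
        """Classes as 0/1 with '+' coded 1."""
        return np.array([1 if c == POS else 0 for c in self.classes])

    def subset(self, ids: list[str]) -> "PropertyLabels":
        index = dict(zip(self.compound_ids, self.classes))
        return PropertyLabels(list(ids), self.property, [index[c] for c in ids])

    def flipped(self) -> "PropertyLabels":
        return PropertyLabels(
            self.compound_ids, self.property,
            [NEG if c == POS else POS for c in self.classes],
        )


@dataclass
class ClassifierSpec:
    """Algorithm choice plus hyperparameters; unknown keys are rejected."""

    algorithm: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        unknown = set(self.hyperparameters) - set(_DEFAULTS[self.algorithm])
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.algorithm}: {sorted(unknown)}")

    def resolved(self) -> dict[str, Any]:
        out = dict(_DEFAULTS[self.algorithm])
        out.update(self.hyperparameters)
        return out


def plsda_fit(
    X: np.ndarray, y: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS partial least squares on a centred X and 0/1 response.

    Components are extracted sequentially with deflation of X. Returns
    ``(weights W, scores T, loadings P, coefficients B)`` where columns of
    W/T/P are per-component and ``B`` maps centred X to the centred response
    via ``B = W (PᵀW)⁻¹ q``.

    Raises
    ------
    ValueError
        If ``n_components`` exceeds the rank of X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_components < 0:
        raise ValueError("n_components must be non-negative")
    if n_components > np.linalg.matrix_rank(X):
        raise ValueError(
            f"n_components={n_components} exceeds rank {np.linalg.matrix_rank(X)} of X"
        )
    Xd = X.copy()
    yd = y - y.mean()
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValueError("response carries no variance along remaining X directions")
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            raise ValueError("rank deficiency encountered during deflation")
        pvec = Xd.T @ t / tt
        q[a] = yd @ t / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - q[a] * t
        W[:, a], T[:, a], P[:, a] = w, t, pvec
    if n_components == 0:
        B = np.zeros(p)
    else:
        B = W @ np.linalg.solve(P.T @ W, q)
    return W, T, P, B


class _PLSDAModel:
    """PLS-DA with the explicit >0.5 decision rule (tie → negative class)."""

    def __init__(self, n_components: int = 2, threshold: float = 0.5):
        self.n_components = n_components
        self.threshold = threshold

    def fit(self, X: np.ndarray, y01: np.ndarray) -> "_PLSDAModel":
        X = np.asarray(X, dtype=float)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(np.mean(y01))
        # cap at the feasible component count so narrow (e.g. GA-selected
        # single-column) feature spaces still train, and back off when the
        # response is orthogonal to the remaining X directions;
        # plsda_fit itself stays strict
        a = min(self.n_components, int(np.linalg.matrix_rank(X - self.x_mean_)))
        self.coef_ = np.zeros(X.shape[1])
        while a > 0:
            try:
                _, _, _, self.coef_ = plsda_fit(X - self.x_mean_, y01, a)
                break
            except ValueError:
                a -= 1
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.y_mean_ + (np.asarray(X, dtype=float) - self.x_mean_) @ self.coef_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > self.threshold).astype(int)


def _build_estimator(spec: ClassifierSpec, p: int):
    hp = spec.resolved()
    if spec.algorithm == "KNN":
        return KNeighborsClassifier(n_neighbors=hp["k"])
    if spec.algorithm == "SVM":
        gamma = hp["gamma"] if hp["gamma"] is not None else 1.0 / p
        return SVC(kernel="rbf", C=hp["cost"], gamma=gamma)
    if spec.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=hp["n_trees"],
            max_features=hp["max_features"],
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.algorithm == "PLSDA":
        return _PLSDAModel(n_components=hp["n_components"], threshold=hp["threshold"])
    if spec.algorithm == "EBPT":
        return MLPClassifier(
            hidden_layer_sizes=(hp["hidden_units"],),
            activation="logistic",
            solver="sgd",
            learning_rate_init=hp["learning_rate"],
            max_iter=hp["epochs"],
            n_iter_no_change=hp["epochs"],
            random_state=spec.seed,
        )
    raise AssertionError(spec.algorithm)


# RF trees partition on raw thresholds; scaling is a no-op for them and
# skipping it keeps the trees readable. All other algorithms are
# distance/margin/gradient based and get z-scored features.
_SCALED = {"KNN", "SVM", "PLSDA", "EBPT"}


@dataclass
class TrainedModel:
    """A fitted classifier bound to its training descriptor names."""

    spec: ClassifierSpec
    feature_names: list[str]
    property: str
    estimator: Any
    center: np.ndarray
    scale: np.ndarray
    training_accuracy: float
    format_version: int = MODEL_FORMAT_VERSION

    def _prepare(self, X) -> np.ndarray:
        if isinstance(X, DescriptorMatrix):
            if list(X.descriptor_names) != self.feature_names:
                if set(X.descriptor_names) == set(self.feature_names):
                    X = X.select(self.feature_names)
                else:
                    raise ValueError("query descriptors do not match training descriptors")
            arr = X.values
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} feature columns, got shape {arr.shape}"
                )
        return (arr - self.center) / self.scale

    def predict(self, X) -> list[str]:
        """Predict '+'/'-' calls; empty input yields an empty list."""
        if isinstance(X, DescriptorMatrix):
            n = X.shape[0]
        else:
            n = np.asarray(X).shape[0]
        if n == 0:
            return []
        y01 = self.estimator.predict(self._prepare(X))
        return [POS if v == 1 else NEG for v in np.asarray(y01).astype(int)]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError("file does not contain a TrainedModel")
        return model


def train_classifier(X, y: PropertyLabels, spec: ClassifierSpec) -> TrainedModel:
    """Fit one classifier; deterministic given ``spec.seed``.

    ``X`` is a :class:`DescriptorMatrix` or a plain array (feature names are
    then synthesised as ``f0..f{p-1}``).
    """
    if isinstance(X, DescriptorMatrix):
        names = list(X.descriptor_names)
        arr = X.values
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"f{j}" for j in range(arr.shape[1])]
    if arr.shape[0] != len(y):
        raise ValueError(f"{arr.shape[0]} feature rows but {len(y)} labels")
    y01 = y.y
    if len(np.unique(y01)) < 2:
        raise ValueError("training labels contain a single class")
    if arr.shape[0] < 4 or min(np.bincount(y01)) < 2:
        raise ValueError("need at least 2 compounds per class")

    if spec.algorithm in _SCALED:
        center = arr.mean(axis=0)
        scale = arr.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
    else:
        center = np.zeros(arr.shape[1])
        scale = np.ones(arr.shape[1])
    Z = (arr - center) / scale

    est = _build_estimator(spec, arr.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Z, y01)
    train_acc = float(np.mean(np.asarray(est.predict(Z)).astype(int) == y01))
    return TrainedModel(
        spec=spec,
        feature_names=names,
        property=y.property,
        estimator=est,
        center=center,
        scale=scale,
        training_accuracy=train_acc,
    )


def predict(model: TrainedModel, X) -> PropertyLabels:
    """Functional form of :meth:`TrainedModel.predict` returning labels."""
    if isinstance(X, DescriptorMatrix):
        ids = list(X.compound_ids)
    else:
        ids = [f"q{i}" for i in range(np.asarray(X).shape[0])]
    return PropertyLabels(ids, model.property, model.predict(X))


def prediction_table(models: dict[str, TrainedModel], X: DescriptorMatrix) -> pd.DataFrame:
    """Five-property call table: one '+'/'-' per compound per property.

    Columns follow the conventional report order ``Caco2 PGPS PGPI OB HIA``
    (restricted to the properties supplied).
    """
    cols = [p for p in PROPERTIES if p in models] + [
        p for p in models if p not in PROPERTIES
    ]
    data = {p: models[p].predict(X) for p in cols}
    return pd.DataFrame(data, index=X.compound_ids, columns=cols)
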