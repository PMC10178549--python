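"""The three origin classifiers behind one train/predict contract.

* **Random forest**: bagged depth-limited decision trees, a random feature
  subset per split, unpruned; prediction is a majority vote with ties broken
  toward the smallest class code. The ensemble is assembled tree-by-tree so
  the voting contract is explicit.
* **RBF SVM**: one-vs-one support vector machine with kernel
  ``exp(-||x - z||^2 / sigma^2)``; features are standardized on the training
  partition and ``sigma`` defaults to the median pairwise training distance.
* **CNN**: each sample's selected-wavelength vector x becomes the rank-1
  outer-product matrix ``S = x x^T``, classified by the 2-D network of
  :mod:`ovotrace.cnn`.

Every fitted classifier is self-describing: it carries its config, the
selected wavelengths it was trained on, and (for MSC pipelines) the
preprocessing reference, and serializes to a single file.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ovotrace.cnn import CNNSpec, OuterProductCNN, TrainConfig, outer_product
from ovotrace.core import SpectraTable
from ovotrace.errors import ParameterError, ValidationError

__all__ = [
    "CNNSpec",
    "TrainConfig",
    "RFConfig",
    "SVMConfig",
    "outer_product",
    "train_cnn",
    "train_rf",
    "train_svm",
    "predict",
    "save_classifier",
    "load_classifier",
]


@dataclass(frozen=True)
class RFConfig:
    """Forest size and tree shape; defaults follow the reference model
    (10 trees of depth 2) with sqrt(M) features considered per split."""

    n_trees: int = 10
    max_depth: int = 2
    features_per_split: int | str = "sqrt"

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1:
            raise ParameterError("n_trees and max_depth must be >= 1")


@dataclass(frozen=True)
class SVMConfig:
    """RBF kernel width sigma (None = median heuristic) and penalty C."""

    sigma: float | None = None
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if self.C <= 0:
            raise ParameterError("C must be > 0")


class _FittedBase:
    """Common bookkeeping: feature count / wavelength check on predict."""

    wavelengths_nm: np.ndarray

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.wavelengths_nm.size:
            raise ValidationError(
                f"feature count {X.shape[1]} does not match the "
                f"{self.wavelengths_nm.size} wavelengths used in training"
            )
        return X


class RandomForestOriginClassifier(_FittedBase):
    """Bagged decision trees with explicit majority voting."""

    def __init__(self, cfg: RFConfig, wavelengths_nm: np.ndarray):
        self.cfg = cfg
        self.wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        self.trees: list[DecisionTreeClassifier] = []
        self.constant_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int) -> "RandomForestOriginClassifier":
        X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            warnings.warn(
                "single-class training data: returning a constant predictor",
                stacklevel=2,
            )
            self.constant_ = int(y[0])
            return self
        rng = np.random.default_rng(seed)
        n = len(y)
        for _ in range(self.cfg.n_trees):
            boot = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(
                max_depth=self.cfg.max_depth,
                max_features=self.cfg.features_per_split,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees.append(tree)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self._check(X)
        if self.constant_ is not None:
            return np.full(X.shape[0], self.constant_, dtype=int)
        votes = np.zeros((X.shape[0], 3), dtype=int)
        for tree in self.trees:
            pred = tree.predict(X).astype(int)
            votes[np.arange(X.shape[0]), pred] += 1
        # argmax returns the first maximum: ties go to the smallest class code
        return votes.argmax(axis=1)


class SVMOriginClassifier(_FittedBase):
    """Standardizer + one-vs-one RBF SVC; exposes sigma actually used."""

    def __init__(self, cfg: SVMConfig, wavelengths_nm: np.ndarray):
        self.cfg = cfg
        self.wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        self.scaler = StandardScaler()
        self.svc: SVC | None = None
        self.sigma_: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMOriginClassifier":
        X = np.asarray(X, dtype=float)
        Z = self.scaler.fit_transform(X)
        if self.cfg.sigma is not None:
            self.sigma_ = self.cfg.sigma
        else:
            # median heuristic on pairwise distances of standardized features
            d2 = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=-1)
            med = float(np.median(np.sqrt(d2[np.triu_indices(len(Z), k=1)])))
            self.sigma_ = med if med > 0 else 1.0
        self.svc = SVC(C=self.cfg.C, kernel="rbf", gamma=1.0 / self.sigma_**2)
        self.svc.fit(Z, np.asarray(y, dtype=int))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self._check(X)
        assert self.svc is not None
        return self.svc.predict(self.scaler.transform(X)).astype(int)


class CNNOriginClassifier(_FittedBase):
    """Outer-product matrix construction + the NumPy CNN."""

    def __init__(
        self, spec: CNNSpec, cfg: TrainConfig, wavelengths_nm: np.ndarray
    ):
        self.spec = spec
        self.cfg = cfg
        self.wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        self.net: OuterProductCNN | None = None

    @staticmethod
    def _stack(X: np.ndarray) -> np.ndarray:
        return np.einsum("ni,nj->nij", X, X)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNOriginClassifier":
        X = np.asarray(X, dtype=float)
        self.net = OuterProductCNN(side=X.shape[1], spec=self.spec, seed=self.cfg.seed)
        self.net.fit(self._stack(X), np.asarray(y, dtype=int), self.cfg)
        return self

    @property
    def loss_history(self) -> list[float]:
        assert self.net is not None
        return self.net.loss_history

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = self._check(X)
        assert self.net is not None
        return self.net.predict(self._stack(X))


def _require_labels(table: SpectraTable) -> None:
    if table.y is None:
        raise ValidationError("training requires origin labels")


def train_rf(
    table: SpectraTable, cfg: RFConfig | None = None, seed: int = 0
) -> RandomForestOriginClassifier:
    """Train the bagged-tree origin classifier on selected wavelengths."""
    _require_labels(table)
    cfg = cfg or RFConfig()
    return RandomForestOriginClassifier(cfg, table.wavelengths_nm).fit(
        table.X, table.y, seed
    )


def train_svm(
    table: SpectraTable, cfg: SVMConfig | None = None
) -> SVMOriginClassifier:
    """Train the RBF SVM origin classifier on selected wavelengths."""
    _require_labels(table)
    cfg = cfg or SVMConfig()
    return SVMOriginClassifier(cfg, table.wavelengths_nm).fit(table.X, table.y)


def train_cnn(
    table: SpectraTable,
    spec: CNNSpec | None = None,
    cfg: TrainConfig | None = None,
) -> CNNOriginClassifier:
    """Train the outer-product CNN origin classifier on selected wavelengths."""
    _require_labels(table)
    if table.n_wavelengths < 2:
        raise ParameterError(
            "the CNN needs >= 2 selected wavelengths (outer-product side >= 2)"
        )
    spec = spec or CNNSpec()
    cfg = cfg or TrainConfig()
    return CNNOriginClassifier(spec, cfg, table.wavelengths_nm).fit(table.X, table.y)


def predict(classifier: _FittedBase, table: SpectraTable) -> np.ndarray:
    """Predict origin codes for every sample in the (restricted) table."""
    return classifier.predict(table.X)


def save_classifier(classifier: _FittedBase, path: str | Path) -> Path:
    """Serialize a fitted classifier (with config + wavelengths) to one file."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(classifier, fh)
    return path


def load_classifier(path: str | Path) -> _FittedBase:
    with open(path, "rb") as fh:
        return pickle.load(fh)
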