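"""The three activity classifiers behind one train/predict contract.

* **KNN** — majority vote among the K nearest training instances by
  Euclidean distance on min-max-scaled features; ties are broken toward the
  candidate class with the smallest mean neighbor distance, then label order.
* **Rotation forest** — an ensemble of M axis-aligned decision trees, each
  trained on the data rotated by a block-diagonal matrix of principal axes:
  features are randomly partitioned into small subsets and each subset's
  principal axes are computed on a bootstrap sample of a random subset of
  classes, which decorrelates the trees while keeping every tree a full-
  feature learner.
* **MLP** — a single-hidden-layer sigmoid network trained by back-propagation
  with momentum (defaults: (features + classes) / 2 hidden units, learning
  rate 0.3, momentum 0.2, 500 epochs — the classic toolkit convention).

All stochastic steps derive from the spec's seed, so training and prediction
are reproducible bit-for-bit.  Feature scaling is min-max fitted on training
data only; a constant training feature scales to 0 everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import joblib
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import DomainError, SchemaError
from .features import FeatureMatrix

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ClassifierSpec:
    """Kind plus hyperparameters of one classifier."""

    kind: Literal["knn", "rotation_forest", "mlp"]
    k: int = 3                              # KNN neighbors
    ensemble_size: int = 10                 # rotation forest: M trees
    rotation_subset_size: int = 3           # features per rotation block
    class_bootstrap_fraction: float = 0.75  # sample fraction for each block's PCA
    hidden_units: int | None = None         # MLP; None = (features + classes) // 2
    learning_rate: float = 0.3
    momentum: float = 0.2
    epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "rotation_forest", "mlp"):
            raise DomainError(f"unknown classifier kind {self.kind!r}")
        if self.k < 1 or self.ensemble_size < 1 or self.rotation_subset_size < 1:
            raise DomainError("K, ensemble size and rotation subset size must be >= 1")


@dataclass(frozen=True)
class MinMaxScaler:
    """Per-feature min-max parameters fitted on training data only.

    Constant features get a unit range so they scale to 0 everywhere;
    test-set values outside the training range map outside [0, 1], which is
    the intended behavior (the scaler must not peek at test data).
    """

    mins: np.ndarray
    ranges: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mins) / self.ranges


def fit_scaler(train: FeatureMatrix) -> MinMaxScaler:
    if len(train) == 0:
        raise DomainError("cannot fit a scaler on an empty matrix")
    mins = train.values.min(axis=0)
    ranges = train.values.max(axis=0) - mins
    ranges = np.where(ranges <= 0, 1.0, ranges)  # constant-feature guard
    return MinMaxScaler(mins, ranges)


@dataclass
class TrainedModel:
    """A fitted classifier: spec, scaler, class vocabulary and model state."""

    spec: ClassifierSpec
    scaler: MinMaxScaler
    classes: np.ndarray
    feature_names: list[str]
    state: dict = field(default_factory=dict)
    version: int = MODEL_FORMAT_VERSION


def train(spec: ClassifierSpec, train_fm: FeatureMatrix) -> TrainedModel:
    """Fit one classifier on a feature matrix (>= 2 classes, finite values)."""
    classes = np.unique(train_fm.labels)
    if len(classes) < 2:
        raise DomainError("training set has a single class")
    if not np.isfinite(train_fm.values).all():
        raise DomainError("training matrix contains non-finite values")
    scaler = fit_scaler(train_fm)
    X = scaler.transform(train_fm.values)
    y = train_fm.labels
    # canonical row order (label-major, then features) makes training, and
    # hence prediction, invariant to the order instances arrive in
    order = np.lexsort(tuple(X.T) + (y,))
    X, y = X[order], y[order]
    if spec.kind == "knn":
        state = {"X": X, "y": y}
    elif spec.kind == "rotation_forest":
        state = _train_rotation_forest(spec, X, y, classes)
    else:
        state = _train_mlp(spec, X, y, classes)
    return TrainedModel(spec, scaler, classes, list(train_fm.names), state)


def predict(model: TrainedModel, fm: FeatureMatrix) -> np.ndarray:
    """Predict labels for a feature matrix whose columns match training."""
    if list(fm.names) != model.feature_names:
        raise SchemaError("feature names do not match the training matrix")
    X = model.scaler.transform(fm.values)
    if model.spec.kind == "knn":
        return _predict_knn(model, X)
    if model.spec.kind == "rotation_forest":
        return _predict_rotation_forest(model, X)
    return model.state["net"].predict(X)


# --------------------------------------------------------------------------
# KNN
# --------------------------------------------------------------------------


def _predict_knn(model: TrainedModel, X: np.ndarray, chunk: int = 512) -> np.ndarray:
    spec = model.spec
    Xtr, ytr = model.state["X"], model.state["y"]
    k = min(spec.k, len(Xtr))
    out = np.empty(len(X), dtype=ytr.dtype)
    for lo in range(0, len(X), chunk):
        D = cdist(X[lo : lo + chunk], Xtr)
        # k smallest distances per query; stable ordering for determinism
        nn = np.argsort(D, axis=1, kind="stable")[:, :k]
        for r in range(len(nn)):
            out[lo + r] = _majority(ytr[nn[r]], D[r][nn[r]], model.classes)
    return out


def _majority(labels: np.ndarray, dists: np.ndarray, vocab: np.ndarray):
    """Majority label; ties -> smallest mean neighbor distance -> label order."""
    best = None
    for c in vocab:
        mask = labels == c
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        mean_d = float(dists[mask].mean())
        key = (-cnt, mean_d)  # label order via vocab iteration breaks final ties
        if best is None or key < best[0]:
            best = (key, c)
    return best[1]


# --------------------------------------------------------------------------
# Rotation forest
# --------------------------------------------------------------------------


def _principal_axes(sample: np.ndarray) -> np.ndarray:
    """All principal axes (columns orthonormal) of a centered sample; identity fallback."""
    d = sample.shape[1]
    if len(sample) < 2:
        return np.eye(d)
    centered = sample - sample.mean(axis=0)
    cov = centered.T @ centered / max(len(sample) - 1, 1)
    try:
        vals, vecs = np.linalg.eigh(cov)
    except np.linalg.LinAlgError:
        return np.eye(d)
    order = np.argsort(vals)[::-1]
    return vecs[:, order]


def _train_rotation_forest(spec, X, y, classes) -> dict:
    rng = np.random.default_rng(spec.seed)
    n, width = X.shape
    trees = []
    for m in range(spec.ensemble_size):
        perm = rng.permutation(width)
        blocks = [perm[i : i + spec.rotation_subset_size]
                  for i in range(0, width, spec.rotation_subset_size)]
        rotation = np.zeros((width, width))
        for block in blocks:
            # random nonempty subset of classes, then a bootstrap of the
            # configured fraction of their instances, for this block's PCA
            keep = classes[rng.random(len(classes)) < 0.5]
            if len(keep) == 0:
                keep = classes[[rng.integers(len(classes))]]
            rows = np.flatnonzero(np.isin(y, keep))
            size = max(2, int(round(spec.class_bootstrap_fraction * len(rows))))
            boot = rng.choice(rows, size=size, replace=True) if len(rows) else rows
            axes = _principal_axes(X[boot][:, block]) if len(boot) else np.eye(len(block))
            rotation[np.ix_(block, block)] = axes
        Xrot = X @ rotation
        tree = DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=2,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(Xrot, y)
        trees.append({"rotation": rotation, "tree": tree})
    return {"trees": trees}


def _predict_rotation_forest(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    votes = np.zeros((len(X), len(model.classes)))
    class_pos = {c: i for i, c in enumerate(model.classes)}
    for member in model.state["trees"]:
        proba = member["tree"].predict_proba(X @ member["rotation"])
        cols = [class_pos[c] for c in member["tree"].classes_]
        votes[:, cols] += proba
    # argmax returns the first maximum -> label-order tie-break (classes sorted)
    return model.classes[np.argmax(votes, axis=1)]


# --------------------------------------------------------------------------
# MLP
# --------------------------------------------------------------------------


def _train_mlp(spec, X, y, classes) -> dict:
    hidden = spec.hidden_units or max(1, (X.shape[1] + len(classes)) // 2)
    net = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="sgd",
        learning_rate_init=spec.learning_rate,
        momentum=spec.momentum,
        nesterovs_momentum=False,
        max_iter=spec.epochs,
        alpha=0.0,
        tol=1e-6,
        random_state=spec.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(X, y)
    return {"net": net}


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------


def save_model(model: TrainedModel, path) -> None:
    """Versioned archive with the spec and seeds recorded alongside the state."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise SchemaError(f"unsupported model archive version in {path}")
    return payload["model"]
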