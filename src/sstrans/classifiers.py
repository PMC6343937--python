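"""The four classifier families used in the translation benchmark.

Every family is wrapped behind one contract: a fitted model exposes, for a
batch of samples in the selected feature space, a hard label drawn from the
two training classes and a per-sample confidence in [0, 1].  Confidence is
only ever *ranked* within a prediction batch (the self-training loop admits
the top fraction of human samples by confidence), so each family defines it
in whatever form is natural:

* KNN (k = 3): the fraction of the 3 nearest neighbors voting the predicted
  label, i.e. 2/3 or 1.
* SVM (linear kernel): |decision value| rank-normalized to [0, 1] within
  the batch.  Fitting a probability calibration on cohorts of 8-40 samples
  is not meaningful; the rank is all the loop consumes.
* RF (50 trees): the fraction of trees voting the predicted (majority)
  label, in [0.5, 1].
* NN: the maximum of the two softmax outputs.

The NN is a three-layer feed-forward network: one input node per feature,
two output nodes (one per class, normalized to sum to 1), and a hidden
layer of ceil((n_in + n_out) / 2) tanh units, trained by full-batch
quasi-Newton minimization (L-BFGS) of the cross-entropy to tolerance 1e-6
or a 500-iteration cap.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import CONTROL, DISEASE, ExpressionDataset
from .feature_selection import FeatureSet

logger = logging.getLogger(__name__)

FAMILIES = ("knn", "svm", "rf", "nn")

KNN_NEIGHBORS = 3
RF_TREES = 50
NN_MAX_ITER = 500
NN_TOL = 1e-6


@dataclass(frozen=True)
class NNArchitecture:
    """Layer sizes of the feed-forward network."""

    n_input: int
    n_output: int = 2

    @property
    def n_hidden(self) -> int:
        # hidden layer = average of input and output node counts, rounded up
        return math.ceil((self.n_input + self.n_output) / 2)


@dataclass
class TrainedClassifier:
    """A fitted model exposing hard labels plus ranking confidences."""

    family: str
    feature_genes: list[str]
    classes: tuple[str, str]
    model_state: Any = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predict a batch; returns (labels, confidences in [0, 1])."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_genes):
            raise ValueError(
                f"expected (n, {len(self.feature_genes)}) matrix, got {X.shape}")
        if self.family == "knn":
            return self._predict_knn(X)
        if self.family == "svm":
            return self._predict_svm(X)
        if self.family == "rf":
            return self._predict_rf(X)
        if self.family == "nn":
            return self._predict_nn(X)
        raise ValueError(f"unknown family {self.family!r}")

    def predict_dataset(self, ds: ExpressionDataset) -> tuple[pd.Series, pd.Series]:
        """Predict every sample of a dataset (rows subset to the features)."""
        X = ds.values.loc[self.feature_genes].to_numpy(dtype=float).T
        labels, conf = self.predict(X)
        return (pd.Series(labels, index=ds.sample_ids),
                pd.Series(conf, index=ds.sample_ids))

    # -- per-family prediction ------------------------------------------
    def _predict_knn(self, X):
        model: KNeighborsClassifier = self.model_state
        proba = model.predict_proba(X)
        idx = np.argmax(proba, axis=1)
        labels = model.classes_[idx]
        conf = proba[np.arange(len(X)), idx]
        return labels, conf

    def _predict_svm(self, X):
        model: SVC = self.model_state
        labels = model.predict(X)
        d = np.abs(model.decision_function(X))
        if len(d) == 1:
            conf = np.ones(1)
        else:
            conf = (rankdata(d, method="average") - 1.0) / (len(d) - 1.0)
        return labels, conf

    def _predict_rf(self, X):
        model: RandomForestClassifier = self.model_state
        votes = np.stack([tree.predict(X) for tree in model.estimators_])
        frac_disease = (votes == 1).mean(axis=0)
        # majority vote of the trees; >= breaks exact 25/25 splits toward
        # the positive class deterministically (50 trees: tie possible)
        is_disease = frac_disease >= 0.5
        labels = np.where(is_disease, DISEASE, CONTROL)
        conf = np.where(is_disease, frac_disease, 1.0 - frac_disease)
        return labels, conf

    def _predict_nn(self, X):
        net: _SoftmaxNet = self.model_state
        proba = net.predict_proba(X)
        idx = np.argmax(proba, axis=1)
        labels = np.asarray(self.classes, dtype=object)[idx]
        conf = proba[np.arange(len(X)), idx]
        return labels, conf


def _check_training(ds: ExpressionDataset, features: FeatureSet | list[str]):
    genes = features.genes if isinstance(features, FeatureSet) else list(features)
    if not genes:
        raise ValueError("empty feature set")
    missing = [g for g in genes if g not in set(ds.gene_ids)]
    if missing:
        raise ValueError(f"features not in dataset: {missing[:5]}")
    if not ds.has_both_classes():
        raise ValueError(f"training requires both classes; got {ds.class_counts()}")
    X = ds.values.loc[genes].to_numpy(dtype=float).T
    y = ds.labels.to_numpy()
    return genes, X, y


def train_knn(ds: ExpressionDataset, features: FeatureSet | list[str]) -> TrainedClassifier:
    """3-nearest-neighbor classifier (Euclidean distance in feature space)."""
    genes, X, y = _check_training(ds, features)
    if len(y) < KNN_NEIGHBORS:
        raise ValueError(f"KNN requires >= {KNN_NEIGHBORS} training samples, got {len(y)}")
    model = KNeighborsClassifier(n_neighbors=KNN_NEIGHBORS, metric="euclidean")
    model.fit(X, y)
    return TrainedClassifier("knn", genes, (CONTROL, DISEASE), model)


def train_svm(ds: ExpressionDataset, features: FeatureSet | list[str]) -> TrainedClassifier:
    """Linear-kernel maximum-margin classifier."""
    genes, X, y = _check_training(ds, features)
    model = SVC(kernel="linear", C=1.0)
    model.fit(X, y)
    return TrainedClassifier("svm", genes, (CONTROL, DISEASE), model)


def train_rf(ds: ExpressionDataset, features: FeatureSet | list[str],
             seed: int = 0) -> TrainedClassifier:
    """Bagged ensemble of 50 trees; sqrt(p) features per split, full depth."""
    genes, X, y = _check_training(ds, features)
    model = RandomForestClassifier(n_estimators=RF_TREES, max_features="sqrt",
                                   random_state=seed % (2 ** 31), n_jobs=1)
    model.fit(X, (y == DISEASE).astype(int))
    return TrainedClassifier("rf", genes, (CONTROL, DISEASE), model)


class _SoftmaxNet:
    """tanh-hidden, softmax-output network trained by full-batch L-BFGS."""

    def __init__(self, arch: NNArchitecture, seed: int = 0, l2: float = 1e-4):
        self.arch = arch
        self.l2 = l2
        rng = np.random.default_rng(seed % (2 ** 31))
        p, h, k = arch.n_input, arch.n_hidden, arch.n_output
        self.W1 = rng.normal(scale=1.0 / np.sqrt(p), size=(p, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(scale=1.0 / np.sqrt(h), size=(h, k))
        self.b2 = np.zeros(k)
        self.converged: bool | None = None

    # -- parameter (un)flattening
    def _pack(self):
        return np.concatenate([self.W1.ravel(), self.b1, self.W2.ravel(), self.b2])

    def _unpack(self, theta):
        p, h, k = self.arch.n_input, self.arch.n_hidden, self.arch.n_output
        i = 0
        W1 = theta[i:i + p * h].reshape(p, h); i += p * h
        b1 = theta[i:i + h]; i += h
        W2 = theta[i:i + h * k].reshape(h, k); i += h * k
        b2 = theta[i:i + k]
        return W1, b1, W2, b2

    @staticmethod
    def _softmax(z):
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _loss_grad(self, theta, X, Y):
        W1, b1, W2, b2 = self._unpack(theta)
        n = len(X)
        A1 = np.tanh(X @ W1 + b1)
        P = self._softmax(A1 @ W2 + b2)
        eps = 1e-12
        loss = -np.sum(Y * np.log(P + eps)) / n
        loss += 0.5 * self.l2 * (np.sum(W1 ** 2) + np.sum(W2 ** 2))
        dZ2 = (P - Y) / n
        gW2 = A1.T @ dZ2 + self.l2 * W2
        gb2 = dZ2.sum(axis=0)
        dA1 = dZ2 @ W2.T
        dZ1 = dA1 * (1.0 - A1 ** 2)
        gW1 = X.T @ dZ1 + self.l2 * W1
        gb1 = dZ1.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
        return loss, grad

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "_SoftmaxNet":
        res = minimize(self._loss_grad, self._pack(), args=(X, Y), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": NN_MAX_ITER, "ftol": NN_TOL,
                                "gtol": NN_TOL})
        self.W1, self.b1, self.W2, self.b2 = self._unpack(res.x)
        self.converged = bool(res.success)
        if not res.success:
            warnings.warn(f"NN training stopped before convergence: {res.message}")
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        A1 = np.tanh(X @ self.W1 + self.b1)
        return self._softmax(A1 @ self.W2 + self.b2)


def train_nn(ds: ExpressionDataset, features: FeatureSet | list[str],
             seed: int = 0) -> TrainedClassifier:
    """Three-layer softmax network (hidden = ceil((n_in + 2)/2) tanh units)."""
    genes, X, y = _check_training(ds, features)
    arch = NNArchitecture(n_input=len(genes))
    Y = np.zeros((len(y), 2))
    Y[np.arange(len(y)), (y == DISEASE).astype(int)] = 1.0
    net = _SoftmaxNet(arch, seed=seed).fit(X, Y)
    return TrainedClassifier("nn", genes, (CONTROL, DISEASE), net)


def train_classifier(family: str, ds: ExpressionDataset,
                     features: FeatureSet | list[str], seed: int = 0) -> TrainedClassifier:
    """Dispatch on family name; seed is ignored by the deterministic families."""
    if family == "knn":
        return train_knn(ds, features)
    if family == "svm":
        return train_svm(ds, features)
    if family == "rf":
        return train_rf(ds, features, seed=seed)
    if family == "nn":
        return train_nn(ds, features, seed=seed)
    raise ValueError(f"unknown classifier family {family!r}; choose from {FAMILIES}")
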