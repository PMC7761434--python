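"""Back-propagation network classifier and repeated k-fold cross-validation.

The classifier is a single-hidden-layer feed-forward network: sigmoid hidden
units (default 6), identity (purely linear) output units — one per class —
trained by full-batch gradient descent on the mean squared error between the
linear outputs and one-hot targets. Prediction is the argmax over the output
units (ties resolve to the first class in ``classes_``).

The evaluation protocol is repeated stratified k-fold cross-validation
(default 10 x 10-fold), training a fresh network per fold and recording the
held-out accuracy in percent; the resulting population of k x repeats
accuracies is the unit of the statistical comparison in :mod:`wcmfe.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["NetConfig", "BPNetClassifier", "CVResult", "repeated_kfold_cv"]


@dataclass(frozen=True)
class NetConfig:
    """Default training hyper-parameters of the BP network.

    The source protocol fixes the architecture (input = feature length,
    6 sigmoid hidden units, 2 linear outputs, MSE loss) but not the training
    regime; these defaults — plain gradient descent at rate 0.05, at most
    2000 epochs with a loss-plateau stop, small uniform seeded init — are the
    package's own and are all overridable.
    """

    hidden_dim: int = 6
    learning_rate: float = 0.05
    max_epochs: int = 2000
    tol: float = 1e-6
    n_iter_no_change: int = 50
    init_scale: float = 0.5
    standardize: bool = True


class BPNetClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward sigmoid/linear network trained with MSE back-propagation.

    Parameters mirror :class:`NetConfig`; ``random_state`` seeds the weight
    initialisation. Inputs are optionally z-scored with training-set
    statistics (``standardize=True``, the default) before entering the
    sigmoid layer.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    coefs_, intercepts_ : list of ndarray
        ``[W_hidden, W_out]`` and ``[b_hidden, b_out]``.
    loss_curve_ : list of float
        MSE after each epoch.
    n_iter_ : int
        Epochs actually run.
    """

    def __init__(self, hidden_dim: int = 6, learning_rate: float = 0.05,
                 max_epochs: int = 2000, tol: float = 1e-6,
                 n_iter_no_change: int = 50, init_scale: float = 0.5,
                 standardize: bool = True, random_state=None):
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.tol = tol
        self.n_iter_no_change = n_iter_no_change
        self.init_scale = init_scale
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        self.n_features_in_ = X.shape[1]
        n_out = len(self.classes_)
        Y = np.zeros((X.shape[0], n_out))
        for j, cls in enumerate(self.classes_):
            Y[y == cls, j] = 1.0

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0.0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(self.n_features_in_)
            self.scale_ = np.ones(self.n_features_in_)
        Xs = (X - self.mean_) / self.scale_

        rng = np.random.default_rng(self.random_state)
        s = self.init_scale
        W1 = rng.uniform(-s, s, size=(self.n_features_in_, self.hidden_dim))
        b1 = rng.uniform(-s, s, size=self.hidden_dim)
        W2 = rng.uniform(-s, s, size=(self.hidden_dim, n_out))
        b2 = rng.uniform(-s, s, size=n_out)

        lr = self.learning_rate
        self.loss_curve_ = []
        for epoch in range(self.max_epochs):
            H = expit(Xs @ W1 + b1)
            O = H @ W2 + b2
            E = O - Y
            self.loss_curve_.append(float((E ** 2).mean()))
            dO = (2.0 / E.size) * E
            dW2 = H.T @ dO
            db2 = dO.sum(axis=0)
            dH = dO @ W2.T
            dZ = dH * H * (1.0 - H)
            dW1 = Xs.T @ dZ
            db1 = dZ.sum(axis=0)
            W2 -= lr * dW2
            b2 -= lr * db2
            W1 -= lr * dW1
            b1 -= lr * db1
            # plateau stop: no meaningful improvement over the last window
            nw = self.n_iter_no_change
            if epoch + 1 >= nw + 1:
                if self.loss_curve_[-nw - 1] - self.loss_curve_[-1] < self.tol:
                    break
        self.n_iter_ = len(self.loss_curve_)
        self.coefs_ = [W1, W2]
        self.intercepts_ = [b1, b2]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw linear outputs, one column per class."""
        check_is_fitted(self, "coefs_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        Xs = (X - self.mean_) / self.scale_
        H = expit(Xs @ self.coefs_[0] + self.intercepts_[0])
        return H @ self.coefs_[1] + self.intercepts_[1]

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


@dataclass(frozen=True)
class CVResult:
    """Accuracies (%) of repeated k-fold cross-validation."""

    accuracies: np.ndarray
    k: int
    repeats: int

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracies, dtype=float)
        object.__setattr__(self, "accuracies", acc)
        if acc.size != self.k * self.repeats:
            raise ValueError(
                f"expected {self.k * self.repeats} accuracies, got {acc.size}"
            )

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation (ddof=1) of the fold accuracies."""
        return float(self.accuracies.std(ddof=1))


def repeated_kfold_cv(X, y, k: int = 10, repeats: int = 10, estimator=None,
                      seed: int = 0, return_indices: bool = False):
    """Repeated stratified k-fold CV with a fresh network per fold.

    Every repeat reshuffles the stratified folds with a seed derived from
    ``seed``; each fold clones ``estimator`` (default
    :class:`BPNetClassifier`), re-seeds its initialisation, trains on the
    fold's training split and scores the held-out split in percent. With
    ``return_indices=True`` also returns the list of (train, test) index
    arrays for fold audits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of samples {X.shape[0]}")
    if estimator is None:
        estimator = BPNetClassifier()
    master = np.random.default_rng(seed)
    accs = []
    indices = []
    for _ in range(repeats):
        fold_seed = int(master.integers(2 ** 31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
        for train_idx, test_idx in skf.split(X, y):
            model = clone(estimator)
            if "random_state" in model.get_params():
                model.set_params(random_state=int(master.integers(2 ** 31)))
            model.fit(X[train_idx], y[train_idx])
            pred = model.predict(X[test_idx])
            accs.append(100.0 * float(np.mean(pred == y[test_idx])))
            if return_indices:
                indices.append((train_idx, test_idx))
    result = CVResult(accuracies=np.asarray(accs), k=k, repeats=repeats)
    return (result, indices) if return_indices else result
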