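"""Sample-set splitting, discriminant models and evaluation.

Three discriminant models classify mean spectra into four origin classes:

* **ELM** (extreme learning machine): a single-hidden-layer network whose
  input weights and biases are drawn uniformly in [-1, 1] and frozen; only
  the output weights are learned, by a least-squares (pseudoinverse) solve
  against one-hot class targets.  The single hyperparameter is the hidden
  node count h, searched over 1..150 for minimum training error.
* **NN-RBF**: an exact-design radial-basis-function network with one
  Gaussian unit per calibration sample.  Hidden response is
  ``exp(-(0.8326 * r / s)**2)`` with r the Euclidean distance to the center
  and s the spread, so the response is 0.5 at r = s.  Output weights by
  linear least squares; the spread is chosen on a grid (0.1..1 and 1..100)
  by cross-validated recognition rate.
* **SVM**: RBF-kernel soft-margin classifier (one-vs-one), delegated to
  scikit-learn; the contract here is the power-of-two (c, g) grid search and
  reporting.

Calibration/prediction sets come from the deterministic Kennard-Stone
max-min-distance procedure, stratified per class at a 2:1 ratio.
Accuracies are macro means: the unweighted average of per-class accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .preprocess import SpectralDataset

__all__ = [
    "SplitResult",
    "EvalReport",
    "ELMClassifier",
    "RBFNetClassifier",
    "kennard_stone_indices",
    "kennard_stone_split",
    "train_elm",
    "search_elm",
    "train_rbf_net",
    "train_svm",
    "evaluate",
    "DEFAULT_SPREAD_GRID",
    "DEFAULT_SVM_GRID",
]

#: Spread grid: 0.1..1 step 0.1, then 1..100 step 1.
DEFAULT_SPREAD_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10)) + tuple(
    float(s) for s in range(1, 101))

#: Powers-of-two grid covering c in [2^-5, 2^10], g in [2^-10, 2^5].
DEFAULT_SVM_GRID = {
    "svc__C": [2.0 ** p for p in range(-5, 11)],
    "svc__gamma": [2.0 ** p for p in range(-10, 6)],
}


@dataclass
class SplitResult:
    """Disjoint calibration/prediction id lists from a deterministic split."""

    calibration_ids: np.ndarray
    prediction_ids: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        cal = set(map(int, self.calibration_ids))
        pred = set(map(int, self.prediction_ids))
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")


@dataclass
class EvalReport:
    """Confusion matrix and macro-mean accuracy for one model on one set."""

    confusion: np.ndarray           # (C, C) counts, rows = true class
    per_class_accuracy: np.ndarray  # (C,) percentages
    mean_accuracy: float            # unweighted mean of per-class accuracies
    classes: np.ndarray
    set_name: str

    def to_frame(self) -> pd.DataFrame:
        cols = {str(c): [round(a, 2)] for c, a in
                zip(self.classes, self.per_class_accuracy)}
        cols["Mean"] = [round(self.mean_accuracy, 2)]
        return pd.DataFrame(cols, index=[self.set_name])


def macro_mean_accuracy(per_class: np.ndarray) -> float:
    """Unweighted mean of per-class accuracies — the tables' "Mean" rule."""
    return float(np.mean(np.asarray(per_class, dtype=float)))


# ---------------------------------------------------------------------------
# Kennard-Stone
# ---------------------------------------------------------------------------

def kennard_stone_indices(X: np.ndarray, n_select: int) -> np.ndarray:
    """Classic Kennard-Stone max-min selection on Euclidean distances.

    Seeds with the two mutually farthest points, then repeatedly adds the
    point whose minimum distance to the selected set is largest, until
    ``n_select`` points are chosen.  Entirely deterministic; ties break on
    the smallest row index, so permuting the input changes nothing beyond
    the corresponding index permutation.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n_select < 2:
        raise ValueError("Kennard-Stone needs at least two selected points")
    if n_select > n:
        raise ValueError("cannot select more points than available")
    dist = cdist(X, X)
    # farthest pair; argmax of flattened upper triangle, smallest-index tie-break
    iu = np.triu_indices(n, k=1)
    flat = dist[iu]
    best = np.argmax(flat)
    first, second = int(iu[0][best]), int(iu[1][best])
    selected = [first, second]
    min_dist = np.minimum(dist[first], dist[second])
    min_dist[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_dist))   # np.argmax takes the first maximum
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    return np.array(selected, dtype=int)


def kennard_stone_split(ds: SpectralDataset, ratio: float = 2.0,
                        per_class: bool = True) -> SplitResult:
    """Stratified Kennard-Stone calibration/prediction split.

    ``ratio`` is calibration:prediction (2.0 means 2:1, i.e. 200 of each 300
    per origin go to calibration).  When ``per_class`` the procedure runs
    within each class so per-class quotas are honored exactly.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    frac = ratio / (1.0 + ratio)

    def quota(n: int) -> int:
        q = min(int(round(n * frac)), n)
        if q < 2:
            raise ValueError(
                f"ratio {ratio} yields {q} calibration point(s); need >= 2")
        return q

    if per_class and ds.y is not None:
        cal_ids = []
        for cls in np.unique(ds.y):
            rows = np.nonzero(ds.y == cls)[0]
            if rows.size < 2:
                raise ValueError(f"class {cls} has fewer than 2 samples")
            local = kennard_stone_indices(ds.X[rows], quota(rows.size))
            cal_ids.extend(ds.ids[rows[local]])
        cal_ids = np.array(sorted(cal_ids))
    else:
        local = kennard_stone_indices(ds.X, quota(ds.n_samples))
        cal_ids = np.array(sorted(ds.ids[local]))
    pred_ids = np.array(sorted(set(map(int, ds.ids)) - set(map(int, cal_ids))))
    return SplitResult(calibration_ids=cal_ids, prediction_ids=pred_ids,
                       ratio=ratio)


# ---------------------------------------------------------------------------
# ELM
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACTIVATIONS = {"sigmoid": _sigmoid, "tanh": np.tanh}


class ELMClassifier(BaseEstimator, ClassifierMixin):
    """Extreme learning machine: random frozen hidden layer, least-squares output.

    Parameters
    ----------
    n_hidden : int
        Hidden node count h.
    activation : {"sigmoid", "tanh"}
        Hidden-unit nonlinearity; logistic sigmoid is the classic choice.
    standardize : bool
        z-score features by training statistics before the hidden layer.
    random_state : int
        Seeds the uniform [-1, 1] draw of input weights and biases, making
        the model fully reproducible.
    """

    def __init__(self, n_hidden: int = 30, activation: str = "sigmoid",
                 standardize: bool = True, random_state: int = 0):
        self.n_hidden = n_hidden
        self.activation = activation
        self.standardize = standardize
        self.random_state = random_state

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return _ACTIVATIONS[self.activation](X @ self.input_weights_.T
                                             + self.biases_)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        self.classes_ = unique_labels(y)
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        rng = np.random.default_rng(self.random_state)
        d = Xs.shape[1]
        self.input_weights_ = rng.uniform(-1.0, 1.0, size=(self.n_hidden, d))
        self.biases_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = self._hidden(Xs)
        if np.allclose(H, H[0]):
            raise ValueError("degenerate hidden matrix: all rows equal")
        T = (y[:, None] == self.classes_[None, :]).astype(float)  # one-hot
        self.output_weights_ = np.linalg.pinv(H) @ T
        return self

    def decision_function(self, X):
        check_is_fitted(self, "output_weights_")
        X = check_array(X)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return self._hidden(X) @ self.output_weights_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def train_elm(ds_cal: SpectralDataset, h: int, activation: str = "sigmoid",
              seed: int = 0) -> ELMClassifier:
    """Fit an ELM with h hidden nodes on a calibration dataset."""
    return ELMClassifier(n_hidden=h, activation=activation,
                         random_state=seed).fit(ds_cal.X, ds_cal.y)


def search_elm(ds_cal: SpectralDataset, h_range: range = range(1, 151),
               activation: str = "sigmoid", seed: int = 0
               ) -> tuple[int, ELMClassifier]:
    """Scan h over ``h_range`` and keep the smallest h with minimum training error.

    The default ceiling of 150 is configurable; hitting the ceiling triggers
    a warning since the optimum may lie beyond it.
    """
    h_values = list(h_range)
    if not h_values:
        raise ValueError("empty hidden-node range")
    best_h, best_err, best_model = None, np.inf, None
    for h in h_values:
        model = train_elm(ds_cal, h, activation, seed)
        err = float(np.mean(model.predict(ds_cal.X) != ds_cal.y))
        if err < best_err:                       # strict: smallest h wins ties
            best_h, best_err, best_model = h, err, model
    if best_h == max(h_values) and best_err > 0:
        warnings.warn(
            f"ELM search selected the range ceiling h={best_h}; the optimum "
            "may lie beyond — raise the ceiling to check", stacklevel=2)
    return best_h, best_model


# ---------------------------------------------------------------------------
# NN-RBF (exact design)
# ---------------------------------------------------------------------------

class RBFNetClassifier(BaseEstimator, ClassifierMixin):
    """Exact-design Gaussian RBF network: one hidden unit per training sample.

    Hidden response for a sample at distance r from a center is
    ``exp(-(0.8326 * r / spread)**2)``, i.e. 0.5 exactly at r = spread
    (0.8326 = sqrt(ln 2)).  Output weights and bias solve the linear
    least-squares problem against one-hot targets; a tiny ridge is added
    only if the design matrix is numerically singular (and logged).
    """

    def __init__(self, spread: float = 1.0, standardize: bool = True,
                 ridge: float = 0.0):
        self.spread = spread
        self.standardize = standardize
        self.ridge = ridge

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        self.classes_ = unique_labels(y)
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        self.centers_ = Xs.copy()
        G = self._design(Xs)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        A = np.hstack([G, np.ones((G.shape[0], 1))])   # bias column
        if self.ridge > 0:
            reg = self.ridge * np.eye(A.shape[1])
            W = np.linalg.solve(A.T @ A + reg, A.T @ T)
        else:
            W, *_ = np.linalg.lstsq(A, T, rcond=None)
            if not np.all(np.isfinite(W)):
                warnings.warn("singular RBF design; refitting with ridge 1e-8",
                              stacklevel=2)
                reg = 1e-8 * np.eye(A.shape[1])
                W = np.linalg.solve(A.T @ A + reg, A.T @ T)
        self.output_weights_ = W[:-1]
        self.bias_ = W[-1]
        return self

    def _design(self, Xs: np.ndarray) -> np.ndarray:
        r = cdist(Xs, self.centers_)
        return np.exp(-((0.8326 * r / self.spread) ** 2))

    def decision_function(self, X):
        check_is_fitted(self, "output_weights_")
        X = check_array(X)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return self._design(X) @ self.output_weights_ + self.bias_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def _cv_accuracy(make_model, X: np.ndarray, y: np.ndarray, cv: int,
                 seed: int) -> float:
    """Mean held-out accuracy of ``make_model()`` under stratified k-fold CV."""
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = make_model().fit(X[tr], y[tr])
        accs.append(np.mean(model.predict(X[te]) == y[te]))
    return float(np.mean(accs))


def train_rbf_net(ds_cal: SpectralDataset,
                  spread_grid: tuple = DEFAULT_SPREAD_GRID,
                  cv: int = 5, seed: int = 0) -> tuple[float, RBFNetClassifier]:
    """Grid-search the spread by cross-validated recognition rate, then refit.

    The recognition rate is measured by stratified k-fold cross-validation
    within the calibration set, which tunes without touching the prediction
    set; the winning spread (smallest on ties) is refit on the full
    calibration data.
    """
    if not spread_grid:
        raise ValueError("empty spread grid")
    best_s, best_acc = None, -1.0
    for s in spread_grid:
        acc = _cv_accuracy(lambda: RBFNetClassifier(spread=s),
                           ds_cal.X, ds_cal.y, cv, seed)
        if acc > best_acc:
            best_s, best_acc = float(s), acc
    model = RBFNetClassifier(spread=best_s).fit(ds_cal.X, ds_cal.y)
    return best_s, model


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

def train_svm(ds_cal: SpectralDataset, grid: dict = None, cv: int = 5,
              seed: int = 0) -> tuple[dict, Pipeline]:
    """Grid-search an RBF-kernel SVM over powers-of-two (c, g).

    One-vs-one multiclass with feature standardization inside the
    cross-validation pipeline; returns the best (c, g) and the refit model.
    """
    grid = DEFAULT_SVM_GRID if grid is None else grid
    for key in ("svc__C", "svc__gamma"):
        if any(v <= 0 for v in grid.get(key, [1.0])):
            raise ValueError("c and g must be positive")
    pipe = Pipeline([("scale", StandardScaler()),
                     ("svc", SVC(kernel="rbf", decision_function_shape="ovo"))])
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=skf, n_jobs=1)
    search.fit(ds_cal.X, ds_cal.y)
    best = {"c": search.best_params_["svc__C"],
            "g": search.best_params_["svc__gamma"]}
    return best, search.best_estimator_


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(model, ds: SpectralDataset, set_name: str = "prediction") -> EvalReport:
    """Confusion matrix, per-class accuracies and macro-mean accuracy (%)."""
    if ds.y is None:
        raise ValueError("evaluation requires labels")
    classes = getattr(model, "classes_", None)
    if classes is None:
        classes = model[-1].classes_   # pipeline
    unseen = set(map(int, np.unique(ds.y))) - set(map(int, classes))
    if unseen:
        raise ValueError(f"labels {sorted(unseen)} were not seen in training")
    y_pred = model.predict(ds.X)
    cm = confusion_matrix(ds.y, y_pred, labels=classes)
    row_sums = cm.sum(axis=1)
    per_class = np.where(row_sums > 0, 100.0 * np.diag(cm) / np.maximum(row_sums, 1),
                         np.nan)
    present = row_sums > 0
    mean_acc = macro_mean_accuracy(per_class[present])
    return EvalReport(confusion=cm, per_class_accuracy=per_class,
                      mean_accuracy=mean_acc, classes=np.asarray(classes),
                      set_name=set_name)
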