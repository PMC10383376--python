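"""Estimators: the hybrid network, baseline learners, and the consensus.

The hybrid estimators follow the scikit-learn contract (``fit`` /
``predict`` / ``predict_proba``, ``get_params`` / ``set_params``, fitted
attributes with a trailing underscore), so they compose with pipelines and
model selection. A sample's features are packed into a single numeric row:
the first ``smiles_length`` columns are the integer token indices of the
encoded mixture SMILES, the remaining columns are the mixture descriptor
vector. ``smiles_length=0`` gives the descriptor-only feedforward network
(the "NN" baseline); passing no descriptor columns gives the SMILES-only CNN.

Descriptor columns are standardized to zero mean / unit variance using
training-set statistics only; token columns are embedded, not scaled.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._net import HybridCore
from .errors import ManifestError
from .smiles import VOCAB_SIZE, vocab_fingerprint


def pack_hybrid_input(tokens: np.ndarray | None, descriptors: np.ndarray | None) -> np.ndarray:
    """Concatenate a token matrix and a descriptor matrix into one X."""
    if tokens is None:
        return np.asarray(descriptors, dtype=float)
    if descriptors is None:
        return np.asarray(tokens, dtype=float)
    return np.hstack([np.asarray(tokens, dtype=float), np.asarray(descriptors, dtype=float)])


class _HybridNetBase(BaseEstimator):
    """Shared plumbing for the classifier and the regressor."""

    _task: str = ""

    def __init__(
        self,
        smiles_length=400,
        embedding_dim=100,
        conv_filters=64,
        conv_kernel=5,
        hidden_layer_sizes=(512, 128),
        merge_units=128,
        dropout=0.2,
        learning_rate=1e-3,
        epochs=50,
        batch_size=64,
        standardize=True,
        random_state=None,
    ):
        self.smiles_length = smiles_length
        self.embedding_dim = embedding_dim
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.hidden_layer_sizes = hidden_layer_sizes
        self.merge_units = merge_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.standardize = standardize
        self.random_state = random_state

    # -- input handling ----------------------------------------------------

    def _split_input(self, X, *, fitting: bool):
        L = int(self.smiles_length)
        if X.shape[1] < L:
            raise ValueError(
                f"X has {X.shape[1]} columns but smiles_length={L} token columns are expected"
            )
        tokens = None
        if L:
            tokens = X[:, :L]
            if not np.all((tokens >= 0) & (tokens <= VOCAB_SIZE) & (tokens == np.round(tokens))):
                raise ValueError(
                    f"the first {L} columns must be integer token indices in 0..{VOCAB_SIZE}"
                )
            tokens = tokens.astype(np.int64)
        desc = X[:, L:]
        if fitting:
            if self.standardize and desc.shape[1]:
                self.scaler_mean_ = desc.mean(axis=0)
                scale = desc.std(axis=0)
                scale[scale == 0] = 1.0
                self.scaler_scale_ = scale
            else:
                self.scaler_mean_ = np.zeros(desc.shape[1])
                self.scaler_scale_ = np.ones(desc.shape[1])
        if desc.shape[1]:
            desc = (desc - self.scaler_mean_) / self.scaler_scale_
        else:
            desc = None
        return tokens, desc

    def _manifest(self, n_descriptors: int) -> dict:
        return {
            "task": self._task,
            "smiles_length": int(self.smiles_length),
            "vocab": vocab_fingerprint() if self.smiles_length else None,
            "n_descriptors": int(n_descriptors),
            "standardize": bool(self.standardize),
        }

    def _check_manifest(self, X):
        expected = self.manifest_["smiles_length"] + self.manifest_["n_descriptors"]
        if X.shape[1] != expected:
            raise ManifestError(
                f"input has {X.shape[1]} features but the fitted manifest expects "
                f"{expected} ({self.manifest_['smiles_length']} tokens + "
                f"{self.manifest_['n_descriptors']} descriptors)"
            )

    def _fit_core(self, X, y, n_outputs):
        tokens, desc = self._split_input(X, fitting=True)
        seed = 0 if self.random_state is None else int(self.random_state)
        self.net_ = HybridCore(
            task=self._task,
            n_outputs=n_outputs,
            smiles_length=int(self.smiles_length),
            n_descriptors=0 if desc is None else desc.shape[1],
            vocab_size=VOCAB_SIZE,
            embedding_dim=self.embedding_dim,
            conv_filters=self.conv_filters,
            conv_kernel=self.conv_kernel,
            hidden_sizes=tuple(self.hidden_layer_sizes),
            merge_units=self.merge_units,
            dropout=self.dropout,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=seed,
        )
        self.loss_curve_ = self.net_.fit(tokens, desc, y)
        self.n_features_in_ = X.shape[1]
        self.manifest_ = self._manifest(0 if desc is None else desc.shape[1])
        return self

    def _raw(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=float)
        self._check_manifest(X)
        tokens, desc = self._split_input(X, fitting=False)
        return self.net_.predict_raw(tokens, desc)


class HybridNetClassifier(ClassifierMixin, _HybridNetBase):
    """Hybrid SMILES-CNN + descriptor-FFNN classifier.

    Binary targets get a single sigmoid output unit; three or more classes
    get a softmax head with one probability per class. Decision rule:
    probability threshold 0.5 for binary, argmax otherwise.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        if len(self.classes_) == 2:
            self._task = "binary"
            return self._fit_core(X, y_idx.astype(float), n_outputs=1)
        self._task = "multiclass"
        return self._fit_core(X, y_idx, n_outputs=len(self.classes_))

    def predict_proba(self, X):
        out = self._raw(X)
        if self.manifest_["task"] == "binary":
            from ._net import _sigmoid

            p = _sigmoid(out[:, 0])
            return np.column_stack([1.0 - p, p])
        from ._net import _softmax

        return _softmax(out)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class HybridNetRegressor(RegressorMixin, _HybridNetBase):
    """Hybrid SMILES-CNN + descriptor-FFNN regressor with one linear output.

    Targets (e.g. -log10 mixture TD50) are internally centered and scaled
    for stable optimization and mapped back at prediction time.
    """

    _task = "regression"

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.y_mean_ = float(np.mean(y))
        self.y_scale_ = float(np.std(y)) or 1.0
        return self._fit_core(X, (y - self.y_mean_) / self.y_scale_, n_outputs=1)

    def predict(self, X):
        return self._raw(X)[:, 0] * self.y_scale_ + self.y_mean_


# --- baseline learners ----------------------------------------------------

CLASSIFIER_METHODS = ("RF", "bagging", "AdaBoost")
REGRESSOR_METHODS = ("RF", "SVR", "GB", "KR", "DT", "KN", "NN")
#: Number of regression methods entering the consensus.
N_CONSENSUS = 7


def build_baseline(method: str, task: str, random_state: int = 0):
    """Baseline learner for the supported (method, task) grid.

    Classification (binary or multiclass): random forest, bagged decision
    trees, AdaBoost. Regression: random forest, support vector regression,
    gradient boosting, kernel ridge, AdaBoost-boosted decision tree,
    k-nearest neighbours, and the descriptor-only feedforward network.
    Library defaults with a fixed seed.
    """
    from sklearn.ensemble import (
        AdaBoostClassifier,
        AdaBoostRegressor,
        BaggingClassifier,
        GradientBoostingRegressor,
        RandomForestClassifier,
        RandomForestRegressor,
    )
    from sklearn.kernel_ridge import KernelRidge
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.svm import SVR

    if task in ("binary", "multiclass"):
        grid = {
            "RF": lambda: RandomForestClassifier(random_state=random_state),
            "bagging": lambda: BaggingClassifier(random_state=random_state),
            "AdaBoost": lambda: AdaBoostClassifier(random_state=random_state),
        }
    elif task == "regression":
        grid = {
            "RF": lambda: RandomForestRegressor(random_state=random_state),
            "SVR": lambda: SVR(),
            "GB": lambda: GradientBoostingRegressor(random_state=random_state),
            "KR": lambda: KernelRidge(),
            "DT": lambda: AdaBoostRegressor(random_state=random_state),
            "KN": lambda: KNeighborsRegressor(),
            "NN": lambda: HybridNetRegressor(
                smiles_length=0,
                hidden_layer_sizes=(128, 64),
                merge_units=64,
                epochs=30,
                random_state=random_state,
            ),
        }
    else:
        raise ValueError(f"unknown task {task!r}")
    if method not in grid:
        raise ValueError(
            f"method {method!r} is not supported for task {task!r}; "
            f"valid methods: {', '.join(grid)}"
        )
    return grid[method]()


def consensus_predict(predictions) -> np.ndarray:
    """Elementwise mean of the seven regression methods' predictions."""
    if len(predictions) != N_CONSENSUS:
        raise ValueError(f"consensus requires exactly {N_CONSENSUS} prediction vectors, got {len(predictions)}")
    arrays = [np.asarray(p, dtype=float).ravel() for p in predictions]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("prediction vectors must be aligned (equal length)")
    return np.mean(arrays, axis=0)


def save_model(estimator, path) -> None:
    """Persist a fitted estimator bundle (parameters + manifest + config)."""
    import joblib

    check_is_fitted(estimator)
    joblib.dump(estimator, path)


def load_model(path):
    import joblib

    return joblib.load(path)
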