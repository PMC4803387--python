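"""The three binding-residue classifiers behind one train/score contract.

SVM is a soft-margin RBF support vector machine (scikit-learn SVC), the
neural network is a single hidden layer of sigmoidal units trained by
full-batch gradient descent, and the random forest grows CART trees with a
per-split feature-sampling count ("tries per tree").  ``score`` returns
continuous values: signed SVM decision values, NN sigmoid outputs, RF
positive-vote fractions.
"""

from __future__ import annotations

import dataclasses
import json
import pickle

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

__all__ = [
    "HyperParams",
    "TrainedModel",
    "TrainingError",
    "rbf_kernel",
    "train",
    "score",
    "default_threshold",
    "save_model",
    "load_model",
]

ALGORITHMS = ("svm", "nn", "rf")


class TrainingError(ValueError):
    pass


@dataclasses.dataclass
class HyperParams:
    """Tunable parameters; only the chosen algorithm's fields are meaningful.

    Defaults are the grid-search operating point reported for the reference
    predictors: w = 9; SVM sigma 0.1, cost 1.0; NN 25 nodes, learning rate
    0.1; RF 1501 trees, 20 tries per split.
    """

    algorithm: str
    w: int = 9
    C: float = 1.0
    sigma: float = 0.1
    hidden_nodes: int = 25
    learning_rate: float = 0.1
    n_trees: int = 1501
    mtry: int = 20
    rbf_variant: str = "2sigma2"  # "2sigma2": exp(-d^2/(2 s^2)); "sigma2": exp(-d^2/s^2)

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.w < 1 or self.w % 2 == 0:
            raise ValueError("w must be odd and >= 1")
        if self.algorithm == "svm" and (self.C <= 0 or self.sigma <= 0):
            raise ValueError("svm requires C > 0 and sigma > 0")
        if self.algorithm == "nn" and (self.hidden_nodes < 1 or self.learning_rate <= 0):
            raise ValueError("nn requires hidden_nodes >= 1 and learning_rate > 0")
        if self.algorithm == "rf" and (self.n_trees < 1 or self.mtry < 1):
            raise ValueError("rf requires n_trees >= 1 and mtry >= 1")
        if self.rbf_variant not in ("2sigma2", "sigma2"):
            raise ValueError("rbf_variant must be '2sigma2' or 'sigma2'")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma**2) if self.rbf_variant == "2sigma2" else 1.0 / self.sigma**2


@dataclasses.dataclass
class TrainedModel:
    algorithm: str
    params: HyperParams
    dim: int
    impl: object  # fitted state, opaque


def rbf_kernel(x1, x2, sigma: float, variant: str = "2sigma2") -> float:
    """Gaussian radial basis similarity K(x1, x2) = exp(-||x1-x2||^2 / (2 sigma^2)).

    ``variant="sigma2"`` selects the exp(-d^2/sigma^2) convention instead
    (the two differ only by a sigma rescaling).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("rbf_kernel: dimension mismatch")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((x1 - x2) ** 2))
    denom = 2.0 * sigma**2 if variant == "2sigma2" else sigma**2
    return float(np.exp(-d2 / denom))


class _SigmoidNet:
    """One sigmoid hidden layer, sigmoid output, squared-error loss,
    full-batch gradient descent.  Inputs are standardized internally."""

    def __init__(self, hidden: int, lr: float, seed: int, max_epochs: int = 500, tol: float = 1e-6):
        self.hidden = hidden
        self.lr = lr
        self.seed = seed
        self.max_epochs = max_epochs
        self.tol = tol

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SigmoidNet":
        rng = np.random.default_rng(self.seed)
        self.mu_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        Z = (X - self.mu_) / self.sd_
        n, d = Z.shape
        self.W1_ = rng.normal(0, 1.0 / np.sqrt(d), size=(d, self.hidden))
        self.b1_ = np.zeros(self.hidden)
        self.W2_ = rng.normal(0, 1.0 / np.sqrt(self.hidden), size=self.hidden)
        self.b2_ = 0.0
        prev = np.inf
        for _ in range(self.max_epochs):
            H = self._sigmoid(Z @ self.W1_ + self.b1_)
            out = self._sigmoid(H @ self.W2_ + self.b2_)
            err = out - y
            loss = float(np.mean(err**2))
            # d(mse)/d(pre-activation) for a sigmoid output
            delta_out = 2.0 * err * out * (1.0 - out) / n
            grad_W2 = H.T @ delta_out
            grad_b2 = delta_out.sum()
            delta_h = np.outer(delta_out, self.W2_) * H * (1.0 - H)
            grad_W1 = Z.T @ delta_h
            grad_b1 = delta_h.sum(axis=0)
            self.W2_ -= self.lr * grad_W2
            self.b2_ -= self.lr * grad_b2
            self.W1_ -= self.lr * grad_W1
            self.b1_ -= self.lr * grad_b1
            if abs(prev - loss) < self.tol:
                break
            prev = loss
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mu_) / self.sd_
        H = self._sigmoid(Z @ self.W1_ + self.b1_)
        p = self._sigmoid(H @ self.W2_ + self.b2_)
        # keep outputs strictly inside (0, 1)
        return np.clip(p, 1e-12, 1.0 - 1e-12)


def train(data, params: HyperParams, seed: int = 0) -> TrainedModel:
    """Fit the classifier named by ``params.algorithm``; deterministic per seed."""
    X, y = _unpack(data)
    if X.shape[0] == 0:
        raise TrainingError("empty training set")
    classes = np.unique(y)
    if classes.size < 2:
        raise TrainingError("training data must contain both classes")

    if params.algorithm == "svm":
        impl = SVC(C=params.C, kernel="rbf", gamma=params.gamma, random_state=seed)
        impl.fit(X, y)
    elif params.algorithm == "nn":
        impl = _SigmoidNet(params.hidden_nodes, params.learning_rate, seed).fit(X, y.astype(float))
    else:
        impl = RandomForestClassifier(
            n_estimators=params.n_trees,
            max_features=min(params.mtry, X.shape[1]),
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
        impl.fit(X, y)
    return TrainedModel(algorithm=params.algorithm, params=params, dim=X.shape[1], impl=impl)


def score(model: TrainedModel, X) -> np.ndarray:
    """Continuous per-row scores; higher means more binding-like."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[0] == 0:
        return np.zeros(0)
    if X.shape[1] != model.dim:
        raise ValueError(f"feature dimension {X.shape[1]} != model dimension {model.dim}")
    if model.algorithm == "svm":
        return np.asarray(model.impl.decision_function(X), dtype=float)
    if model.algorithm == "nn":
        return np.asarray(model.impl.predict_proba(X), dtype=float)
    proba = model.impl.predict_proba(X)
    pos_col = int(np.where(model.impl.classes_ == 1)[0][0])
    return np.asarray(proba[:, pos_col], dtype=float)


def default_threshold(algorithm: str) -> float:
    """Natural operating threshold: 0 for decision values, 0.5 for probabilities."""
    return 0.0 if algorithm == "svm" else 0.5


def _unpack(data):
    if hasattr(data, "X"):
        return np.asarray(data.X, dtype=float), np.asarray(data.y, dtype=int)
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y, dtype=int)


def save_model(model: TrainedModel, path: str) -> None:
    """Pickle container plus a JSON metadata sidecar (algorithm, params, dim)."""
    with open(path, "wb") as fh:
        pickle.dump({"version": 1, "model": model}, fh)
    meta = {
        "version": 1,
        "algorithm": model.algorithm,
        "dim": model.dim,
        "params": dataclasses.asdict(model.params),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: str) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != 1:
        raise ValueError("unsupported model container version")
    return payload["model"]
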