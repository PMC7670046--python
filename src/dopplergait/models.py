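"""The seven classifiers under one fit/predict contract.

Five are standard tabular learners provided by scikit-learn behind a thin
uniform wrapper: a linear support vector machine, k-nearest neighbours,
Gaussian naive Bayes, an information-gain decision tree, and a 100-tree
random forest.  The remaining two are implemented here:

* :class:`FeedForwardNet` — a small five-layer network (ReLU on the raw
  inputs, dense 16/32/64 ReLU layers, one sigmoid output) trained for
  exactly 50 epochs of adaptive-moment (Adam) descent on binary
  cross-entropy.  A sigmoid output above the confidence threshold 0.5
  (strictly greater) is read as apathy.
* :class:`MajorityVoteEnsemble` — counts member votes (``apVote`` vs
  ``noapVote``) and predicts apathy on ties, with SVM, random forest, the
  network and KNN as the default members.

All models consume feature matrices of shape (n_samples, n_features) and
string labels ``"apathy"`` / ``"non-apathy"``; stochastic models are fully
determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .apathy_scale import APATHY, LABELS, NON_APATHY

__all__ = [
    "MODEL_NAMES",
    "ENSEMBLE_MEMBERS",
    "ModelSpec",
    "EnsembleVote",
    "FeedForwardNet",
    "SklearnModel",
    "MajorityVoteEnsemble",
    "make_model",
    "fit_model",
    "nn_parameter_count",
]

MODEL_NAMES = ("svm", "knn", "naive_bayes", "decision_tree", "random_forest", "nn", "ensemble")
ENSEMBLE_MEMBERS = ("svm", "random_forest", "nn", "knn")


@dataclass(frozen=True)
class ModelSpec:
    """Name + hyperparameters + seed identifying one classifier."""

    name: str
    hyperparameters: dict = dc_field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")


@dataclass(frozen=True)
class EnsembleVote:
    """Vote tally for one sample; apathy wins ties."""

    ap_vote: int
    noap_vote: int

    @property
    def label(self) -> str:
        return APATHY if self.ap_vote >= self.noap_vote else NON_APATHY


def _check_training_set(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D feature matrix, got shape {X.shape}")
    if len(labels) != X.shape[0]:
        raise ValueError(f"{X.shape[0]} feature vectors but {len(labels)} labels")
    unknown = set(labels) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes")
    return X, labels


def nn_parameter_count(n_inputs: int = 8, hidden_layers: tuple[int, ...] = (16, 32, 64), n_outputs: int = 1) -> int:
    """Number of trainable weights + biases of the dense stack.

    The default 8→16→32→64→1 architecture has 2865 parameters.
    """
    sizes = (n_inputs, *hidden_layers, n_outputs)
    if len(sizes) < 2 or any(s < 1 for s in sizes):
        raise ValueError(f"invalid architecture {sizes}: every layer needs at least one node")
    return int(sum((fan_in + 1) * fan_out for fan_in, fan_out in zip(sizes[:-1], sizes[1:])))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class FeedForwardNet:
    """Five-layer binary classifier: ReLU input, 16/32/64 ReLU, sigmoid output.

    The input "layer" applies ReLU to the raw features without weights; on
    the non-negative count features it is the identity, and it guards
    against negative inputs.  Features are then z-scored with statistics
    fitted on the training set (a numerical conditioning step — normalized
    strip fractions are small, and standardization keeps the first layer's
    gradients usable within the short training budget).

    Training: binary cross-entropy, Adam (lr 0.001), mini-batches of 32 with
    a seeded shuffle, exactly ``epochs`` passes (default 50).  Prediction:
    apathy iff the sigmoid output is strictly greater than
    ``decision_threshold`` (default 0.5).
    """

    def __init__(
        self,
        hidden_layers: tuple[int, ...] = (16, 32, 64),
        epochs: int = 50,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        decision_threshold: float = 0.5,
        seed: int = 0,
    ) -> None:
        if not hidden_layers or any(h < 1 for h in hidden_layers):
            raise ValueError("hidden_layers must be a non-empty tuple of positive widths")
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie strictly inside (0, 1)")
        self.hidden_layers = tuple(int(h) for h in hidden_layers)
        self.epochs = int(epochs)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.decision_threshold = float(decision_threshold)
        self.seed = int(seed)
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self._mean: np.ndarray | None = None
        self._std: np.ndarray | None = None

    # -- internals ---------------------------------------------------------
    def _init_parameters(self, n_inputs: int, rng: np.random.Generator) -> None:
        sizes = (n_inputs, *self.hidden_layers, 1)
        self.weights_, self.biases_ = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization for the ReLU stack; the final (sigmoid) layer
            # inherits the same scheme — at these widths the distinction is
            # immaterial.
            self.weights_.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            self.biases_.append(np.zeros(fan_out))

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        a = np.maximum(np.asarray(X, dtype=np.float64), 0.0)  # input ReLU
        a = (a - self._mean) / self._std
        activations = [a]
        n_layers = len(self.weights_)
        for k in range(n_layers):
            z = activations[-1] @ self.weights_[k] + self.biases_[k]
            a = np.maximum(z, 0.0) if k < n_layers - 1 else _sigmoid(z)
            activations.append(a)
        return activations, activations[-1][:, 0]

    # -- public API --------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        if self.weights_ is None:
            raise RuntimeError("network not fitted yet")
        return int(sum(w.size for w in self.weights_) + sum(b.size for b in self.biases_))

    def fit(self, X: np.ndarray, labels: np.ndarray) -> "FeedForwardNet":
        X, labels = _check_training_set(X, labels)
        y = (labels == APATHY).astype(np.float64)
        rng = np.random.default_rng(self.seed)
        Xr = np.maximum(X, 0.0)
        self._mean = Xr.mean(axis=0)
        std = Xr.std(axis=0)
        self._std = np.where(std > 0, std, 1.0)
        self._init_parameters(X.shape[1], rng)

        # Adam state
        m = [np.zeros_like(w) for w in self.weights_] + [np.zeros_like(b) for b in self.biases_]
        v = [np.zeros_like(g) for g in m]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = X.shape[0]
        batch = min(self.batch_size, n)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                acts, p = self._forward(X[idx])
                # sigmoid + cross-entropy: dL/dz_out = p - y
                delta = (p - y[idx])[:, None] / len(idx)
                grads_w, grads_b = [], []
                for k in range(len(self.weights_) - 1, -1, -1):
                    grads_w.append(acts[k].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if k > 0:
                        delta = (delta @ self.weights_[k].T) * (acts[k] > 0)
                grads = list(reversed(grads_w)) + list(reversed(grads_b))
                params = self.weights_ + self.biases_
                t += 1
                for p_arr, g, mk, vk in zip(params, grads, m, v):
                    mk *= beta1
                    mk += (1 - beta1) * g
                    vk *= beta2
                    vk += (1 - beta2) * g * g
                    m_hat = mk / (1 - beta1**t)
                    v_hat = vk / (1 - beta2**t)
                    p_arr -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Apathy confidence (sigmoid output) per sample."""
        if self.weights_ is None:
            raise RuntimeError("network not fitted yet")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.weights_[0].shape[0]:
            raise ValueError(f"expected {self.weights_[0].shape[0]} features, got {X.shape[1]}")
        return self._forward(X)[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return np.where(p > self.decision_threshold, APATHY, NON_APATHY).astype(object)


class SklearnModel:
    """Uniform wrapper around one scikit-learn estimator."""

    def __init__(self, name: str, estimator) -> None:
        self.name = name
        self.estimator = estimator
        self.fitted_ = False

    def fit(self, X: np.ndarray, labels: np.ndarray) -> "SklearnModel":
        X, labels = _check_training_set(X, labels)
        self.estimator.fit(X, labels)
        self.fitted_ = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted_:
            raise RuntimeError(f"{self.name} model not fitted yet")
        return np.asarray(self.estimator.predict(np.atleast_2d(X)), dtype=object)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted_:
            raise RuntimeError(f"{self.name} model not fitted yet")
        proba = self.estimator.predict_proba(np.atleast_2d(X))
        ap_col = list(self.estimator.classes_).index(APATHY)
        return proba[:, ap_col]


class MajorityVoteEnsemble:
    """Majority vote over member classifiers; ties go to apathy.

    ``apVote`` and ``noapVote`` count the members predicting apathy and
    non-apathy; the ensemble predicts apathy iff ``apVote >= noapVote``.
    Members may be passed already fitted (``prefitted=True``) so a sweep can
    reuse the single models it has just trained.
    """

    def __init__(self, members: list | None = None, seed: int = 0, prefitted: bool = False) -> None:
        if members is None:
            members = [make_model(name, seed=seed) for name in ENSEMBLE_MEMBERS]
        if not members:
            raise ValueError("ensemble needs at least one member model")
        self.members = list(members)
        self.fitted_ = bool(prefitted)

    def fit(self, X: np.ndarray, labels: np.ndarray) -> "MajorityVoteEnsemble":
        _check_training_set(X, labels)
        for member in self.members:
            member.fit(X, labels)
        self.fitted_ = True
        return self

    def votes(self, X: np.ndarray) -> list[EnsembleVote]:
        if not self.fitted_:
            raise RuntimeError("ensemble not fitted yet")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        ballots = np.stack([member.predict(X) for member in self.members])
        ap = (ballots == APATHY).sum(axis=0)
        return [EnsembleVote(int(a), int(len(self.members) - a)) for a in ap]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray([vote.label for vote in self.votes(X)], dtype=object)


def make_model(name: str, seed: int = 0, **hyperparameters):
    """Instantiate one of the seven classifiers by name.

    Hyperparameters not overridden keep the documented defaults: linear SVM
    with C=1; KNN with k=5 and Euclidean distance; Gaussian naive Bayes;
    information-gain (entropy) decision tree without a depth limit;
    100-tree bootstrap random forest with sqrt(d) features per split.
    """
    hp = dict(hyperparameters)
    if name == "svm":
        return SklearnModel(name, SVC(kernel=hp.pop("kernel", "linear"), C=hp.pop("C", 1.0), **hp))
    if name == "knn":
        return SklearnModel(name, KNeighborsClassifier(n_neighbors=hp.pop("k", 5), **hp))
    if name == "naive_bayes":
        return SklearnModel(name, GaussianNB(**hp))
    if name == "decision_tree":
        return SklearnModel(name, DecisionTreeClassifier(criterion="entropy", random_state=seed, **hp))
    if name == "random_forest":
        return SklearnModel(
            name,
            RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 100),
                criterion="entropy",
                max_features="sqrt",
                bootstrap=True,
                random_state=seed,
                **hp,
            ),
        )
    if name == "nn":
        return FeedForwardNet(seed=seed, **hp)
    if name == "ensemble":
        members = hp.pop("members", None)
        if members is not None and members and isinstance(members[0], str):
            members = [make_model(m, seed=seed) for m in members]
        return MajorityVoteEnsemble(members=members, seed=seed, **hp)
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


def fit_model(spec: ModelSpec, X: np.ndarray, labels) -> object:
    """Build the classifier described by ``spec`` and fit it."""
    model = make_model(spec.name, seed=spec.rng_seed, **spec.hyperparameters)
    return model.fit(np.asarray(X, dtype=np.float64), np.asarray(labels, dtype=object))
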