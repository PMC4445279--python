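"""Training-set assembly, windowed-momentum MLP, cross-validation and chain selection.

A discriminative model is an *algorithm chain*: an ordered set of feature
extractors followed by one classifier.  Chains are compared by stratified
k-fold cross-validation accuracy on a labeled ROI set; the winning chain
becomes the punctum-center detector.

The bespoke classifier is a single-hidden-layer perceptron trained by
full-batch backpropagation with *windowed momentum*: the momentum term is
the mean of the last W weight updates rather than only the most recent
one, which damps oscillation on small training sets,

    dw(t) = -eta * grad E(t) + alpha * mean(dw(t-1), ..., dw(t-W)).

With W = 1 this reduces exactly to classical momentum.  SVM and
random-forest classifiers are available behind the same interface.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier as _SkRF
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC as _SkSVC

from puncta3d.core import MarkerSet, Roi3D, VolumeStack, extract_roi
from puncta3d.features import get_extractor

__all__ = [
    "MlpConfig",
    "AlgorithmChain",
    "TrainedModel",
    "assemble_training_set",
    "chain_features",
    "train_mlp",
    "predict",
    "cross_validate",
    "compare_chains",
]


@dataclass(frozen=True)
class MlpConfig:
    hidden_units: int = 16
    learning_rate: float = 0.05
    momentum: float = 0.9
    momentum_window: int = 5
    epochs: int = 500
    tol: float = 1e-7  # early stop when the epoch loss decrease falls below this
    seed: int = 0

    def __post_init__(self):
        if min(self.hidden_units, self.epochs, self.momentum_window) < 1:
            raise ValueError("hidden_units, epochs and momentum_window must be >= 1")
        if self.learning_rate <= 0 or self.momentum < 0:
            raise ValueError("learning_rate must be > 0 and momentum >= 0")


@dataclass(frozen=True)
class AlgorithmChain:
    """Feature extractor(s) + optional selector slot + classifier."""

    extractors: tuple[str, ...] = ("haar3d",)
    classifier: str = "mlp"
    classifier_config: MlpConfig | None = None
    name: str = ""

    def __post_init__(self):
        if len(self.extractors) < 1:
            raise ValueError("a chain needs at least one feature extractor")
        if not self.name:
            object.__setattr__(self, "name", "+".join(self.extractors) + "->" + self.classifier)


def chain_features(chain: AlgorithmChain, rois: Sequence[Roi3D]) -> np.ndarray:
    """Stack the concatenated extractor outputs for every ROI, (n, d)."""
    rows = []
    for roi in rois:
        parts = [get_extractor(name)(roi).values for name in chain.extractors]
        rows.append(np.concatenate(parts))
    return np.asarray(rows, dtype=np.float64)


def roi_labels(rois: Sequence[Roi3D]) -> np.ndarray:
    lab = np.array([1 if r.label == "positive" else 0 for r in rois], dtype=int)
    if any(r.label == "unlabeled" for r in rois):
        raise ValueError("training ROIs must be labeled positive or negative")
    return lab


def assemble_training_set(
    volume: VolumeStack,
    positives: MarkerSet,
    negatives: MarkerSet,
    roi_size: tuple[int, int, int] = (9, 9, 3),
) -> list[Roi3D]:
    """One labeled ROI per marker; counts preserved."""
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("binary training needs both positive and negative markers")
    pos_coords = {m.coord for m in positives}
    dup = pos_coords & {m.coord for m in negatives}
    if dup:
        raise ValueError(f"coordinates labeled both positive and negative: {sorted(dup)[:5]}")
    rois = [extract_roi(volume, m.coord, roi_size, label="positive") for m in positives]
    rois += [extract_roi(volume, m.coord, roi_size, label="negative") for m in negatives]
    return rois


# ---------------------------------------------------------------------------
# windowed-momentum MLP
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class TrainedModel:
    """A fitted chain: weights plus the standardization constants.

    ``predict`` is deterministic given the stored weights.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    config: MlpConfig
    chain: AlgorithmChain = field(default_factory=AlgorithmChain)
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(f"feature length {X.shape[1]} != trained length {self.n_features}")
        Xs = (X - self.mu) / self.sigma
        H = _sigmoid(Xs @ self.W1 + self.b1)
        return _sigmoid(H @ self.W2 + self.b2).ravel()

    def save(self, path) -> None:
        doc = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
            "config": asdict(self.config),
            "chain": {"extractors": list(self.chain.extractors),
                      "classifier": self.chain.classifier, "name": self.chain.name},
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            W1=np.array(doc["W1"]), b1=np.array(doc["b1"]),
            W2=np.array(doc["W2"]), b2=np.array(doc["b2"]),
            mu=np.array(doc["mu"]), sigma=np.array(doc["sigma"]),
            config=MlpConfig(**doc["config"]),
            chain=AlgorithmChain(extractors=tuple(doc["chain"]["extractors"]),
                                 classifier=doc["chain"]["classifier"],
                                 name=doc["chain"]["name"]),
            metadata=doc.get("metadata", {}),
        )


def train_mlp(
    features: np.ndarray,
    labels: np.ndarray,
    config: MlpConfig = MlpConfig(),
    chain: AlgorithmChain | None = None,
) -> TrainedModel:
    """Fit the windowed-momentum MLP on standardized features.

    Full-batch backpropagation of the binary cross-entropy with sigmoid
    activations throughout; deterministic under a fixed config seed.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, d) with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")

    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma == 0] = 1.0
    Xs = (X - mu) / sigma

    rng = np.random.default_rng(config.seed)
    d, H = X.shape[1], config.hidden_units
    W1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, H))
    b1 = np.zeros(H)
    W2 = rng.normal(0.0, 1.0 / np.sqrt(H), size=(H, 1))
    b2 = np.zeros(1)

    n = X.shape[0]
    hist: deque[list[np.ndarray]] = deque(maxlen=config.momentum_window)
    prev_loss = np.inf
    epochs_run = 0
    for epoch in range(config.epochs):
        Hid = _sigmoid(Xs @ W1 + b1)
        out = _sigmoid(Hid @ W2 + b2).ravel()
        eps = 1e-12
        loss = -np.mean(y * np.log(out + eps) + (1 - y) * np.log(1 - out + eps))
        delta_out = (out - y)[:, None] / n  # dL/d(pre-activation) of the output
        gW2 = Hid.T @ delta_out
        gb2 = delta_out.sum(axis=0)
        delta_hid = (delta_out @ W2.T) * Hid * (1 - Hid)
        gW1 = Xs.T @ delta_hid
        gb1 = delta_hid.sum(axis=0)

        grads = [gW1, gb1, gW2, gb2]
        if hist:
            mean_prev = [np.mean([h[i] for h in hist], axis=0) for i in range(4)]
        else:
            mean_prev = [0.0, 0.0, 0.0, 0.0]
        update = [
            -config.learning_rate * g + config.momentum * m
            for g, m in zip(grads, mean_prev)
        ]
        W1 = W1 + update[0]
        b1 = b1 + update[1]
        W2 = W2 + update[2]
        b2 = b2 + update[3]
        hist.append(update)
        epochs_run = epoch + 1
        if abs(prev_loss - loss) < config.tol:
            break
        prev_loss = loss

    model = TrainedModel(W1=W1, b1=b1, W2=W2, b2=b2, mu=mu, sigma=sigma,
                         config=config, chain=chain or AlgorithmChain())
    train_scores = model.predict_scores(X)
    model.metadata = {
        "seed": config.seed,
        "epochs_run": epochs_run,
        "final_loss": float(loss),
        "train_accuracy": float(np.mean((train_scores > 0.5) == (y == 1))),
    }
    return model


def predict(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (bool, positive = score strictly > 0.5) and scores in [0, 1]."""
    scores = model.predict_scores(features)
    return scores > 0.5, scores


# ---------------------------------------------------------------------------
# classifier registry for chain comparison
# ---------------------------------------------------------------------------

class _Dummy:
    """Majority-class baseline."""

    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.majority = vals[np.argmax(counts)]
        return self

    def predict_labels(self, X):
        return np.full(len(np.atleast_2d(X)), self.majority == 1, dtype=bool)


class _MlpWrap:
    def __init__(self, config: MlpConfig):
        self.config = config

    def fit(self, X, y):
        self.model = train_mlp(X, y, self.config)
        return self

    def predict_labels(self, X):
        return self.model.predict_scores(X) > 0.5


class _SkWrap:
    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        self.mu = X.mean(axis=0)
        self.sigma = X.std(axis=0)
        self.sigma[self.sigma == 0] = 1.0
        self.est.fit((X - self.mu) / self.sigma, y)
        return self

    def predict_labels(self, X):
        return self.est.predict((np.atleast_2d(X) - self.mu) / self.sigma) == 1


def _make_classifier(name: str, config, seed: int):
    if name == "mlp":
        cfg = config if isinstance(config, MlpConfig) else MlpConfig(seed=seed)
        return _MlpWrap(cfg)
    if name == "dummy":
        return _Dummy()
    if name == "svm":
        return _SkWrap(_SkSVC(kernel="rbf", C=1.0, random_state=seed))
    if name == "rf":
        return _SkWrap(_SkRF(n_estimators=100, random_state=seed))
    raise KeyError(f"unknown classifier {name!r}")


def cross_validate(
    chain: AlgorithmChain,
    rois: Sequence[Roi3D],
    k: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold CV accuracy (pooled correct / total) of a chain."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = roi_labels(rois)
    counts = np.bincount(y)
    if k > counts[counts > 0].min():
        raise ValueError(f"k={k} exceeds the smallest class count {counts[counts > 0].min()}")
    X = chain_features(chain, rois)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        clf = _make_classifier(chain.classifier, chain.classifier_config, seed)
        clf.fit(X[tr], y[tr])
        correct += int(np.sum(clf.predict_labels(X[te]) == (y[te] == 1)))
    return correct / len(y)


def compare_chains(
    chains: Sequence[AlgorithmChain],
    rois: Sequence[Roi3D],
    k: int = 5,
    seed: int = 0,
) -> list[tuple[AlgorithmChain, float]]:
    """Rank chains by CV accuracy, descending; ties keep declaration order."""
    if len(chains) < 1:
        raise ValueError("need at least one chain")
    scored = [(chain, cross_validate(chain, rois, k=k, seed=seed)) for chain in chains]
    order = sorted(range(len(scored)), key=lambda i: (-scored[i][1], i))
    return [scored[i] for i in order]
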