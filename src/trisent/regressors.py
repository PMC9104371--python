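"""Continuous sentiment scorers: a small feed-forward network and an SVR.

Both models are trained on a binary-polarity corpus (labels 0/1 mapped to
regression targets -1/+1) and emit a continuous sentiment score in
[-1, 1] for arbitrary text; the downstream decision stage trichotomizes
that score.  The network is the 20 -> 16 -> 1 architecture with a ReLU
hidden layer and a hyperbolic-tangent output, trained by minibatch SGD
with momentum on squared error; its output range is [-1, 1] by
construction.  The support-vector regressor (RBF kernel) has an unbounded
output, so its predictions are clipped into [-1, 1].
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVR

from .embedding import EmbeddingProvider, embed_corpus, embed_document
from .synthetic_data import BinaryReview, Testimony
from .text_prep import preprocess

_PERSIST_FORMAT = 1


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and training hyperparameters for the network scorer."""

    input_dim: int = 20
    hidden_units: int = 16
    epochs: int = 50
    learning_rate: float = 0.05
    momentum: float = 0.9
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_units < 1:
            raise ValueError("input_dim and hidden_units must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class SVRConfig:
    """Kernel and regularisation settings for the support-vector scorer."""

    kernel: str = "rbf"
    regularization: float = 1.0
    epsilon: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


class _TinyMLP:
    """Minimal dense network: input -> ReLU hidden -> tanh scalar output."""

    def __init__(self, config: MLPConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, h = config.input_dim, config.hidden_units
        # He-style init for the ReLU layer, Xavier-style for the output.
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0.0, np.sqrt(1.0 / h), size=(h, 1))
        self.b2 = np.zeros(1)
        self._rng = rng

    def predict(self, X: np.ndarray) -> np.ndarray:
        hidden = np.maximum(X @ self.W1 + self.b1, 0.0)
        return np.tanh(hidden @ self.W2 + self.b2).ravel()

    def fit(self, X: np.ndarray, y: np.ndarray) -> None:
        cfg = self.config
        n = X.shape[0]
        vel = [np.zeros_like(p) for p in (self.W1, self.b1, self.W2, self.b2)]
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                Xb, yb = X[idx], y[idx]
                z1 = Xb @ self.W1 + self.b1
                hid = np.maximum(z1, 0.0)
                z2 = hid @ self.W2 + self.b2
                out = np.tanh(z2).ravel()
                # d MSE / d z2, averaged over the batch
                d2 = (2.0 * (out - yb) * (1.0 - out**2) / len(idx))[:, None]
                gW2 = hid.T @ d2
                gb2 = d2.sum(axis=0)
                dh = (d2 @ self.W2.T) * (z1 > 0.0)
                gW1 = Xb.T @ dh
                gb1 = dh.sum(axis=0)
                params = (self.W1, self.b1, self.W2, self.b2)
                grads = (gW1, gb1, gW2, gb2)
                for p, g, v in zip(params, grads, vel):
                    v *= cfg.momentum
                    v -= cfg.learning_rate * g
                    p += v


class Scorer:
    """A trained text -> sentiment-score function, score always in [-1, 1]."""

    def __init__(self, model, provider: EmbeddingProvider, name: str, config):
        if getattr(config, "input_dim", provider.dimension) != provider.dimension:
            raise ValueError(
                f"model input dimension {config.input_dim} does not match "
                f"provider dimension {provider.dimension}"
            )
        self.model = model
        self.provider = provider
        self.name = name
        self.config = config

    def score_vectors(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.model.predict(X), -1.0, 1.0)

    def score_texts(self, texts: Sequence[str]) -> np.ndarray:
        X = embed_corpus((preprocess(t) for t in texts), self.provider)
        return self.score_vectors(X)

    def __call__(self, text: str) -> float:
        X = embed_document(preprocess(text), self.provider)[None, :]
        return float(self.score_vectors(X)[0])


def _training_matrix(
    corpus: Sequence[BinaryReview], provider: EmbeddingProvider, split: str
) -> tuple[np.ndarray, np.ndarray]:
    rows = [r for r in corpus if r.split == split]
    labels = {r.label for r in corpus}
    if labels != {0, 1}:
        raise ValueError(f"binary corpus must contain both labels, found {sorted(labels)}")
    if not rows:
        raise ValueError(f"no documents in the {split!r} split")
    X = embed_corpus((preprocess(r.text) for r in rows), provider)
    # dichotomous labels {0,1} become regression targets {-1,+1}
    y = np.asarray([2.0 * r.label - 1.0 for r in rows])
    return X, y


def train_mlp(
    corpus: Sequence[BinaryReview],
    provider: EmbeddingProvider,
    config: MLPConfig | None = None,
) -> Scorer:
    """Fit the feed-forward scorer on the corpus's train split."""
    config = config or MLPConfig(input_dim=provider.dimension)
    if config.input_dim != provider.dimension:
        raise ValueError(
            f"config.input_dim={config.input_dim} does not match provider "
            f"dimension {provider.dimension}"
        )
    X, y = _training_matrix(corpus, provider, "train")
    model = _TinyMLP(config)
    model.fit(X, y)
    return Scorer(model, provider, "mlp", config)


def train_svr(
    corpus: Sequence[BinaryReview],
    provider: EmbeddingProvider,
    config: SVRConfig | None = None,
) -> Scorer:
    """Fit the support-vector scorer on the corpus's train split."""
    config = config or SVRConfig()
    X, y = _training_matrix(corpus, provider, "train")
    model = SVR(kernel=config.kernel, C=config.regularization, epsilon=config.epsilon)
    model.fit(X, y)
    return Scorer(model, provider, "svm", config)


def validation_accuracy(scorer: Scorer, corpus: Sequence[BinaryReview], threshold: float = 0.0) -> float:
    """Binary accuracy on the validation split at a score threshold."""
    rows = [r for r in corpus if r.split == "validation"]
    if not rows:
        raise ValueError("no documents in the validation split")
    scores = scorer.score_texts([r.text for r in rows])
    predicted = (scores >= threshold).astype(int)
    return float(np.mean(predicted == np.asarray([r.label for r in rows])))


def score_corpus(testimonies: Sequence[Testimony], scorer: Scorer) -> list[tuple[str, float]]:
    """Score every testimony, preserving input order."""
    if not testimonies:
        return []
    scores = scorer.score_texts([t.text for t in testimonies])
    return [(t.id, float(s)) for t, s in zip(testimonies, scores)]


def save_scorer(scorer: Scorer, path: str | Path) -> None:
    """Persist a trained scorer with a format version and config snapshot."""
    payload = {
        "format": _PERSIST_FORMAT,
        "name": scorer.name,
        "config": asdict(scorer.config),
        "scorer": scorer,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_scorer(path: str | Path) -> Scorer:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != _PERSIST_FORMAT:
        raise ValueError(f"unsupported scorer file format: {payload.get('format')!r}")
    return payload["scorer"]
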