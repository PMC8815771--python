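"""Metric-learning embedding: a small feed-forward net trained with triplet loss.

The network maps p raw (standardized) features through three hidden layers of
widths (4d, 2d, d); the d-dimensional output is the embedding.  The Gumbel
cumulative distribution function sigma(x) = exp(-exp(-x)) serves as the
activation: it is smooth, strictly increasing, bounded in (0, 1) and
asymmetric, and — unlike ReLU — has no dead region.  Training minimizes the
hinge triplet loss

    L = max(0, D(anchor, positive) - D(anchor, negative) + m)

with Euclidean distance D in embedding space, anchors and positives drawn
from the minority class and negatives from the majority class, so that
minority samples cluster together and away from the majority by margin m.

Gradients are computed by hand-written backpropagation (plain numpy); the
optimizer is minibatch gradient descent with a fixed learning rate.  All
randomness (weight init, triplet mining) flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import Dataset

__all__ = [
    "gumbel",
    "gumbel_grad",
    "EmbeddingConfig",
    "EmbeddingNet",
    "TripletBatch",
    "init_net",
    "mine_triplets",
    "triplet_loss",
    "train_embedding",
    "embed",
]


def gumbel(x):
    """Gumbel (GEV type I) CDF, exp(-exp(-x)); strictly increasing into (0, 1)."""
    return np.exp(-np.exp(-np.asarray(x, dtype=float)))


def gumbel_grad(x):
    """Derivative of the Gumbel CDF: exp(-x - exp(-x)); saturates to 0 at +/-inf."""
    x = np.asarray(x, dtype=float)
    return np.exp(-x - np.exp(-x))


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    return (np.asarray(x) > 0).astype(float)


_ACTIVATIONS = {"gumbel": (gumbel, gumbel_grad), "relu": (_relu, _relu_grad)}


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyper-parameters of the embedding network and its training loop.

    ``embed_dim`` is the width d of the third hidden layer (the embedding);
    the first two hidden layers have widths 4d and 2d (each layer half the
    previous).  ``margin`` is the triplet-loss margin m (default 0.2).
    """

    embed_dim: int = 8
    margin: float = 0.2
    epochs: int = 200
    triplets_per_epoch: int = 128
    batch_size: int = 32
    learning_rate: float = 1e-2
    seed: int = 0
    activation: str = "gumbel"
    last_layer_activated: bool = True

    def __post_init__(self):
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class EmbeddingNet:
    """Weights of the p -> 4d -> 2d -> d feed-forward map."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "gumbel"
    last_layer_activated: bool = True
    fitted: bool = False

    @property
    def in_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def out_dim(self) -> int:
        return self.weights[-1].shape[1]

    def forward(self, X: np.ndarray) -> np.ndarray:
        Z, _ = self.forward_cached(X)
        return Z

    def forward_cached(self, X: np.ndarray):
        """Forward pass keeping pre-activations for backpropagation."""
        act, _ = _ACTIVATIONS[self.activation]
        a = np.asarray(X, dtype=float)
        if a.ndim != 2 or a.shape[1] != self.in_dim:
            raise ValueError(
                f"input has {a.shape[-1] if a.ndim == 2 else '?'} columns, "
                f"network expects {self.in_dim}"
            )
        cache = []
        n_layers = len(self.weights)
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            last = layer == n_layers - 1
            cache.append((a, z))
            a = z if (last and not self.last_layer_activated) else act(z)
        return a, cache

    def backward(self, cache, dZ: np.ndarray):
        """Gradients of the weights given d(loss)/d(embedding) for one stream."""
        _, dact = _ACTIVATIONS[self.activation]
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        da = dZ
        n_layers = len(self.weights)
        for layer in range(n_layers - 1, -1, -1):
            a_prev, z = cache[layer]
            last = layer == n_layers - 1
            dz = da if (last and not self.last_layer_activated) else da * dact(z)
            gW[layer] = a_prev.T @ dz
            gb[layer] = dz.sum(axis=0)
            da = dz @ self.weights[layer].T
        return gW, gb

    def save(self, path: str) -> None:
        payload = {
            "activation": self.activation,
            "last_layer_activated": self.last_layer_activated,
            "fitted": self.fitted,
            "weights": [W.tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "EmbeddingNet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=[np.asarray(W) for W in payload["weights"]],
            biases=[np.asarray(b) for b in payload["biases"]],
            activation=payload["activation"],
            last_layer_activated=payload["last_layer_activated"],
            fitted=payload["fitted"],
        )


def init_net(p: int, config: EmbeddingConfig) -> EmbeddingNet:
    """Glorot-scaled uniform init for layer widths (p, 4d, 2d, d); seeded."""
    if p < 1:
        raise ValueError("p must be >= 1")
    d = config.embed_dim
    widths = [p, 4 * d, 2 * d, d]
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return EmbeddingNet(
        weights=weights,
        biases=biases,
        activation=config.activation,
        last_layer_activated=config.last_layer_activated,
    )


@dataclass(frozen=True)
class TripletBatch:
    """Index triplets: anchors/positives are minority rows, negatives majority."""

    anchor: np.ndarray
    positive: np.ndarray
    negative: np.ndarray

    def __len__(self) -> int:
        return len(self.anchor)


def mine_triplets(y: np.ndarray, count: int, rng: np.random.Generator) -> TripletBatch:
    """Sample ``count`` uniform triplets.

    Anchor and positive are distinct minority indices (unless the minority
    has a single sample, in which case positive == anchor); the negative is
    a uniform majority index.
    """
    y = np.asarray(y)
    min_idx = np.flatnonzero(y == 1)
    maj_idx = np.flatnonzero(y == -1)
    if len(min_idx) == 0 or len(maj_idx) == 0:
        raise ValueError("triplet mining needs both classes present")
    anchors = rng.choice(min_idx, size=count, replace=True)
    if len(min_idx) == 1:
        positives = anchors.copy()
    else:
        # uniform over minority indices excluding the anchor
        offsets = rng.integers(1, len(min_idx), size=count)
        anchor_pos = np.searchsorted(min_idx, anchors)
        positives = min_idx[(anchor_pos + offsets) % len(min_idx)]
    negatives = rng.choice(maj_idx, size=count, replace=True)
    return TripletBatch(anchor=anchors, positive=positives, negative=negatives)


def triplet_loss(d_a_min, d_a_maj, m: float):
    """Hinge loss max(0, D(a, min) - D(a, maj) + m), elementwise."""
    return np.maximum(0.0, np.asarray(d_a_min) - np.asarray(d_a_maj) + m)


def _row_norms(D: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(D * D, axis=1))


def triplet_loss_and_grads(net: EmbeddingNet, X: np.ndarray, batch: TripletBatch, margin: float):
    """Mean triplet loss over a batch and its analytic weight gradients."""
    Za, cache_a = net.forward_cached(X[batch.anchor])
    Zp, cache_p = net.forward_cached(X[batch.positive])
    Zn, cache_n = net.forward_cached(X[batch.negative])

    diff_ap = Za - Zp
    diff_an = Za - Zn
    d_ap = _row_norms(diff_ap)
    d_an = _row_norms(diff_an)
    losses = triplet_loss(d_ap, d_an, margin)
    loss = float(losses.mean())

    B = len(batch)
    active = (losses > 0).astype(float) / B
    # unit vectors; subgradient 0 at coincident points
    with np.errstate(invalid="ignore", divide="ignore"):
        u_ap = np.where(d_ap[:, None] > 0, diff_ap / np.where(d_ap[:, None] == 0, 1, d_ap[:, None]), 0.0)
        u_an = np.where(d_an[:, None] > 0, diff_an / np.where(d_an[:, None] == 0, 1, d_an[:, None]), 0.0)
    dZa = active[:, None] * (u_ap - u_an)
    dZp = -active[:, None] * u_ap
    dZn = active[:, None] * u_an

    gW = [np.zeros_like(W) for W in net.weights]
    gb = [np.zeros_like(b) for b in net.biases]
    for cache, dZ in ((cache_a, dZa), (cache_p, dZp), (cache_n, dZn)):
        gWs, gbs = net.backward(cache, dZ)
        for k in range(len(gW)):
            gW[k] += gWs[k]
            gb[k] += gbs[k]
    return loss, gW, gb


def _resolve_xy(data, y):
    if isinstance(data, Dataset):
        return data.X, data.y
    return np.asarray(data, dtype=float), np.asarray(y)


def train_embedding(data, y=None, config: EmbeddingConfig | None = None):
    """Train the embedding net by minibatch gradient descent on triplet loss.

    ``data`` may be a Dataset or a (standardized) feature matrix with ``y``
    given separately.  Returns ``(net, loss_trace)`` where ``loss_trace[e]``
    is the mean triplet loss of epoch e.  Fully reproducible per
    ``config.seed``.
    """
    if config is None:
        config = EmbeddingConfig()
    X, yv = _resolve_xy(data, y)
    if len(np.unique(yv)) < 2:
        raise ValueError("training needs both classes present")
    net = init_net(X.shape[1], config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), 1]))

    loss_trace = []
    for epoch in range(config.epochs):
        batch_all = mine_triplets(yv, config.triplets_per_epoch, rng)
        epoch_losses = []
        for start in range(0, config.triplets_per_epoch, config.batch_size):
            sl = slice(start, start + config.batch_size)
            batch = TripletBatch(
                anchor=batch_all.anchor[sl],
                positive=batch_all.positive[sl],
                negative=batch_all.negative[sl],
            )
            loss, gW, gb = triplet_loss_and_grads(net, X, batch, config.margin)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite triplet loss at epoch {epoch}; "
                    f"learning_rate={config.learning_rate} may be too large"
                )
            for k in range(len(net.weights)):
                net.weights[k] -= config.learning_rate * gW[k]
                net.biases[k] -= config.learning_rate * gb[k]
            epoch_losses.append(loss)
        loss_trace.append(float(np.mean(epoch_losses)))
    net.fitted = True
    return net, np.asarray(loss_trace)


def embed(net: EmbeddingNet, X: np.ndarray) -> np.ndarray:
    """Deterministic forward map of X into the embedding space."""
    return net.forward(np.atleast_2d(np.asarray(X, dtype=float)))
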