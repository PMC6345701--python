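"""1D convolutional network over similarity profiles, in pure numpy.

The network is the classic conv → ReLU → max-pool stack repeated per
block, followed by fully-connected ReLU layers and a linear output layer
with one logit per location.  Training minimizes multi-label binary
cross-entropy over sigmoid activations (the default) or softmax
cross-entropy with the label set normalized to a target distribution, by
mini-batch Adam.  All randomness — weight initialization and epoch
shuffling — derives from a single seed, and the arithmetic is plain
single-threaded numpy, so training is bit-reproducible.

After training, the classifier head is discarded and the post-ReLU
activations of the last hidden fully-connected layer serve as the learned
feature representation for the boosted-tree stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(targets: np.ndarray, logits: np.ndarray) -> float:
    """Multi-label binary cross-entropy over sigmoid activations.

    ``-(1/n) * sum_i sum_j [y_ij log σ(f_ij) + (1-y_ij) log(1-σ(f_ij))]``
    evaluated in the standard numerically stable form
    ``max(f,0) - f*y + log(1+exp(-|f|))``, finite for any finite logits.
    """
    targets = np.asarray(targets, dtype=float)
    logits = np.asarray(logits, dtype=float)
    if targets.shape != logits.shape:
        raise ValueError(
            f"shape mismatch: targets {targets.shape} vs logits "
            f"{logits.shape}"
        )
    per = (
        np.maximum(logits, 0.0)
        - logits * targets
        + np.log1p(np.exp(-np.abs(logits)))
    )
    return float(per.sum() / targets.shape[0])


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax along the last axis."""
    logits = np.asarray(logits, dtype=float)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_ce_loss(targets: np.ndarray, logits: np.ndarray) -> float:
    """Cross-entropy with the label set normalized to a distribution."""
    targets = np.asarray(targets, dtype=float)
    logits = np.asarray(logits, dtype=float)
    if targets.shape != logits.shape:
        raise ValueError("shape mismatch between targets and logits")
    row = targets.sum(axis=1, keepdims=True)
    if (row == 0).any():
        raise ValueError("softmax loss requires >= 1 label per example")
    dist = targets / row
    z = logits - logits.max(axis=1, keepdims=True)
    log_p = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-(dist * log_p).sum() / targets.shape[0])


# ---------------------------------------------------------------------------
# Layers

class _Conv1D:
    def __init__(self, c_in, c_out, kernel, rng):
        std = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, std, size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._xw = sliding_window_view(x, self.W.shape[2], axis=2)
        return (
            np.einsum("nclk,ock->nol", self._xw, self.W)
            + self.b[None, :, None]
        )

    def backward(self, dy):
        k = self.W.shape[2]
        self.grads[0][...] = np.einsum("nclk,nol->ock", self._xw, dy)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        n, c_in = self._xw.shape[0], self._xw.shape[1]
        L = self._xw.shape[2] + k - 1
        dx = np.zeros((n, c_in, L))
        for t in range(k):
            dx[:, :, t : t + dy.shape[2]] += np.einsum(
                "nol,oc->ncl", dy, self.W[:, :, t]
            )
        return dx


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class _MaxPool1D:
    params: list = []
    grads: list = []

    def __init__(self, pool):
        self.pool = pool

    def forward(self, x):
        n, c, L = x.shape
        self._in_len = L
        m = (L // self.pool) * self.pool
        xt = x[:, :, :m].reshape(n, c, m // self.pool, self.pool)
        self._arg = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, dy):
        n, c, L_out = dy.shape
        dxt = np.zeros((n, c, L_out, self.pool))
        np.put_along_axis(dxt, self._arg[..., None], dy[..., None], axis=3)
        dx = np.zeros((n, c, self._in_len))
        dx[:, :, : L_out * self.pool] = dxt.reshape(n, c, L_out * self.pool)
        return dx


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, d_in, d_out, rng):
        std = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, std, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class _Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.pairs = [
            (p, g) for layer in layers for p, g in zip(layer.params, layer.grads)
        ]
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# Estimator

@dataclass
class CNNConfig:
    """Architecture and training hyperparameters for the extractor."""

    conv_blocks: tuple = ((16, 5, 2), (32, 5, 2))
    fc_sizes: tuple = (64, 32)
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    loss: str = "bce"
    seed: int = 0


class ConvNetFeatureExtractor(TransformerMixin, BaseEstimator):
    """1D CNN trained on similarity profiles; transform() yields the
    post-ReLU activations of the last hidden fully-connected layer.

    Parameters mirror :class:`CNNConfig`.  ``loss`` is ``"bce"``
    (multi-label, sigmoid outputs) or ``"softmax_ce"`` (single-label).
    """

    def __init__(
        self,
        conv_blocks=((16, 5, 2), (32, 5, 2)),
        fc_sizes=(64, 32),
        epochs: int = 30,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        loss: str = "bce",
        seed: int = 0,
    ):
        self.conv_blocks = conv_blocks
        self.fc_sizes = fc_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss = loss
        self.seed = seed

    # -- construction -----------------------------------------------------

    def _build(self, input_length: int, n_labels: int, rng):
        if len(self.conv_blocks) < 1:
            raise ValueError("need at least one conv block")
        if len(self.fc_sizes) < 1 or self.fc_sizes[-1] < 2:
            raise ValueError("need >= 1 fc layer; feature dimension >= 2")
        layers = []
        c_in, length = 1, input_length
        for n_filters, kernel, pool in self.conv_blocks:
            if length < kernel:
                raise ValueError(
                    f"input length {input_length} is shorter than the "
                    f"receptive field of conv_blocks {self.conv_blocks}"
                )
            layers += [_Conv1D(c_in, n_filters, kernel, rng), _ReLU()]
            length = length - kernel + 1
            if pool > 1:
                layers.append(_MaxPool1D(pool))
                length //= pool
            if length < 1:
                raise ValueError("pooling reduced the signal to length 0")
            c_in = n_filters
        layers.append(_Flatten())
        d = c_in * length
        for width in self.fc_sizes:
            layers += [_Dense(d, width, rng), _ReLU()]
            d = width
        head = _Dense(d, n_labels, rng)
        return layers, head

    def _forward(self, X, upto_features=False):
        a = np.asarray(X, dtype=float)[:, None, :]
        for layer in self.body_:
            a = layer.forward(a)
        if upto_features:
            return a
        return self.head_.forward(a)

    # -- training ---------------------------------------------------------

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X must be n×L and Y n×n_labels")
        if self.loss not in ("bce", "softmax_ce"):
            raise ValueError(f"unknown loss {self.loss!r}")
        n, L = X.shape
        if self.epochs > 0 and n < self.batch_size:
            raise ValueError("need n >= batch_size")
        rng = np.random.default_rng(self.seed)
        self.input_length_ = L
        self.n_labels_ = Y.shape[1]
        self.body_, self.head_ = self._build(L, Y.shape[1], rng)
        opt = _Adam(self.body_ + [self.head_], self.learning_rate)
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self._forward(X[idx])
                dz = self._loss_grad(Y[idx], logits)
                da = self.head_.backward(dz)
                for layer in reversed(self.body_):
                    da = layer.backward(da)
                opt.step()
            self.loss_history_.append(self._loss(Y, self._forward(X)))
        return self

    def _loss(self, Y, logits):
        if self.loss == "bce":
            return bce_loss(Y, logits)
        return softmax_ce_loss(Y, logits)

    def _loss_grad(self, Y, logits):
        n = Y.shape[0]
        if self.loss == "bce":
            return (sigmoid(logits) - Y) / n
        dist = Y / Y.sum(axis=1, keepdims=True)
        return (softmax_probs(logits) - dist) / n

    # -- inference --------------------------------------------------------

    def _check_input(self, X):
        check_is_fitted(self, "body_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_length_:
            raise ValueError(
                f"expected n×{self.input_length_} input, got {X.shape}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        """Feature matrix: last hidden FC activations (all ≥ 0)."""
        return self._forward(self._check_input(X), upto_features=True)

    def decision_function(self, X) -> np.ndarray:
        return self._forward(self._check_input(X))

    def predict_proba(self, X) -> np.ndarray:
        """Per-location probabilities: sigmoid logits under the BCE loss,
        softmax under the cross-entropy loss."""
        logits = self.decision_function(X)
        if self.loss == "bce":
            return sigmoid(logits)
        return softmax_probs(logits)


# ---------------------------------------------------------------------------
# Functional wrappers

def train_cnn(X, Y, config: CNNConfig):
    """Train an extractor; returns (model, per-epoch loss history)."""
    model = ConvNetFeatureExtractor(
        conv_blocks=config.conv_blocks,
        fc_sizes=config.fc_sizes,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        loss=config.loss,
        seed=config.seed,
    ).fit(X, Y)
    return model, list(model.loss_history_)


def extract_features(model: ConvNetFeatureExtractor, X) -> np.ndarray:
    return model.transform(X)


def predict_cnn(model: ConvNetFeatureExtractor, X) -> np.ndarray:
    return model.predict_proba(X)
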