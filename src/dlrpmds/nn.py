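"""Minimal deterministic dense networks with Adam.

Both the time-lagged autoencoder and the latent-space classifier are plain
multi-layer perceptrons: Glorot-uniform weight initialization, zero biases,
leaky-ReLU hidden activations, Adam optimization.  Everything runs on CPU
with numpy and a caller-supplied Generator, so a fixed seed gives
bit-identical weights and predictions.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ValidationError

ACTIVATIONS = ("leaky_relu", "linear", "sigmoid")


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class DenseNet:
    """Fully connected net ``dims[0] -> ... -> dims[-1]``.

    ``activations`` gives the activation applied after each of the
    ``len(dims) - 1`` affine layers; the default is leaky-ReLU on every
    layer except a linear last one.  The autoencoder composite needs this
    per-layer control because its latent (encoder-output) layer is linear
    even though it sits mid-network.  ``init="zeros"`` is a test hook that
    bypasses Glorot.
    """

    def __init__(
        self,
        dims: list[int],
        activations: list[str] | None = None,
        leaky_slope: float = 0.01,
        rng: np.random.Generator | None = None,
        init: str = "glorot",
    ) -> None:
        if len(dims) < 2:
            raise ValidationError("need at least input and output dimensions")
        n_layers = len(dims) - 1
        if activations is None:
            activations = ["leaky_relu"] * (n_layers - 1) + ["linear"]
        if len(activations) != n_layers:
            raise ValidationError(
                f"{len(activations)} activations for {n_layers} layers"
            )
        for a in activations:
            if a not in ACTIVATIONS:
                raise ValidationError(f"unknown activation {a!r}")
        self.dims = list(dims)
        self.activations = list(activations)
        self.leaky_slope = leaky_slope
        if init == "glorot":
            if rng is None:
                raise ValidationError("Glorot init requires an rng")
            self.weights = []
            for fan_in, fan_out in zip(dims, dims[1:]):
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        elif init == "zeros":
            self.weights = [np.zeros((i, o)) for i, o in zip(dims, dims[1:])]
        else:
            raise ValidationError(f"unknown init {init!r}")
        self.biases = [np.zeros(o) for o in dims[1:]]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def _act(self, z: np.ndarray, kind: str) -> np.ndarray:
        if kind == "linear":
            return z
        if kind == "leaky_relu":
            return np.where(z > 0, z, self.leaky_slope * z)
        return sigmoid(z)

    def _act_grad(self, z: np.ndarray, h: np.ndarray, kind: str) -> np.ndarray:
        if kind == "linear":
            return np.ones_like(z)
        if kind == "leaky_relu":
            return np.where(z > 0, 1.0, self.leaky_slope)
        return h * (1.0 - h)  # sigmoid, from the activation value

    def forward(self, X: np.ndarray):
        """Return (output, preactivations, activations) for backprop."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.dims[0]:
            raise ValidationError(
                f"input shape {X.shape} incompatible with input dim {self.dims[0]}"
            )
        acts = [X]
        pre = []
        h = X
        for li in range(self.n_layers):
            z = h @ self.weights[li] + self.biases[li]
            pre.append(z)
            h = self._act(z, self.activations[li])
            acts.append(h)
        return h, pre, acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def _backward(self, delta_out, pre, acts):
        """Gradients given dL/dz at the output layer (pre-activation)."""
        gW = [None] * self.n_layers
        gb = [None] * self.n_layers
        delta = delta_out
        for li in range(self.n_layers - 1, -1, -1):
            gW[li] = acts[li].T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ self.weights[li].T) * self._act_grad(
                    pre[li - 1], acts[li], self.activations[li - 1]
                )
        return gW, gb


def train_dense(
    net: DenseNet,
    X: np.ndarray,
    Y: np.ndarray,
    loss: str = "mse",
    epochs: int = 50,
    batch_size: int = 64,
    learning_rate: float = 0.001,
    rng: np.random.Generator | None = None,
    shuffle: bool = True,
) -> list[float]:
    """Mini-batch Adam; returns the per-epoch mean training loss.

    ``loss="mse"``: L = (1/N) sum_i ||y_i - yhat_i||^2 (squared L2 norm per
    sample, averaged over samples); requires a linear output layer.
    ``loss="bce"``: per-unit binary cross-entropy, averaged over samples;
    requires a sigmoid output layer.  Both pairings give the simple
    ``out - y`` form for dL/dz at the output.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("X and Y row counts differ")
    if loss == "mse" and net.activations[-1] != "linear":
        raise ValidationError("mse loss expects a linear output layer")
    if loss == "bce" and net.activations[-1] != "sigmoid":
        raise ValidationError("bce loss requires a sigmoid output layer")
    if loss not in ("mse", "bce"):
        raise ValidationError(f"unknown loss {loss!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    n = X.shape[0]
    batch_size = min(batch_size, n)

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    mW = [np.zeros_like(w) for w in net.weights]
    vW = [np.zeros_like(w) for w in net.weights]
    mb = [np.zeros_like(b) for b in net.biases]
    vb = [np.zeros_like(b) for b in net.biases]
    step = 0
    history: list[float] = []

    for epoch in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], Y[idx]
            out, pre, acts = net.forward(xb)
            m = xb.shape[0]
            if loss == "mse":
                resid = out - yb
                batch_loss = float(np.sum(resid**2)) / m
                delta = 2.0 * resid / m
            else:
                p = np.clip(out, 1e-12, 1 - 1e-12)
                batch_loss = float(
                    -np.sum(yb * np.log(p) + (1 - yb) * np.log(1 - p))
                ) / m
                delta = (out - yb) / m
            if not np.isfinite(batch_loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            total += batch_loss * m
            gW, gb = net._backward(delta, pre, acts)
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for li in range(net.n_layers):
                mW[li] = beta1 * mW[li] + (1 - beta1) * gW[li]
                vW[li] = beta2 * vW[li] + (1 - beta2) * gW[li] ** 2
                net.weights[li] -= learning_rate * (mW[li] / bc1) / (
                    np.sqrt(vW[li] / bc2) + eps
                )
                mb[li] = beta1 * mb[li] + (1 - beta1) * gb[li]
                vb[li] = beta2 * vb[li] + (1 - beta2) * gb[li] ** 2
                net.biases[li] -= learning_rate * (mb[li] / bc1) / (
                    np.sqrt(vb[li] / bc2) + eps
                )
        history.append(total / n)
    return history
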