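"""Time-one-lagged autoencoder over standardized torsion frames.

The encoder E maps a standardized frame X_t through M leaky-ReLU hidden
layers and a final linear layer to the q-dimensional latent H; the decoder
D mirrors the widths back to the input dimension.  Training minimizes the
mean squared reconstruction error against the *next* frame,

    L(X, X*) = (1/N) ||X* - D(E(X))||^2,

so the latent space is pushed towards slowly varying torsional modes rather
than frame-to-frame noise.  Glorot-uniform initialization, Adam with
learning rate 0.001.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import ValidationError
from .features import FeatureSpace, LaggedPairSet
from .nn import DenseNet, train_dense

CHECKPOINT_VERSION = 1


@dataclass
class AEConfig:
    """Autoencoder hyperparameters.

    Defaults: three hidden layers tapering 512-256-64 into a latent
    dimension q = 6, leaky-ReLU slope 0.01, Adam lr 0.001.
    """

    hidden_widths: list[int] = field(default_factory=lambda: [512, 256, 64])
    latent_dim: int = 6
    leaky_slope: float = 0.01
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    hidden_activation: str = "leaky_relu"  # "linear" enables the PCA limit
    init: str = "glorot"

    def __post_init__(self) -> None:
        if not self.hidden_widths or any(w < 1 for w in self.hidden_widths):
            raise ValidationError("hidden_widths must be positive integers")
        if self.latent_dim < 1:
            raise ValidationError("latent_dim must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be positive")

    @property
    def n_hidden_layers(self) -> int:
        return len(self.hidden_widths)


@dataclass
class AutoencoderModel:
    """Trained encoder/decoder pair tied to a FeatureSpace."""

    encoder: DenseNet
    decoder: DenseNet
    config: AEConfig
    feature_space: FeatureSpace
    loss_history: list[float]

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    def reconstruct(self, frames: np.ndarray) -> np.ndarray:
        return self.decoder.predict(self.encoder.predict(np.asarray(frames, float)))


def _build_nets(config: AEConfig, n_features: int, rng) -> tuple[DenseNet, DenseNet]:
    if config.latent_dim >= n_features:
        raise ValidationError(
            f"latent_dim {config.latent_dim} must be < input dim {n_features}"
        )
    act = config.hidden_activation
    enc_dims = [n_features, *config.hidden_widths, config.latent_dim]
    dec_dims = [config.latent_dim, *reversed(config.hidden_widths), n_features]
    # final layer of each stack is linear, exactly as the encoder/decoder
    # compositions are written
    enc_act = [act] * len(config.hidden_widths) + ["linear"]
    dec_act = [act] * len(config.hidden_widths) + ["linear"]
    encoder = DenseNet(enc_dims, enc_act, config.leaky_slope, rng=rng, init=config.init)
    decoder = DenseNet(dec_dims, dec_act, config.leaky_slope, rng=rng, init=config.init)
    return encoder, decoder


class _Composite(DenseNet):
    """Encoder and decoder trained jointly as one weight stack."""

    def __init__(self, encoder: DenseNet, decoder: DenseNet, slope: float):
        self.dims = encoder.dims + decoder.dims[1:]
        self.activations = encoder.activations + decoder.activations
        self.leaky_slope = slope
        self.weights = encoder.weights + decoder.weights
        self.biases = encoder.biases + decoder.biases


def train_autoencoder(
    pairs: LaggedPairSet, config: AEConfig, feature_space: FeatureSpace
) -> AutoencoderModel:
    """Train D(E(X_t)) to reconstruct X_{t+lag} under MSE with Adam."""
    n_features = pairs.inputs.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    encoder, decoder = _build_nets(config, n_features, rng)
    composite = _Composite(encoder, decoder, config.leaky_slope)
    history = train_dense(
        composite,
        pairs.inputs,
        pairs.targets,
        loss="mse",
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        rng=rng,
    )
    if history[-1] > history[0]:
        # Adam on these smooth targets should never end worse than it began
        raise ValidationError(
            f"autoencoder failed to reduce loss ({history[0]:.4g} -> {history[-1]:.4g})"
        )
    return AutoencoderModel(
        encoder=encoder,
        decoder=decoder,
        config=config,
        feature_space=feature_space,
        loss_history=history,
    )


def encode(model: AutoencoderModel, frames: np.ndarray) -> np.ndarray:
    """Latent representation H = E(X) for standardized frames, shape (n, q)."""
    X = np.asarray(frames, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return model.encoder.predict(X)


def save_checkpoint(model: AutoencoderModel, path) -> None:
    """Single-archive checkpoint: config + feature space (JSON) + weights."""
    path = Path(path)
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": {
            "hidden_widths": model.config.hidden_widths,
            "latent_dim": model.config.latent_dim,
            "leaky_slope": model.config.leaky_slope,
            "learning_rate": model.config.learning_rate,
            "epochs": model.config.epochs,
            "batch_size": model.config.batch_size,
            "seed": model.config.seed,
            "hidden_activation": model.config.hidden_activation,
        },
        "loss_history": model.loss_history,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("feature_space.json", model.feature_space.to_json())
        for tag, net in (("encoder", model.encoder), ("decoder", model.decoder)):
            for i, (w, b) in enumerate(zip(net.weights, net.biases)):
                zf.writestr(f"{tag}_W{i}.npy", _npy_bytes(w))
                zf.writestr(f"{tag}_b{i}.npy", _npy_bytes(b))


def load_checkpoint(path) -> AutoencoderModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValidationError(f"unsupported checkpoint version {meta['version']}")
        config = AEConfig(**meta["config"])
        space = FeatureSpace.from_json(zf.read("feature_space.json").decode())
        encoder, decoder = _build_nets(
            config, space.n_features, np.random.default_rng(config.seed)
        )
        for tag, net in (("encoder", encoder), ("decoder", decoder)):
            for i in range(net.n_layers):
                net.weights[i] = _npy_load(zf.read(f"{tag}_W{i}.npy"))
                net.biases[i] = _npy_load(zf.read(f"{tag}_b{i}.npy"))
    return AutoencoderModel(
        encoder=encoder,
        decoder=decoder,
        config=config,
        feature_space=space,
        loss_history=list(meta["loss_history"]),
    )


def _npy_bytes(arr: np.ndarray) -> bytes:
    import io

    buf = io.BytesIO()
    np.save(buf, arr)
    return buf.getvalue()


def _npy_load(data: bytes) -> np.ndarray:
    import io

    return np.load(io.BytesIO(data))
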