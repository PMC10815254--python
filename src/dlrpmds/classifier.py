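"""Latent-space classification: SMOTE balancing, the multi-layer classifier,
and performance metrics.

Frames derived from pathogenic variants carry the "deleterious" label;
benign- and wildtype-derived frames carry "unknown".  Because ClinVar-style
training sets are heavily imbalanced, the minority class is oversampled
with SMOTE before training.  The classifier is a multi-layer network whose
hidden activations are leaky-ReLU and whose final activation alone is a
sigmoid; its two outputs are normalized to the probability pair
(P(unknown), P(deleterious)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.neighbors import NearestNeighbors

from .datatypes import ValidationError
from .nn import DenseNet, train_dense

#: Column order of the classifier's two-unit output head.
CLASS_NAMES = ("unknown", "deleterious")

#: Labels mapped to the binary "deleterious" side.
DELETERIOUS_LABELS = frozenset({"pathogenic"})
UNKNOWN_SIDE_LABELS = frozenset({"benign", "wildtype"})


@dataclass
class LabeledLatentSet:
    """Latent rows with binary labels (1 = deleterious, 0 = unknown side)."""

    latents: np.ndarray  # (n, q)
    labels: np.ndarray  # (n,) in {0, 1}
    variant_ids: np.ndarray  # (n,) str

    def __post_init__(self) -> None:
        self.latents = np.asarray(self.latents, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.variant_ids = np.asarray(self.variant_ids)
        if self.latents.ndim != 2:
            raise ValidationError("latents must be a 2-D matrix")
        if len(self.labels) != len(self.latents) or len(self.variant_ids) != len(
            self.latents
        ):
            raise ValidationError("latents, labels and variant_ids must align")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be binary (0/1)")

    @property
    def n(self) -> int:
        return len(self.labels)


def binary_labels_from_meta(meta: pd.DataFrame) -> np.ndarray:
    """Map variant labels to the binary training target.

    Wildtype and benign frames are pooled on the "unknown" (0) side;
    pathogenic frames are "deleterious" (1).
    """
    out = np.empty(len(meta), dtype=int)
    for i, lab in enumerate(meta["label"]):
        if lab in DELETERIOUS_LABELS:
            out[i] = 1
        elif lab in UNKNOWN_SIDE_LABELS:
            out[i] = 0
        else:
            raise ValidationError(f"frame with non-training label {lab!r}")
    return out


def smote_balance(
    data: LabeledLatentSet, k_neighbors: int = 5, seed: int = 0
) -> LabeledLatentSet:
    """Oversample the minority class to parity with SMOTE.

    Each synthetic row is x_i + u * (x_nn - x_i) with u ~ U[0, 1] and x_nn
    one of the k nearest minority neighbours of a minority row x_i
    (Euclidean distance in the latent space).  Original rows are returned
    unchanged, synthetic rows appended.
    """
    counts = np.bincount(data.labels, minlength=2)
    if counts[0] == counts[1]:
        return data
    minority = int(np.argmin(counts))
    n_needed = int(abs(counts[0] - counts[1]))
    min_idx = np.flatnonzero(data.labels == minority)
    if len(min_idx) < 2:
        raise ValidationError(
            "minority class has a single sample; SMOTE cannot interpolate — "
            "add more labeled variants or augment with wildtype frames"
        )
    X_min = data.latents[min_idx]
    k = min(k_neighbors, len(min_idx) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    # drop self-neighbour in column 0
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(min_idx), size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    x_i = X_min[base]
    x_nn = X_min[neigh[base, pick]]
    synth = x_i + u[:, None] * (x_nn - x_i)

    return LabeledLatentSet(
        latents=np.vstack([data.latents, synth]),
        labels=np.concatenate([data.labels, np.full(n_needed, minority)]),
        variant_ids=np.concatenate(
            [data.variant_ids, np.array([f"smote_{i}" for i in range(n_needed)])]
        ),
    )


@dataclass
class ClassifierConfig:
    """Classifier hyperparameters: 3 hidden layers x 512 nodes, no dropout."""

    hidden_layers: int = 3
    width: int = 512
    dropout: float = 0.0
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 64
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1:
            raise ValidationError("need at least one hidden layer")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if self.dropout != 0.0:
            raise ValidationError("dropout > 0 is not implemented (default is 0)")


@dataclass
class ClassifierModel:
    net: DenseNet
    config: ClassifierConfig
    loss_history: list[float] = field(default_factory=list)

    def predict_proba(self, latents: np.ndarray) -> np.ndarray:
        """Normalized (P(unknown), P(deleterious)) per row; rows sum to 1."""
        X = np.asarray(latents, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        raw = self.net.predict(X)  # two sigmoid units
        return raw / raw.sum(axis=1, keepdims=True)

    def predict_deleterious(self, latents: np.ndarray) -> np.ndarray:
        return self.predict_proba(latents)[:, 1]


def train_classifier(
    data: LabeledLatentSet, config: ClassifierConfig
) -> ClassifierModel:
    """Train the latent-space classifier with BCE on one-hot labels."""
    classes = np.unique(data.labels)
    if len(classes) < 2:
        raise ValidationError("both classes must be present to train the classifier")
    q = data.latents.shape[1]
    dims = [q] + [config.width] * config.hidden_layers + [2]
    activations = ["leaky_relu"] * config.hidden_layers + ["sigmoid"]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    net = DenseNet(dims, activations, config.leaky_slope, rng=rng)
    onehot = np.zeros((data.n, 2))
    onehot[np.arange(data.n), data.labels] = 1.0
    history = train_dense(
        net,
        data.latents,
        onehot,
        loss="bce",
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        rng=rng,
    )
    return ClassifierModel(net=net, config=config, loss_history=history)


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    accuracy: float
    auc: float
    roc_points: np.ndarray  # (k, 2): FPR, TPR

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "accuracy": self.accuracy,
            "auc": self.auc,
        }


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> Metrics:
    """Sensitivity, specificity, balanced accuracy = (sens + spec)/2, ROC/AUC.

    ``scores`` are P(deleterious) per sample; ``labels`` are binary with
    1 = deleterious.  AUC is computed over all score cut-points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    if scores.min() < 0 or scores.max() > 1:
        raise ValidationError("scores must lie in [0, 1]")
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUC undefined: labels contain a single class")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    fpr, tpr, _ = roc_curve(labels, scores)
    return Metrics(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        accuracy=(tp + tn) / len(labels),
        auc=float(sk_auc(fpr, tpr)),
        roc_points=np.column_stack([fpr, tpr]),
    )
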