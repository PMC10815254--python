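"""Frame flattening, standardization, and time-lagged training pairs.

A frame of R residues is flattened residue-major, phi before psi, into a
vector of length 2R.  Standardization is per-feature (z-score) with
parameters fitted on training data only; the autoencoder consumes pairs
(X_t, X_{t+lag}) that never cross trajectory boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import RSPTrajectory, ValidationError

EPS_SCALE = 1e-8  # floor for constant features


@dataclass
class FeatureSpace:
    """Flattening convention plus per-feature mean/scale."""

    n_residues: int
    means: np.ndarray  # (2R,)
    scales: np.ndarray  # (2R,), floored at EPS_SCALE

    @property
    def n_features(self) -> int:
        return 2 * self.n_residues

    def transform(self, frames: np.ndarray) -> np.ndarray:
        """Standardize flattened frames of shape (n, 2R)."""
        X = np.asarray(frames, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return (X - self.means) / self.scales

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scales + self.means

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_residues": self.n_residues,
                "means": self.means.tolist(),
                "scales": self.scales.tolist(),
                "order": "residue-major, phi before psi",
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FeatureSpace":
        d = json.loads(s)
        return cls(
            n_residues=int(d["n_residues"]),
            means=np.asarray(d["means"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
        )


def flatten_trajectory(traj: RSPTrajectory) -> np.ndarray:
    """Frames as a (n_frames, 2R) matrix: residue-major, phi then psi."""
    return traj.angle_array().reshape(traj.n_frames, -1)


def fit_feature_space(trajectories: list[RSPTrajectory]) -> FeatureSpace:
    """Per-feature mean and std over all frames of the given trajectories."""
    if not trajectories:
        raise ValidationError("no trajectories to fit on")
    R = trajectories[0].n_residues
    for t in trajectories:
        if t.n_residues != R:
            raise ValidationError(
                f"inconsistent residue counts: {t.variant_id!r} has "
                f"{t.n_residues}, expected {R}"
            )
    X = np.vstack([flatten_trajectory(t) for t in trajectories])
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales = np.where(scales < EPS_SCALE, EPS_SCALE, scales)
    # constant features standardize exactly to 0
    means = np.where(X.std(axis=0) < EPS_SCALE, X[0], means)
    return FeatureSpace(n_residues=R, means=means, scales=scales)


@dataclass
class LaggedPairSet:
    """Standardized (X_t, X_{t+lag}) pairs with per-row provenance."""

    inputs: np.ndarray  # (N, 2R)
    targets: np.ndarray  # (N, 2R)
    meta: pd.DataFrame  # columns: variant_id, label, time_index

    @property
    def n_pairs(self) -> int:
        return self.inputs.shape[0]


def make_lagged_pairs(
    trajectories: list[RSPTrajectory],
    space: FeatureSpace,
    lag: int = 1,
    strict: bool = False,
) -> LaggedPairSet:
    """Build time-lagged pairs; pairs never span two trajectories.

    Trajectories with <= lag frames contribute no pairs (warning; error in
    strict mode).  N = sum over trajectories of (n_frames - lag).
    """
    if lag < 1:
        raise ValidationError("lag must be >= 1")
    X_parts, Y_parts, meta_parts = [], [], []
    for traj in trajectories:
        if traj.n_frames <= lag:
            msg = (
                f"trajectory {traj.variant_id!r} has {traj.n_frames} frames, "
                f"<= lag {lag}: no pairs"
            )
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        Z = space.transform(flatten_trajectory(traj))
        X_parts.append(Z[:-lag])
        Y_parts.append(Z[lag:])
        meta_parts.append(
            pd.DataFrame(
                {
                    "variant_id": traj.variant_id,
                    "label": traj.label,
                    "time_index": [f.time_index for f in traj.frames[:-lag]],
                }
            )
        )
    if not X_parts:
        raise ValidationError("no trajectory long enough to form lagged pairs")
    return LaggedPairSet(
        inputs=np.vstack(X_parts),
        targets=np.vstack(Y_parts),
        meta=pd.concat(meta_parts, ignore_index=True),
    )


def standardized_frames(
    trajectories: list[RSPTrajectory], space: FeatureSpace
) -> tuple[np.ndarray, pd.DataFrame]:
    """All frames standardized, with (variant_id, label, time_index) metadata."""
    Z_parts, meta_parts = [], []
    for traj in trajectories:
        Z_parts.append(space.transform(flatten_trajectory(traj)))
        meta_parts.append(
            pd.DataFrame(
                {
                    "variant_id": traj.variant_id,
                    "label": traj.label,
                    "time_index": [f.time_index for f in traj.frames],
                }
            )
        )
    return np.vstack(Z_parts), pd.concat(meta_parts, ignore_index=True)
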