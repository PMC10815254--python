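"""Core containers shared across the pipeline.

A *torsion frame* is one MD snapshot reduced to its Ramachandran scatter
plot: the ordered vector of backbone (phi, psi) dihedral pairs, one pair per
residue.  A trajectory is the time-ordered stack of such frames for a single
protein variant, tagged with its training label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Allowed training labels for a variant trajectory.
LABELS = ("benign", "pathogenic", "wildtype", "unknown")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class TorsionFrame:
    """One snapshot: ``angles[r] = (phi, psi)`` in degrees for residue ``r``."""

    angles: np.ndarray  # shape (R, 2), degrees in [-180, 180)
    time_index: int

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.ndim != 2 or a.shape[1] != 2:
            raise ValidationError(f"angles must have shape (R, 2), got {a.shape}")
        if self.time_index < 0:
            raise ValidationError("time_index must be non-negative")
        object.__setattr__(self, "angles", a)

    @property
    def n_residues(self) -> int:
        return self.angles.shape[0]


@dataclass
class RSPTrajectory:
    """Time-ordered Ramachandran scatter plots for one simulated variant."""

    variant_id: str
    label: str
    frames: list[TorsionFrame]
    residue_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(
                f"label {self.label!r} not in {LABELS} for variant {self.variant_id!r}"
            )
        if self.frames:
            r = self.frames[0].n_residues
            for f in self.frames:
                if f.n_residues != r:
                    raise ValidationError(
                        f"inconsistent residue count in {self.variant_id!r}: "
                        f"{f.n_residues} != {r}"
                    )
            times = [f.time_index for f in self.frames]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValidationError(
                    f"frames of {self.variant_id!r} not strictly time-ordered"
                )
            if not self.residue_labels:
                self.residue_labels = [f"R{i + 1}" for i in range(r)]
            if len(self.residue_labels) != r:
                raise ValidationError(
                    f"{len(self.residue_labels)} residue labels for {r} residues"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        if not self.frames:
            raise ValidationError("empty trajectory has no residue count")
        return self.frames[0].n_residues

    def angle_array(self) -> np.ndarray:
        """Stack frames into an array of shape (n_frames, R, 2)."""
        if not self.frames:
            raise ValidationError("empty trajectory")
        return np.stack([f.angles for f in self.frames])


def wrap_angles(a: np.ndarray | float) -> np.ndarray:
    """Wrap angles in degrees into the principal range [-180, 180)."""
    return np.mod(np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0
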