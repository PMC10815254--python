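"""Class-structured synthetic torsion-angle trajectories.

Real inputs to this tool are Ramachandran scatter plots extracted from MD
simulations of protein variants.  This module emulates their statistical
signature without any physics: each residue's (phi, psi) angles fluctuate
around a basin centre with a wrapped-normal AR(1) process whose stationary
spread matches a von Mises concentration kappa, giving both the angular
basins and the temporal autocorrelation that the time-lagged autoencoder
exploits.  Pathogenic-class trajectories shift the basin centres of a small
subset of residues, mimicking variants that perturb local but not global
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import RSPTrajectory, TorsionFrame, ValidationError, wrap_angles

#: Conventional alpha-helical basin used as the benign/wildtype reference.
DEFAULT_CENTER = (-60.0, -45.0)


@dataclass(frozen=True)
class BasinSpec:
    """Angular basin for one residue.

    ``concentration`` is the von Mises kappa of the stationary marginal of
    each angle; ``ar_coefficient`` is the lag-1 autocorrelation of the
    angular deviations from the basin centre.
    """

    center_phi: float
    center_psi: float
    concentration: float = 8.0
    ar_coefficient: float = 0.5

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValidationError(f"concentration must be > 0, got {self.concentration}")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValidationError(
                f"ar_coefficient must be in [0, 1), got {self.ar_coefficient}"
            )
        for name in ("center_phi", "center_psi"):
            v = getattr(self, name)
            if not -180.0 <= v < 180.0:
                raise ValidationError(f"{name}={v} outside [-180, 180)")

    @property
    def sigma_deg(self) -> float:
        """Stationary standard deviation (degrees) matching kappa.

        For a von Mises distribution with large kappa the marginal is close
        to a normal with variance 1/kappa (radians^2); the wrapped-normal
        AR(1) process targets that spread.
        """
        return math.degrees(1.0 / math.sqrt(self.concentration))


@dataclass
class SyntheticClassSpec:
    """Generating distribution for one variant class.

    All variants of a class share the same basin structure; only the noise
    realisation differs between variants.  ``separation`` shifts the phi
    centre of the residues in ``shifted_residues`` relative to the benign
    reference basins, so class differences are local.
    """

    label: str
    basins: list[BasinSpec]
    separation: float = 0.0
    shifted_residues: list[int] | None = None
    n_variants: int = 1
    n_frames_per_variant: int = 334
    seed: int = 0
    #: fraction of residues shifted when shifted_residues is not given
    shifted_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.label not in ("benign", "pathogenic", "wildtype", "unknown"):
            raise ValidationError(f"bad class label {self.label!r}")
        if not self.basins:
            raise ValidationError("at least one residue basin required")
        if self.separation < 0:
            raise ValidationError("separation must be non-negative")
        if self.n_variants < 1:
            raise ValidationError("n_variants must be positive")
        if self.n_frames_per_variant < 2:
            raise ValidationError(
                "n_frames_per_variant must be >= 2 (lagged pairs must exist)"
            )
        if self.shifted_residues is None:
            k = max(1, int(round(self.shifted_fraction * len(self.basins))))
            self.shifted_residues = list(range(k))
        for r in self.shifted_residues:
            if not 0 <= r < len(self.basins):
                raise ValidationError(f"shifted residue index {r} out of range")

    @property
    def n_residues(self) -> int:
        return len(self.basins)

    def effective_centers(self) -> np.ndarray:
        """Basin centres after applying the class shift, shape (R, 2)."""
        centers = np.array(
            [[b.center_phi, b.center_psi] for b in self.basins], dtype=float
        )
        if self.separation:
            centers[self.shifted_residues, 0] = wrap_angles(
                centers[self.shifted_residues, 0] + self.separation
            )
        return centers


def make_class_spec(
    label: str,
    n_residues: int = 20,
    separation: float = 0.0,
    concentration: float = 8.0,
    ar_coefficient: float = 0.5,
    n_variants: int = 1,
    n_frames_per_variant: int = 334,
    seed: int = 0,
    center: tuple[float, float] = DEFAULT_CENTER,
    shifted_residues: list[int] | None = None,
) -> SyntheticClassSpec:
    """Convenience constructor with identical basins on every residue."""
    basins = [
        BasinSpec(center[0], center[1], concentration, ar_coefficient)
        for _ in range(n_residues)
    ]
    return SyntheticClassSpec(
        label=label,
        basins=basins,
        separation=separation,
        shifted_residues=shifted_residues,
        n_variants=n_variants,
        n_frames_per_variant=n_frames_per_variant,
        seed=seed,
    )


_LABEL_STREAM = {"benign": 0, "pathogenic": 1, "wildtype": 2, "unknown": 3}


def _variant_rng(spec: SyntheticClassSpec, variant_index: int) -> np.random.Generator:
    # independent, reproducible stream per (seed, class, variant)
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=spec.seed,
            spawn_key=(_LABEL_STREAM[spec.label], variant_index),
        )
    )


def simulate_trajectory(spec: SyntheticClassSpec, variant_index: int) -> RSPTrajectory:
    """Simulate one variant's trajectory of Ramachandran frames.

    Each angle follows ``d_t = a * d_{t-1} + sqrt(1 - a^2) * sigma * eps_t``
    around its basin centre, with ``d_0`` drawn from the stationary
    distribution, then wrapped to [-180, 180).  Deterministic for a fixed
    (spec.seed, variant_index).
    """
    if not 0 <= variant_index < spec.n_variants:
        raise ValidationError(
            f"variant_index {variant_index} out of range [0, {spec.n_variants})"
        )
    rng = _variant_rng(spec, variant_index)
    T, R = spec.n_frames_per_variant, spec.n_residues
    centers = spec.effective_centers()  # (R, 2)
    a = np.array([b.ar_coefficient for b in spec.basins])[:, None]  # (R, 1)
    sigma = np.array([b.sigma_deg for b in spec.basins])[:, None]  # (R, 1)

    eps = rng.standard_normal((T, R, 2))
    dev = np.empty((T, R, 2))
    dev[0] = sigma * eps[0]  # stationary start
    innov_scale = np.sqrt(1.0 - a**2) * sigma
    for t in range(1, T):
        dev[t] = a * dev[t - 1] + innov_scale * eps[t]

    angles = wrap_angles(centers[None, :, :] + dev)
    frames = [TorsionFrame(angles[t], time_index=t) for t in range(T)]
    return RSPTrajectory(
        variant_id=f"{spec.label}_{variant_index:03d}",
        label=spec.label,
        frames=frames,
    )


def simulate_class(spec: SyntheticClassSpec) -> list[RSPTrajectory]:
    """All ``n_variants`` trajectories of a class."""
    return [simulate_trajectory(spec, i) for i in range(spec.n_variants)]


def write_rama_xvg(traj: RSPTrajectory, path) -> None:
    """Write a trajectory in the ``gmx rama`` XVG dialect.

    Header lines start with '#' or '@'; each data row is
    ``phi psi residue-label``.  Frames are concatenated in time order with
    residues in fixed order inside each frame, exactly as ``gmx rama``
    emits them (no frame separators).
    """
    if not traj.frames:
        raise ValidationError(f"refusing to write empty trajectory {traj.variant_id!r}")
    lines = [
        f"# Ramachandran scatter plot for variant {traj.variant_id}",
        f"# label: {traj.label}",
        '@    title "Ramachandran Plot"',
        '@    xaxis  label "Phi"',
        '@    yaxis  label "Psi"',
        "@TYPE xy",
    ]
    for frame in traj.frames:
        for r, (phi, psi) in enumerate(frame.angles):
            lines.append(f"{phi:.6f}  {psi:.6f}  {traj.residue_labels[r]}")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed to write XVG to {path}: {exc}") from exc


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees (oracle-friendly helper)."""
    rad = np.radians(np.asarray(angles_deg, dtype=float))
    return float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))
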