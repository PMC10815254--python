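"""Reading ``gmx rama`` XVG files and label manifests.

``gmx rama`` concatenates all frames of a trajectory into one file, one row
per (residue, frame) with no frame separators, so frame boundaries must be
recovered from the repeating residue-label cycle: a new frame starts when
the first residue label of the cycle recurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LABELS, RSPTrajectory, TorsionFrame, ValidationError


class XVGParseError(ValueError):
    """Malformed ``gmx rama`` file (names the offending line)."""


def parse_rama_xvg(
    path,
    variant_id: str | None = None,
    label: str = "unknown",
    residue_count_hint: int | None = None,
    strict: bool = True,
) -> RSPTrajectory:
    """Parse a ``gmx rama``-style XVG file into a trajectory.

    Parameters
    ----------
    residue_count_hint
        Force the per-frame residue count instead of inferring it from the
        label cycle; needed when residue labels are not unique within a
        frame.
    strict
        If the final frame is incomplete, raise (strict) or truncate it
        with a warning (lenient).
    """
    path = Path(path)
    phis: list[float] = []
    psis: list[float] = []
    res_labels: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise XVGParseError(f"{path}:{lineno}: expected 'phi psi label' row")
            try:
                phi, psi = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise XVGParseError(f"{path}:{lineno}: non-numeric angle: {exc}") from exc
            phis.append(phi)
            psis.append(psi)
            res_labels.append(parts[2])
    if not phis:
        raise XVGParseError(f"{path}: no data rows")

    if residue_count_hint is not None:
        R = int(residue_count_hint)
        if R < 1:
            raise ValidationError("residue_count_hint must be positive")
    else:
        # frame length = distance until the first residue label recurs
        first = res_labels[0]
        R = next((i for i in range(1, len(res_labels)) if res_labels[i] == first),
                 len(res_labels))

    n_rows = len(phis)
    if n_rows % R != 0:
        if strict:
            raise XVGParseError(
                f"{path}: {n_rows} rows is not a multiple of frame size {R} "
                f"(incomplete final frame begins at line > {n_rows - n_rows % R})"
            )
        keep = n_rows - n_rows % R
        warnings.warn(
            f"{path}: truncating {n_rows - keep} trailing rows of an incomplete frame",
            stacklevel=2,
        )
        phis, psis, res_labels = phis[:keep], psis[:keep], res_labels[:keep]
        n_rows = keep

    cycle = res_labels[:R]
    for i, lab in enumerate(res_labels):
        if lab != cycle[i % R]:
            raise XVGParseError(
                f"{path}: residue-label cycle breaks at data row {i + 1} "
                f"(expected {cycle[i % R]!r}, found {lab!r})"
            )

    angles = np.column_stack([phis, psis]).reshape(-1, R, 2)
    frames = [TorsionFrame(angles[t], time_index=t) for t in range(angles.shape[0])]
    return RSPTrajectory(
        variant_id=variant_id if variant_id is not None else path.stem,
        label=label,
        frames=frames,
        residue_labels=list(cycle),
    )


def select_window(
    traj: RSPTrajectory, start_index: int, end_index: int, stride: int = 1
) -> RSPTrajectory:
    """Contiguous (optionally strided) sub-trajectory ``[start, end)``.

    Original ``time_index`` values are preserved.  Used to take the tail
    window of a production run, and — with ``stride`` — to thin long
    wildtype simulations to evenly spaced snapshots.
    """
    n = traj.n_frames
    if not (0 <= start_index < end_index <= n):
        raise ValidationError(
            f"invalid window [{start_index}, {end_index}) for {n} frames"
        )
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    frames = traj.frames[start_index:end_index:stride]
    if not frames:
        raise ValidationError("selected window is empty")
    return RSPTrajectory(
        variant_id=traj.variant_id,
        label=traj.label,
        frames=frames,
        residue_labels=list(traj.residue_labels),
    )


@dataclass
class LabelManifest:
    """Rows of (variant_id, label, path); paths relative to the manifest."""

    rows: pd.DataFrame  # columns: variant_id, label, path
    base_dir: Path

    def __post_init__(self) -> None:
        required = {"variant_id", "label", "path"}
        if not required.issubset(self.rows.columns):
            raise ValidationError(f"manifest needs columns {sorted(required)}")
        if self.rows["variant_id"].duplicated().any():
            dup = self.rows["variant_id"][self.rows["variant_id"].duplicated()]
            raise ValidationError(f"duplicate variant ids: {sorted(set(dup))}")
        bad = set(self.rows["label"]) - set(LABELS)
        if bad:
            raise ValidationError(f"unknown labels in manifest: {sorted(bad)}")

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p

    def load_trajectories(self, strict: bool = True) -> list[RSPTrajectory]:
        return [
            parse_rama_xvg(
                self.resolve(row.path),
                variant_id=row.variant_id,
                label=row.label,
                strict=strict,
            )
            for row in self.rows.itertuples()
        ]


def read_manifest(path) -> LabelManifest:
    """Read a CSV/TSV manifest with header ``variant_id,label,path``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = pd.read_csv(path, sep=sep, dtype=str)
    return LabelManifest(rows=rows, base_dir=path.parent)
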