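"""Inter-domain interface scanning: rigid pose generation, contact
specificity ranking, and the flat-bottom closure restraint.

To decide where a mobile domain docks onto a target, candidate orientations
are generated by sliding the mobile selection to evenly spaced positions
along the target's principal axis and rotating it about that axis at evenly
spaced angles (defaults 3 positions x 8 angles = 24 poses).  Per-pose
contact maps are then ranked for *specificity*: a residue pair whose
contacts concentrate in a single pose pinpoints a geometric binding site,
whereas promiscuous pairs contact in every pose.

The flat-bottom restraint used to hold a candidate contact closed is zero
between its walls and harmonic (½k·Δd²) outside, so it never biases the
interior distance range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from confshift.errors import InputError
from confshift.model_io import MolecularModel


@dataclass(frozen=True)
class Pose:
    """One rigid transform: ``x -> rotation @ x + translation`` (nm)."""

    rotation: np.ndarray
    translation: np.ndarray
    axial_index: int
    angle_index: int
    angle_deg: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class PoseSet:
    poses: tuple[Pose, ...]
    axial_positions: int
    angles: int

    def __post_init__(self) -> None:
        if len(self.poses) != self.axial_positions * self.angles:
            raise InputError("pose count must equal axial_positions x angles")

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


@dataclass(frozen=True)
class FlatBottomRestraint:
    """Zero between the walls, harmonic outside; k in kJ/mol/nm²."""

    force_constant: float = 1000.0
    lower_wall: float = 0.15
    upper_wall: float = 0.40

    def __post_init__(self) -> None:
        if self.lower_wall >= self.upper_wall:
            raise InputError("lower_wall must be below upper_wall")
        if self.force_constant <= 0:
            raise InputError("force constant must be positive")


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit vector along the largest-variance direction of a selection —
    the working definition of a domain's main axis."""
    coords = np.asarray(coords, dtype=float)
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    # orient deterministically: positive projection on the largest component
    lead = np.argmax(np.abs(axis))
    return axis * np.sign(axis[lead])


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(axis * angle).as_matrix()


def generate_orientations(
    mobile: MolecularModel | np.ndarray,
    target_axis: np.ndarray,
    anchor_point: np.ndarray,
    n_axial: int = 3,
    n_angles: int = 8,
    axial_span: float = 1.0,
) -> PoseSet:
    """Rigid pose grid: ``n_axial`` anchor points evenly spaced along the
    target axis x ``n_angles`` rotations evenly spaced in [0°, 360°).

    Angle 0 at each axial position reproduces the input orientation,
    translated so the mobile centroid sits at that position; every pose
    preserves the mobile's internal geometry exactly.
    """
    if n_axial < 1 or n_angles < 1:
        raise InputError("n_axial and n_angles must be >= 1")
    axis = np.asarray(target_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise InputError("target axis must be a non-zero vector")
    axis = axis / norm
    anchor = np.asarray(anchor_point, dtype=float)
    coords = mobile.coords if isinstance(mobile, MolecularModel) else np.asarray(mobile)
    centroid = coords.mean(axis=0)

    offsets = (
        np.zeros(1) if n_axial == 1 else np.linspace(0.0, axial_span, n_axial)
    )
    angles = np.arange(n_angles) * (2.0 * np.pi / n_angles)
    poses = []
    for ai, off in enumerate(offsets):
        position = anchor + off * axis
        for gi, angle in enumerate(angles):
            rot = _rotation_about_axis(axis, angle)
            # rotate about the pose position, then place centroid there
            translation = position - rot @ centroid
            poses.append(
                Pose(rot, translation, ai, gi, float(np.degrees(angle)))
            )
    return PoseSet(tuple(poses), n_axial, n_angles)


def rank_contact_specificity(
    contact_maps: Sequence[Mapping[tuple[int, int], float] | pd.DataFrame],
) -> pd.DataFrame:
    """Rank residue pairs by how concentrated their contacts are in one pose.

    ``specificity = max-pose frequency / total frequency`` (1.0 = seen in a
    single pose only); ranking is by specificity, then total frequency.
    Accepts per-pose dicts keyed by (residue_a, residue_b) or DataFrames
    shaped like :func:`confshift.dynamics.contact_probability`'s map.
    """
    if not contact_maps:
        raise InputError("at least one pose contact map is required")
    per_pose: list[dict[tuple[int, int], float]] = []
    for m in contact_maps:
        if isinstance(m, pd.DataFrame):
            d = {
                (int(r.residue_a), int(r.residue_b)): float(r.frequency)
                for r in m.itertuples()
            }
        else:
            d = {tuple(k): float(v) for k, v in m.items()}
        per_pose.append(d)
    pairs = sorted(set().union(*per_pose))
    rows = []
    for pair in pairs:
        freqs = np.array([d.get(pair, 0.0) for d in per_pose])
        total = float(freqs.sum())
        if total <= 0:
            continue
        best = int(freqs.argmax())
        rows.append(
            {
                "residue_a": pair[0],
                "residue_b": pair[1],
                "total_frequency": total,
                "best_pose": best,
                "specificity": float(freqs.max() / total),
            }
        )
    if not rows:
        import warnings

        warnings.warn("all contact maps are empty; nothing to rank",
                      stacklevel=2)
        return pd.DataFrame(
            columns=["residue_a", "residue_b", "total_frequency",
                     "best_pose", "specificity"]
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["specificity", "total_frequency"], ascending=[False, False]
    ).reset_index(drop=True)


def flat_bottom_energy(
    distance: float, restraint: FlatBottomRestraint = FlatBottomRestraint()
) -> tuple[float, float]:
    """Energy (kJ/mol) and force magnitude (kJ/mol/nm) of the restraint.

    E = ½k(d−upper)² beyond the upper wall, ½k(lower−d)² below the lower
    wall, zero in between; the force −dE/dd is continuous (zero) at both
    walls.  The ½k convention is recorded here so users of the k·Δd²
    convention can simply double the force constant.
    """
    if distance < 0:
        raise InputError("distance cannot be negative")
    k, lo, hi = restraint.force_constant, restraint.lower_wall, restraint.upper_wall
    if distance > hi:
        delta = distance - hi
        return 0.5 * k * delta**2, -k * delta
    if distance < lo:
        delta = lo - distance
        return 0.5 * k * delta**2, k * delta
    return 0.0, 0.0
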