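"""Synthetic coarse-grained trajectories with planted ground truth.

The generator emulates the statistical shape of the study system — a
multi-domain chain that dwells in a small number of anchor conformations
(circular "O", fishhook "J", extended, sigmoidal) and transitions between
them — without any physics: dwell frames are an anchor plus isotropic
Gaussian noise, transition frames interpolate linearly between flanking
anchors, and every frame carries a ground-truth label.  On top of that,
two effects can be planted with known magnitude so downstream analyses
have an answer key:

* an exposure change: a "shield" region rigidly displaced away from a
  "target" region from a chosen frame onwards (the analogue of one domain
  unblocking another's surface), and
* correlated motion: a shared scalar drive added to a residue pair with
  chosen sign, which a cross-correlation analysis must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from confshift.errors import ConfigError, InputError
from confshift.model_io import MolecularModel, RegionSet, Trajectory

DEFAULT_BOND_NM = 0.38  # consecutive Cα-Cα distance

SHAPE_NAMES = ("ring", "hook", "extended", "scurve")


@dataclass(frozen=True)
class AnchorConformation:
    """One labelled anchor shape; coordinates (n_beads, 3) in nm."""

    label: str
    coordinates: np.ndarray

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class TransitionSchedule:
    """Ordered (anchor label, dwell frames, interpolation frames) segments.

    The interpolation length of a segment is the number of blended frames
    inserted *after* its dwell, leading into the next segment's anchor; the
    last segment's interpolation length is ignored.
    """

    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for label, dwell, interp in self.segments:
            if dwell < 0 or interp < 0:
                raise ConfigError(f"segment {label!r}: negative length")
        if self.total_frames() < 2:
            raise ConfigError("schedule must produce at least 2 frames")

    def total_frames(self) -> int:
        total = 0
        for i, (_, dwell, interp) in enumerate(self.segments):
            total += dwell
            if i < len(self.segments) - 1:
                total += interp
        return total


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to generate one reproducible trajectory."""

    n_beads: int
    schedule: TransitionSchedule
    seed: int
    bead_radius: float = 0.30
    noise_sigma: float = 0.02
    bond_length: float = DEFAULT_BOND_NM
    shield_region: str | None = None
    target_region: str | None = None
    correlated_pairs: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.n_beads < 4:
            raise ConfigError("n_beads must be >= 4")


def _ring(n: int, bond: float) -> np.ndarray:
    # chord between consecutive beads on a circle of radius R equals bond
    radius = bond / (2.0 * np.sin(np.pi / n))
    angles = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)]
    )


def _extended(n: int, bond: float) -> np.ndarray:
    return np.column_stack(
        [bond * np.arange(n), np.zeros(n), np.zeros(n)]
    )


def _turning_walk(turn_angles: np.ndarray, bond: float) -> np.ndarray:
    """Planar chain walk with exact bond spacing: step k leaves at heading
    ``cumsum(turn_angles)[k]``; n beads need n-1 turn entries."""
    headings = np.concatenate([[0.0], np.cumsum(turn_angles)])[:-1]
    steps = bond * np.column_stack(
        [np.cos(headings), np.sin(headings), np.zeros(len(headings))]
    )
    coords = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return coords


def _hook(n: int, bond: float) -> np.ndarray:
    """J-shape: a straight stem flowing into a half-turn hook."""
    n_stem = max(2, int(round(n * 0.6)))
    n_arc = n - n_stem
    turns = np.zeros(n - 1)
    if n_arc > 0:
        turns[n_stem - 1 :] = np.pi / max(1, n_arc)  # half-turn over the hook
    return _turning_walk(turns, bond)


def _scurve(n: int, bond: float) -> np.ndarray:
    """Sigmoid: two opposite half-turns of equal length."""
    half = (n - 1) // 2
    turns = np.empty(n - 1)
    turns[:half] = np.pi / max(1, half)
    turns[half:] = -np.pi / max(1, n - 1 - half)
    return _turning_walk(turns, bond)


def make_anchor(
    shape_name: str, n_beads: int, bond_length: float = DEFAULT_BOND_NM,
    label: str | None = None,
) -> AnchorConformation:
    """Build a named anchor shape with exact consecutive-bead spacing.

    ``ring`` closes the chain (first-to-last distance ≈ bond length),
    ``hook`` is a J-like stem-plus-half-turn, ``extended`` is collinear,
    ``scurve`` is a sigmoid of two opposite turns.
    """
    if n_beads < 4:
        raise InputError("n_beads must be >= 4")
    builders = {
        "ring": _ring, "hook": _hook, "extended": _extended, "scurve": _scurve,
    }
    if shape_name not in builders:
        raise ConfigError(
            f"unknown shape {shape_name!r}; expected one of {SHAPE_NAMES}"
        )
    coords = builders[shape_name](n_beads, bond_length)
    return AnchorConformation(label or shape_name, coords)


def bead_topology(
    n_beads: int, bead_radius: float = 0.30, chain_id: str = "A"
) -> MolecularModel:
    """One-bead-per-residue topology (alanine beads, Cα naming)."""
    return MolecularModel(
        coords=np.zeros((n_beads, 3)),
        elements=["C"] * n_beads,
        residue_numbers=np.arange(1, n_beads + 1),
        residue_names=["ALA"] * n_beads,
        chain_ids=[chain_id] * n_beads,
        atom_names=["CA"] * n_beads,
        radii=[bead_radius] * n_beads,
    )


def generate_trajectory(
    spec: SyntheticSpec, anchors: dict[str, AnchorConformation] | list[AnchorConformation]
) -> tuple[Trajectory, list[str]]:
    """Generate a trajectory from a transition schedule plus ground truth.

    Dwell frames are the segment's anchor plus isotropic Gaussian noise of
    ``spec.noise_sigma``; interpolation frames blend linearly between the
    flanking anchors (plus the same noise) and are labelled
    ``transition:<from>-<to>``.  The same (spec, seed) always produces a
    bit-identical trajectory.
    """
    if not isinstance(anchors, dict):
        anchors = {a.label: a for a in anchors}
    for label, *_ in spec.schedule.segments:
        if label not in anchors:
            raise ConfigError(f"schedule references unknown anchor {label!r}")
    counts = {a.n_beads for a in anchors.values()}
    if counts != {spec.n_beads}:
        raise ConfigError(
            f"anchors have bead counts {sorted(counts)}, spec wants {spec.n_beads}"
        )
    rng = np.random.default_rng(spec.seed)
    frames: list[np.ndarray] = []
    labels: list[str] = []
    segs = spec.schedule.segments
    for i, (label, dwell, interp) in enumerate(segs):
        base = anchors[label].coordinates
        for _ in range(dwell):
            frames.append(base + rng.normal(0.0, spec.noise_sigma, base.shape))
            labels.append(label)
        if i < len(segs) - 1 and interp > 0:
            nxt = anchors[segs[i + 1][0]].coordinates
            for t in range(1, interp + 1):
                alpha = t / (interp + 1)
                blend = (1 - alpha) * base + alpha * nxt
                frames.append(blend + rng.normal(0.0, spec.noise_sigma, base.shape))
                labels.append(f"transition:{label}-{segs[i + 1][0]}")
    topology = bead_topology(spec.n_beads, spec.bead_radius)
    traj = Trajectory(topology, np.stack(frames))
    return traj, labels


def plant_exposure_change(
    traj: Trajectory,
    regions: RegionSet,
    shield: str,
    target: str,
    displacement: float,
    switch_frame: int,
) -> Trajectory:
    """Rigidly displace the shield region away from the target's centroid
    from ``switch_frame`` onwards; target coordinates are untouched.

    The direction is fixed at the switch frame (shield centroid minus
    target centroid, normalised), so the planted exposure change has a
    single known magnitude.
    """
    ids = regions.atom_indices(traj.topology, shield)
    idt = regions.atom_indices(traj.topology, target)
    if np.intersect1d(ids, idt).size:
        raise ConfigError("shield and target regions overlap")
    if not (0 <= switch_frame < traj.n_frames):
        raise InputError(
            f"switch_frame {switch_frame} outside 0..{traj.n_frames - 1}"
        )
    coords = traj.coords.copy()
    if displacement != 0.0:
        shield_c = coords[switch_frame, ids].mean(axis=0)
        target_c = coords[switch_frame, idt].mean(axis=0)
        direction = shield_c - target_c
        norm = np.linalg.norm(direction)
        direction = (direction / norm) if norm > 0 else np.array([1.0, 0.0, 0.0])
        coords[switch_frame:, ids, :] += displacement * direction
    return traj.with_coords(coords)


def plant_correlated_motion(
    traj: Trajectory,
    pairs: list[tuple[int, int, int]],
    amplitude: float,
    seed: int,
) -> Trajectory:
    """Add a shared zero-mean scalar drive to residue pairs.

    Each pair (i, j, sign) receives s(t)·u on bead i and sign·s(t)·u on
    bead j, where s(t) ~ N(0, amplitude²) is drawn per frame and u is a
    fixed random unit direction — strong positive or negative DCCM signal
    at amplitudes well above the background noise.  Residues are 1-based.
    """
    if amplitude <= 0:
        raise InputError("amplitude must be positive")
    rng = np.random.default_rng(seed)
    coords = traj.coords.copy()
    res = traj.topology.residue_numbers
    for i, j, sign in pairs:
        if i == j:
            raise ConfigError("correlated pair must involve two residues")
        if sign not in (-1, 1):
            raise ConfigError("sign must be +1 or -1")
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        s = rng.normal(0.0, amplitude, traj.n_frames)
        s -= s.mean()
        ii = np.nonzero(res == i)[0]
        jj = np.nonzero(res == j)[0]
        if ii.size == 0 or jj.size == 0:
            raise ConfigError(f"pair ({i}, {j}) not present in topology")
        coords[:, ii, :] += s[:, None, None] * u
        coords[:, jj, :] += sign * s[:, None, None] * u
    return traj.with_coords(coords)
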