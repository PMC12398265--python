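"""Hausdorff path-similarity between whole trajectories.

Two trajectories are compared as unordered sets of conformations under the
superposed-RMSD metric.  The directed Hausdorff value

    δ_H(P|Q) = max_{p ∈ P} min_{q ∈ Q} rmsd(p, q)

is the RMSD between a frame of P and its least-similar nearest neighbour in
Q; the symmetric value max(δ_H(P|Q), δ_H(Q|P)) is a pseudometric on
trajectories and is the default.  Higher values mean increasingly
dissimilar paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from confshift.errors import InputError
from confshift.model_io import Trajectory
from confshift.superposition import _rmsd_grid, _selection_indices


@dataclass(frozen=True)
class PathDistanceMatrix:
    """All-vs-all path distances (nm) between named trajectories."""

    labels: tuple[str, ...]
    values: np.ndarray
    method: str  # "hausdorff-symmetric" | "hausdorff-directed"
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.labels), len(self.labels)):
            raise InputError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InputError("path distance matrix must have a zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def group_means(self) -> dict[str, float]:
        """Mean off-diagonal distance within each named group — the common
        scale on which two sets of repeats are compared."""
        out: dict[str, float] = {}
        for group, members in self.groups.items():
            idx = [self.labels.index(m) for m in members]
            if len(idx) < 2:
                out[group] = 0.0
                continue
            sub = self.values[np.ix_(idx, idx)]
            off = sub[~np.eye(len(idx), dtype=bool)]
            out[group] = float(off.mean())
        return out


def _frame_stack(traj: Trajectory, selection) -> np.ndarray:
    idx = _selection_indices(traj, selection)
    return traj.coords[:, idx, :]


def directed_hausdorff(P: Trajectory, Q: Trajectory, selection=None) -> float:
    """δ_H(P|Q): worst-case nearest-neighbour superposed RMSD, in nm."""
    fp = _frame_stack(P, selection)
    fq = _frame_stack(Q, selection)
    if fp.shape[0] == 0 or fq.shape[0] == 0:
        raise InputError("both trajectories must be non-empty")
    if fp.shape[1] != fq.shape[1]:
        raise InputError(
            f"selection atom counts differ: {fp.shape[1]} vs {fq.shape[1]}"
        )
    grid = _rmsd_grid(fp, fq)
    return float(grid.min(axis=1).max())


def hausdorff(P: Trajectory, Q: Trajectory, selection=None) -> float:
    """Symmetric Hausdorff path distance max(δ_H(P|Q), δ_H(Q|P)), nm."""
    fp = _frame_stack(P, selection)
    fq = _frame_stack(Q, selection)
    if fp.shape[0] == 0 or fq.shape[0] == 0:
        raise InputError("both trajectories must be non-empty")
    if fp.shape[1] != fq.shape[1]:
        raise InputError(
            f"selection atom counts differ: {fp.shape[1]} vs {fq.shape[1]}"
        )
    grid = _rmsd_grid(fp, fq)
    return float(max(grid.min(axis=1).max(), grid.min(axis=0).max()))


def psa_matrix(
    trajectories: dict[str, Trajectory],
    selection=None,
    groups: dict[str, list[str]] | None = None,
    method: str = "hausdorff-symmetric",
) -> PathDistanceMatrix:
    """All-vs-all path-similarity matrix across named repeats.

    ``groups`` maps a group label (e.g. condition name) to member
    trajectory names; per-group mean off-diagonal values are then available
    through :meth:`PathDistanceMatrix.group_means` so two conditions can be
    compared on a common scale.
    """
    labels = list(trajectories)
    if len(labels) != len(set(labels)):
        raise InputError("duplicate trajectory names")
    if len(labels) < 2:
        raise InputError("need at least 2 trajectories")
    if method not in ("hausdorff-symmetric", "hausdorff-directed"):
        raise InputError(f"unknown method {method!r}")
    fn = hausdorff if method == "hausdorff-symmetric" else directed_hausdorff
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if method == "hausdorff-symmetric" and j < i:
                values[i, j] = values[j, i]
                continue
            values[i, j] = fn(trajectories[labels[i]], trajectories[labels[j]],
                              selection)
    group_map = {}
    if groups:
        for gname, members in groups.items():
            missing = [m for m in members if m not in trajectories]
            if missing:
                raise InputError(f"group {gname!r} names unknown trajectories "
                                 f"{missing}")
            group_map[gname] = tuple(members)
    return PathDistanceMatrix(tuple(labels), values, method, group_map)
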