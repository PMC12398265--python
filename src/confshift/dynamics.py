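"""Flexibility and correlated-motion measures.

* windowed RMSF: the trajectory is split into fixed-length fragments; each
  fragment is superposed to its own mean before the per-residue
  fluctuation is taken, so the number measures local flexibility rather
  than drift.  Percent differences of later windows against the first
  window expose gradual stabilisation (negative) or loosening (positive).
* DCCM: the normalised covariance C_ij = <Δr_i·Δr_j> /
  sqrt(<|Δr_i|²><|Δr_j|²>) of residue displacements about the superposed
  mean, using the isotropic scalar-product convention; values in [-1, 1].
* inter-region distances (centroid or minimum-atom) and contact
  probabilities (any atom pair strictly below the cutoff, default 0.24 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from confshift.errors import InputError
from confshift.model_io import RegionSet, Trajectory
from confshift.superposition import _selection_indices, kabsch_superpose

DEFAULT_CONTACT_CUTOFF_NM = 0.24


@dataclass(frozen=True)
class RmsfWindows:
    """Per-window, per-residue RMSF (nm) plus trends vs the first window."""

    window_length: int
    values: pd.DataFrame  # rows: window index (0-based), cols: residue numbers

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def percent_difference(self) -> pd.DataFrame:
        """Percent RMSF difference of every later window vs window 0;
        negative values mean the residue stabilised."""
        base = self.values.iloc[0]
        later = self.values.iloc[1:]
        return (later - base) / base * 100.0


@dataclass(frozen=True)
class Dccm:
    """Residue-residue correlation matrix; NaN rows mark immobile residues."""

    values: pd.DataFrame  # square, index/columns: residue numbers

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        finite = np.isfinite(v)
        if np.any(np.abs(v[finite]) > 1.0 + 1e-9):
            raise InputError("correlations must lie in [-1, 1]")


def _align_stack_to_mean(frames: np.ndarray, passes: int = 2) -> np.ndarray:
    aligned = frames.copy()
    reference = aligned[0]
    for _ in range(passes + 1):
        for i in range(aligned.shape[0]):
            aligned[i] = kabsch_superpose(aligned[i], reference).transformed
        reference = aligned.mean(axis=0)
    return aligned


def _residue_numbers_for(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    return traj.topology.residue_numbers[idx]


def windowed_rmsf(
    traj: Trajectory, window: int, selection=None
) -> RmsfWindows:
    """RMSF of each residue within consecutive ``window``-frame fragments.

    A trailing partial fragment is dropped; with 150 frames and 25-frame
    windows this yields six fragments.
    """
    if window < 2:
        raise InputError("window must span at least 2 frames")
    if window > traj.n_frames:
        raise InputError("window exceeds trajectory length")
    idx = _selection_indices(traj, selection)
    res_ids = _residue_numbers_for(traj, idx)
    n_windows = traj.n_frames // window
    rows = []
    for w in range(n_windows):
        frames = traj.coords[w * window : (w + 1) * window, idx, :]
        aligned = _align_stack_to_mean(frames)
        mean = aligned.mean(axis=0)
        dev = aligned - mean
        per_atom = np.sqrt(np.mean(np.einsum("fij,fij->fi", dev, dev), axis=0))
        rows.append(pd.Series(per_atom).groupby(res_ids).mean())
    return RmsfWindows(window_length=window,
                       values=pd.DataFrame(rows).reset_index(drop=True))


def dccm(traj: Trajectory, selection=None) -> Dccm:
    """Dynamic cross-correlation matrix of per-residue displacements.

    Residues with more than one atom are reduced to their centroid before
    the correlation is taken.  Zero-variance residues yield NaN rows and
    columns (undefined, not uncorrelated).
    """
    if traj.n_frames < 2:
        raise InputError("need at least 2 frames")
    idx = _selection_indices(traj, selection)
    res_ids = _residue_numbers_for(traj, idx)
    aligned = _align_stack_to_mean(traj.coords[:, idx, :])
    unique_res = np.unique(res_ids)
    pos = np.stack(
        [aligned[:, res_ids == r, :].mean(axis=1) for r in unique_res], axis=1
    )  # (F, R, 3)
    dev = pos - pos.mean(axis=0)
    cov = np.einsum("fia,fja->ij", dev, dev) / dev.shape[0]
    var = np.diag(cov).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        corr = np.where(denom > 0, cov / denom, np.nan)
    corr = np.clip(corr, -1.0, 1.0, out=corr, where=np.isfinite(corr))
    frame = pd.DataFrame(corr, index=unique_res, columns=unique_res)
    return Dccm(frame)


def _region_atoms(traj: Trajectory, regions: RegionSet, name: str) -> np.ndarray:
    return regions.atom_indices(traj.topology, name)


def region_distance_series(
    traj: Trajectory,
    regions: RegionSet,
    region_a: str,
    region_b: str,
    mode: str = "centroid",
) -> np.ndarray:
    """Per-frame distance (nm) between two disjoint regions.

    ``centroid`` measures between unweighted region centroids; ``min_atom``
    takes the closest atom pair (always <= the centroid distance).
    """
    ia = _region_atoms(traj, regions, region_a)
    ib = _region_atoms(traj, regions, region_b)
    if np.intersect1d(ia, ib).size:
        raise InputError(f"regions {region_a!r} and {region_b!r} overlap")
    if mode == "centroid":
        ca = traj.coords[:, ia, :].mean(axis=1)
        cb = traj.coords[:, ib, :].mean(axis=1)
        return np.linalg.norm(ca - cb, axis=1)
    if mode == "min_atom":
        a = traj.coords[:, ia, :]
        b = traj.coords[:, ib, :]
        d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=3)
        return d.reshape(traj.n_frames, -1).min(axis=1)
    raise InputError(f"unknown mode {mode!r}")


def contact_probability(
    traj: Trajectory,
    regions: RegionSet,
    region_a: str,
    region_b: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
) -> tuple[float, pd.DataFrame]:
    """Fraction of frames with any inter-region atom pair strictly below
    ``cutoff`` (nm), plus a residue-pair contact-frequency map.

    A frame counts once toward the probability no matter how many pairs
    touch; the map preserves per-pair multiplicity (fraction of frames in
    which that residue pair is in contact).
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    ia = _region_atoms(traj, regions, region_a)
    ib = _region_atoms(traj, regions, region_b)
    if ia.size == 0 or ib.size == 0:
        raise InputError("regions must be non-empty")
    res_a = traj.topology.residue_numbers[ia]
    res_b = traj.topology.residue_numbers[ib]
    a = traj.coords[:, ia, :]
    b = traj.coords[:, ib, :]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=3)
    touching = d < cutoff  # (F, |A|, |B|)
    frame_fraction = float(touching.any(axis=(1, 2)).mean())
    records = []
    for ra in np.unique(res_a):
        for rb in np.unique(res_b):
            block = touching[:, res_a == ra][:, :, res_b == rb]
            freq = float(block.any(axis=(1, 2)).mean())
            if freq > 0:
                records.append(
                    {"residue_a": int(ra), "residue_b": int(rb), "frequency": freq}
                )
    pair_map = pd.DataFrame(records, columns=["residue_a", "residue_b", "frequency"])
    return frame_fraction, pair_map
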