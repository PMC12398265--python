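"""Rigid-body superposition, RMSD matrices and radius of gyration.

This is the metric layer the path-similarity, landscape and fluctuation
modules build on.  Superposition is the classical Kabsch solution: the
rotation comes from the SVD of the weighted cross-covariance of the two
centred coordinate sets, with the reflection branch removed by flipping the
smallest singular vector whenever the determinant of V·Uᵀ is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from confshift.errors import DegenerateGeometryError, InputError
from confshift.model_io import Trajectory

_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference.

    ``transformed = mobile @ rotation.T + translation``; rmsd in nm.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    transformed: np.ndarray

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise InputError("rmsd cannot be negative")


def _as_coords(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise InputError("expected coordinates of shape (n, 3)")
    return x


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference
        Coordinate sets of equal shape (n, 3), n >= 3, in nm.
    weights
        Optional non-negative per-atom weights (e.g. masses).

    Raises
    ------
    InputError
        On count mismatch, fewer than 3 points, or invalid weights.
    DegenerateGeometryError
        When the points are (near-)collinear, leaving the rotation
        under-determined.
    """
    mobile = _as_coords(mobile)
    reference = _as_coords(reference)
    if mobile.shape != reference.shape:
        raise InputError(
            f"atom count mismatch: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise InputError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise InputError("weights must be one value per atom")
        if np.any(w < 0) or w.sum() <= 0:
            raise InputError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mob_center = w @ mobile
    ref_center = w @ reference
    p = mobile - mob_center
    q = reference - ref_center

    h = (p * w[:, None]).T @ q  # 3x3 cross-covariance
    u, s, vt = np.linalg.svd(h)
    # collinear (or single-point) configurations leave >=2 singular values ~0
    if s[0] > 0 and s[1] <= _DEGENERACY_RTOL * s[0] and not np.allclose(p, 0.0) \
            and not np.allclose(q, 0.0):
        raise DegenerateGeometryError(
            "point sets are collinear; rotation is under-determined"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = ref_center - rotation @ mob_center
    transformed = mobile @ rotation.T + translation
    diff = transformed - reference
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return SuperpositionResult(rotation, translation, rmsd, transformed)


def superposed_rmsd(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Minimum RMSD between two conformations after optimal superposition."""
    return kabsch_superpose(mobile, reference, weights).rmsd


def _rmsd_grid(frames_p: np.ndarray, frames_q: np.ndarray) -> np.ndarray:
    """All-pairs superposed RMSD between two frame stacks, batched.

    Uses the singular values of every pairwise cross-covariance:
    rmsd²(p,q) = (tr Pc·Pcᵀ + tr Qc·Qcᵀ − 2·Σᵢ σᵢ) / n with the smallest
    singular value sign-flipped for reflection pairs.
    """
    n = frames_p.shape[1]
    pc = frames_p - frames_p.mean(axis=1, keepdims=True)
    qc = frames_q - frames_q.mean(axis=1, keepdims=True)
    ssp = np.einsum("fij,fij->f", pc, pc)
    ssq = np.einsum("fij,fij->f", qc, qc)
    # (F_p, F_q, 3, 3) cross-covariances
    h = np.einsum("pia,qib->pqab", pc, qc)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("pqab,pqbc->pqac", np.swapaxes(vt, -1, -2),
                                  np.swapaxes(u, -1, -2)))
    s_sum = s[..., 0] + s[..., 1] + np.where(det < 0, -s[..., 2], s[..., 2])
    msd = (ssp[:, None] + ssq[None, :] - 2.0 * s_sum) / n
    return np.sqrt(np.clip(msd, 0.0, None))


def _selection_indices(traj: Trajectory, selection) -> np.ndarray:
    """Resolve a selection (None/'all', 'ca', region name unsupported here,
    an iterable of residue numbers, or explicit atom indices) to indices."""
    if selection is None or (isinstance(selection, str) and selection == "all"):
        return np.arange(traj.n_atoms)
    if isinstance(selection, str) and selection.lower() in ("ca", "calpha"):
        return traj.topology.ca_indices()
    sel = np.asarray(list(selection), dtype=int)
    if sel.size == 0:
        raise InputError("empty selection")
    if sel.max(initial=-1) >= traj.n_atoms or sel.min(initial=0) < 0:
        raise InputError("selection indices out of range")
    return sel


def pairwise_rmsd_matrix(traj: Trajectory, selection=None) -> np.ndarray:
    """Symmetric frame-vs-frame superposed RMSD matrix (nm).

    Entry (i, j) is the RMSD after superposing frame j onto frame i; the
    diagonal is zero by construction.
    """
    if traj.n_frames < 2:
        raise InputError("need at least 2 frames for a pairwise matrix")
    idx = _selection_indices(traj, selection)
    frames = traj.coords[:, idx, :]
    mat = _rmsd_grid(frames, frames)
    mat = 0.5 * (mat + mat.T)  # numerical symmetrization
    np.fill_diagonal(mat, 0.0)
    return mat


def radius_of_gyration(
    frame: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """Mass-weighted RMS distance from the centre of mass, in nm."""
    frame = _as_coords(np.atleast_2d(np.asarray(frame, dtype=float)))
    n = frame.shape[0]
    if masses is None:
        m = np.full(n, 1.0)
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape != (n,):
            raise InputError("masses must be one value per atom")
        if np.any(m <= 0):
            raise InputError("masses must be positive")
    m = m / m.sum()
    com = m @ frame
    d2 = np.einsum("ij,ij->i", frame - com, frame - com)
    return float(np.sqrt(m @ d2))


def rg_series(
    traj: Trajectory, masses: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Per-frame radius of gyration plus a plateau diagnostic.

    Returns ``(series, slope)`` where slope is the least-squares slope (nm
    per frame) of the final third of the series — near zero once the
    trajectory has settled into its final conformational state.
    """
    series = np.array(
        [radius_of_gyration(traj.coords[i], masses) for i in range(traj.n_frames)]
    )
    tail = series[-max(2, len(series) // 3):]
    if len(tail) < 2 or np.allclose(tail, tail[0]):
        slope = 0.0
    else:
        slope = float(np.polyfit(np.arange(len(tail)), tail, 1)[0])
    return series, slope
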