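"""Conformational landscape: coordinate PCA, state clustering, populations.

All repeats are combined into a single frame stack before the principal
components are computed, so every trajectory is projected onto one shared
basis — the composite weighting that best represents all motions in the
dataset.  Frames are superposed to an iteratively refined mean structure
before the covariance is formed.  Clustering into conformational states is
agglomerative with average linkage on Euclidean distance in the leading
principal components (defaults: 4 components, 5 states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import gaussian_kde

from confshift.errors import DegenerateGeometryError, InputError
from confshift.model_io import Trajectory
from confshift.superposition import _selection_indices, kabsch_superpose

_MEAN_REFINEMENT_PASSES = 2


@dataclass(frozen=True)
class LandscapeModel:
    """Shared PCA basis over 3N coordinate space plus per-frame projections.

    eigenvalues are in nm² and sorted descending; eigenvectors (3N, k) are
    orthonormal columns; projections (F, k) are coordinates of each centred,
    superposed frame in the basis; frame_index maps row -> (trajectory
    name, frame number within it).
    """

    mean_structure: np.ndarray  # (n_sel_atoms, 3), nm
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    projections: np.ndarray
    frame_index: tuple[tuple[str, int], ...]
    selection_indices: np.ndarray

    def variance_explained(self, m: int | None = None) -> float:
        total = float(self.eigenvalues.sum())
        if total <= 0:
            return 0.0
        if m is None:
            m = len(self.eigenvalues)
        return float(self.eigenvalues[:m].sum()) / total

    @property
    def n_frames(self) -> int:
        return self.projections.shape[0]

    def trajectory_rows(self, name: str) -> np.ndarray:
        rows = np.array([i for i, (t, _) in enumerate(self.frame_index) if t == name])
        if rows.size == 0:
            raise InputError(f"unknown trajectory {name!r}")
        return rows


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-frame conformational-state labels in 1..k."""

    labels: np.ndarray
    k: int
    linkage: str
    n_pc: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.min(initial=1) < 1 or lab.max(initial=1) > self.k:
            raise InputError("cluster labels must lie in 1..k")

    def members(self, cluster_id: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster_id)[0]


def _superpose_to_iterative_mean(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame to the mean, refining the mean a fixed number
    of passes.  Returns (aligned frames, mean)."""
    aligned = frames.copy()
    reference = aligned[0]
    for _ in range(_MEAN_REFINEMENT_PASSES + 1):
        for i in range(aligned.shape[0]):
            aligned[i] = kabsch_superpose(aligned[i], reference).transformed
        new_ref = aligned.mean(axis=0)
        if np.allclose(new_ref, reference, atol=1e-12):
            reference = new_ref
            break
        reference = new_ref
    return aligned, reference


def fit_landscape(
    trajectories: dict[str, Trajectory], selection=None
) -> LandscapeModel:
    """Combined-trajectory coordinate PCA over all frames of all repeats.

    The eigenproblem is solved on whichever side of the duality is smaller:
    the 3N×3N coordinate covariance when 3N <= F, otherwise the F×F Gram
    matrix of centred frames (identical spectra by construction).
    """
    if not trajectories:
        raise InputError("no trajectories given")
    names = list(trajectories)
    first = trajectories[names[0]]
    idx = _selection_indices(first, selection)
    stacks, frame_index = [], []
    for name in names:
        traj = trajectories[name]
        if traj.n_atoms != first.n_atoms:
            raise InputError("all trajectories must share one topology")
        stacks.append(traj.coords[:, idx, :])
        frame_index.extend((name, i) for i in range(traj.n_frames))
    frames = np.concatenate(stacks, axis=0)
    n_frames = frames.shape[0]
    if n_frames < 2:
        raise InputError("need at least 2 frames for PCA")

    aligned, mean = _superpose_to_iterative_mean(frames)
    x = (aligned - mean).reshape(n_frames, -1)  # (F, 3N)
    dim = x.shape[1]
    denom = n_frames - 1
    if dim <= n_frames:
        cov = (x.T @ x) / denom
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    else:
        gram = (x @ x.T) / denom
        evals, u = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1]
        evals, u = evals[order], u[:, order]
        keep = evals > max(evals.max(), 0.0) * 1e-12
        keep[: min(1, len(evals))] = True
        evals_k = evals[keep]
        evecs = x.T @ u[:, keep]
        norms = np.linalg.norm(evecs, axis=0)
        norms[norms == 0] = 1.0
        evecs /= norms
        evals = evals_k
    evals = np.clip(evals, 0.0, None)
    projections = x @ evecs
    return LandscapeModel(
        mean_structure=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        projections=projections,
        frame_index=tuple(frame_index),
        selection_indices=idx,
    )


def cluster_frames(
    model: LandscapeModel, n_pc: int = 4, k: int = 5, linkage_method: str = "average"
) -> ClusterAssignment:
    """Agglomerative clustering of frames in the leading PC coordinates.

    The dendrogram (Euclidean distance, given linkage) is cut to exactly
    ``k`` groups; labels are renumbered 1..k by order of first appearance
    so repeated runs on identical input are bit-identical.
    """
    n_pc = min(n_pc, model.eigenvectors.shape[1])
    if n_pc < 1:
        raise InputError("n_pc must be >= 1")
    if k > model.n_frames:
        raise InputError(f"k={k} exceeds frame count {model.n_frames}")
    if k < 1:
        raise InputError("k must be >= 1")
    coords = model.projections[:, :n_pc]
    if k == 1:
        labels = np.ones(model.n_frames, dtype=int)
    else:
        z = linkage(coords, method=linkage_method, metric="euclidean")
        raw = fcluster(z, t=k, criterion="maxclust")
        remap: dict[int, int] = {}
        labels = np.empty_like(raw)
        for i, r in enumerate(raw):
            if r not in remap:
                remap[r] = len(remap) + 1
            labels[i] = remap[r]
    return ClusterAssignment(labels=labels, k=int(labels.max()),
                             linkage=linkage_method, n_pc=n_pc)


def population_table(
    assignment: ClusterAssignment, group_of: dict[int, str] | list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster population percentages, normalised both ways.

    Returns ``(share_of_cluster_by_group, share_of_group_by_cluster)``:
    the first table's rows (clusters) sum to 100% across groups — which
    condition owns each conformational state; the second table's columns
    (groups) sum to 100% across clusters — how each condition distributes
    its frames over the states.
    """
    labels = assignment.labels
    if isinstance(group_of, dict):
        try:
            groups = [group_of[i] for i in range(len(labels))]
        except KeyError as exc:
            raise InputError(f"frame {exc} has no group") from exc
    else:
        groups = list(group_of)
        if len(groups) != len(labels):
            raise InputError("one group per frame required")
    df = pd.DataFrame({"cluster": labels, "group": groups})
    counts = pd.crosstab(df["cluster"], df["group"])
    by_group = counts.div(counts.sum(axis=1), axis=0) * 100.0
    within_group = counts.div(counts.sum(axis=0), axis=1) * 100.0
    return by_group, within_group


def local_density(
    model: LandscapeModel, n_pc: int = 2, bandwidth="auto"
) -> np.ndarray:
    """Gaussian KDE of the frame cloud in the leading PCs, evaluated at
    every frame and normalised to a maximum of 1."""
    if model.n_frames < 2:
        raise InputError("need at least 2 frames for a density estimate")
    pts = model.projections[:, : min(n_pc, model.projections.shape[1])].T
    spread = np.ptp(pts, axis=1)
    if np.any(spread <= 1e-10 * max(1.0, np.abs(pts).max())):
        raise DegenerateGeometryError("zero variance in the chosen components")
    bw = None if bandwidth == "auto" else float(bandwidth)
    try:
        kde = gaussian_kde(pts, bw_method=bw)  # None -> Scott's rule
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(
            f"frame cloud is degenerate in the chosen components: {exc}"
        ) from exc
    dens = kde(pts)
    return dens / dens.max()


def representative_frame(
    model: LandscapeModel, assignment: ClusterAssignment, cluster_id: int
) -> int:
    """The member frame closest to its cluster's centroid in PC space — the
    state's structural mid-point.  Ties break to the lowest frame index."""
    members = assignment.members(cluster_id)
    if members.size == 0:
        raise InputError(f"cluster {cluster_id} is empty")
    coords = model.projections[:, : assignment.n_pc]
    centroid = coords[members].mean(axis=0)
    d = np.linalg.norm(coords[members] - centroid, axis=1)
    return int(members[np.argmin(d)])


def _majority(window_labels: np.ndarray) -> int:
    return int(np.bincount(window_labels).argmax())


def convergence_analysis(
    model: LandscapeModel,
    n_pc: int = 4,
    k: int = 5,
    window: int = 10,
    seed: int = 0,
) -> dict[str, int]:
    """Per-trajectory convergence frame from K-means on the shared projections.

    K-means (k-means++ init, 10 restarts, fixed seed) labels every frame;
    for each trajectory the convergence frame is the earliest frame t0 such
    that every rolling ``window``-frame majority label from t0 onwards
    equals the final window's majority.  Early transitions to the terminal
    state give small convergence frames.
    """
    from sklearn.cluster import KMeans

    if window < 1:
        raise InputError("window must be >= 1")
    coords = model.projections[:, : min(n_pc, model.projections.shape[1])]
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    out: dict[str, int] = {}
    for name in dict.fromkeys(t for t, _ in model.frame_index):
        rows = model.trajectory_rows(name)
        lab = labels[rows]
        n = len(lab)
        if n < window:
            raise InputError(f"trajectory {name!r} shorter than window")
        majorities = np.array(
            [_majority(lab[t : t + window]) for t in range(n - window + 1)]
        )
        final = majorities[-1]
        t0 = len(majorities) - 1
        while t0 > 0 and majorities[t0 - 1] == final:
            t0 -= 1
        out[name] = int(t0)
    return out
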