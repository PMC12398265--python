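"""Solvent-accessible surface area and epitope-exposure delta tables.

SASA is computed with the Shrake–Rupley method: each atom's sphere of
radius (r_vdw + probe) is sampled with a deterministic golden-spiral point
set; a test point is accessible if it lies outside every neighbouring
atom's probe-expanded sphere, and the atom's area is the accessible
fraction of 4π(r+probe)².  Defaults follow the water-probe convention:
probe 0.14 nm, 960 sphere points.

The exposure analysis of a conformational transition is summarised as a
delta table: for every (group, conformational state, region) the mean
region SASA over member frames, its SEM, and the percent difference from a
reference state (the closed conformation), with SEMs propagated in
quadrature on the ratio.  A positive percent difference means the region
became more solvent-exposed in that state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from confshift.errors import InputError
from confshift.landscape import ClusterAssignment
from confshift.model_io import MolecularModel, RegionSet, Trajectory

DEFAULT_PROBE_NM = 0.14
DEFAULT_N_POINTS = 960

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = _GOLDEN_ANGLE * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_NM,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in nm²."""
    if probe_radius < 0:
        raise InputError("probe radius must be non-negative")
    if n_points < 24:
        raise InputError("n_points must be at least 24")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise InputError("all radii must be positive")
    n = coords.shape[0]
    expanded = radii + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.empty(n)
    for i in range(n):
        # neighbours that could shadow atom i's probe sphere
        neigh = tree.query_ball_point(coords[i], r=expanded[i] + expanded.max())
        neigh = [j for j in neigh if j != i
                 and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]]
        pts = coords[i] + expanded[i] * unit
        if neigh:
            d2 = np.sum(
                (pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2
            )
            buried = np.any(d2 < (expanded[neigh] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return areas


def residue_sasa(per_atom: np.ndarray, topology: MolecularModel) -> pd.Series:
    """Sum member-atom areas per residue (index: residue number)."""
    per_atom = np.asarray(per_atom, dtype=float)
    if per_atom.shape[0] != topology.n_atoms:
        raise InputError("per-atom SASA length must match topology")
    return pd.Series(per_atom).groupby(topology.residue_numbers).sum()


@dataclass(frozen=True)
class SasaSeries:
    """Per-frame, per-residue SASA over a trajectory, nm²."""

    values: pd.DataFrame  # rows: frames, columns: residue numbers
    probe_radius: float
    n_sphere_points: int

    def __post_init__(self) -> None:
        if (self.values.values < -1e-12).any():
            raise InputError("SASA values cannot be negative")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def residues(self) -> np.ndarray:
        return self.values.columns.to_numpy()


def sasa_series(
    traj: Trajectory,
    probe_radius: float = DEFAULT_PROBE_NM,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaSeries:
    """Per-residue SASA measured at every frame of a trajectory."""
    top = traj.topology
    rows = []
    for f in range(traj.n_frames):
        per_atom = shrake_rupley(traj.coords[f], top.radii, probe_radius, n_points)
        rows.append(residue_sasa(per_atom, top))
    frame = pd.DataFrame(rows).reset_index(drop=True)
    return SasaSeries(frame, probe_radius, n_points)


def region_series(sasa: SasaSeries, regions: RegionSet) -> pd.DataFrame:
    """Per-frame total SASA for each named region (columns: region names)."""
    out = {}
    available = set(int(r) for r in sasa.residues)
    for name in regions.names():
        wanted = sorted(regions.residues(name))
        missing = [r for r in wanted if r not in available]
        if missing:
            raise InputError(f"region {name!r}: residues {missing} absent "
                             "from SASA series")
        out[name] = sasa.values[wanted].sum(axis=1)
    return pd.DataFrame(out)


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def _block_sem(values: np.ndarray, block: int = 10) -> float:
    """SEM over block means — a coarse guard against the frame-to-frame
    autocorrelation of dynamics trajectories."""
    values = np.asarray(values, dtype=float)
    n_blocks = len(values) // block
    if n_blocks < 2:
        return _sem(values)
    means = values[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return _sem(means)


def _ratio_percent(mean: float, sem: float, ref_mean: float, ref_sem: float
                   ) -> tuple[float, float]:
    if ref_mean == 0:
        raise InputError("reference mean is zero; percent difference undefined")
    ratio = mean / ref_mean
    pct = 100.0 * (ratio - 1.0)
    rel = np.hypot(sem / mean if mean != 0 else 0.0, ref_sem / ref_mean)
    return pct, 100.0 * abs(ratio) * float(rel)


def delta_table(
    series: pd.DataFrame,
    assignment: ClusterAssignment,
    reference_cluster,
    group_of: list[str] | dict[int, str] | None = None,
    cluster_names: dict[int, str] | None = None,
    reference_group: str | None = None,
    block: int = 10,
) -> pd.DataFrame:
    """Per-region, per-state exposure statistics with percent differences.

    For every group g, state c and region r the table carries the mean and
    SEM of the per-frame region metric, the percent difference from the
    reference state within the same group, and — when ``reference_group``
    is given — the cross-group percent difference from the reference
    group's same state.  Both plain (frames independent) and
    block-averaged SEMs are emitted.
    """
    n = len(series)
    if n != len(assignment.labels):
        raise InputError("series and assignment cover different frame counts")
    if group_of is None:
        groups = ["all"] * n
    elif isinstance(group_of, dict):
        groups = [group_of[i] for i in range(n)]
    else:
        groups = list(group_of)
    cluster_names = cluster_names or {}

    def cname(c: int) -> str:
        return str(cluster_names.get(c, c))

    ref_label = None
    for c in range(1, assignment.k + 1):
        if cname(c) == str(reference_cluster) or c == reference_cluster:
            ref_label = c
            break
    if ref_label is None:
        raise InputError(f"reference cluster {reference_cluster!r} not found")

    df = series.copy()
    df["_cluster"] = assignment.labels
    df["_group"] = groups
    stats: dict[tuple[str, int, str], tuple[float, float, float, int]] = {}
    for (g, c), sub in df.groupby(["_group", "_cluster"], sort=True):
        for region in series.columns:
            vals = sub[region].to_numpy()
            stats[(g, c, region)] = (
                float(vals.mean()), _sem(vals), _block_sem(vals, block), len(vals)
            )
    for g in sorted(set(groups)):
        for region in series.columns:
            if (g, ref_label, region) not in stats:
                raise InputError(
                    f"reference cluster empty within group {g!r}"
                )

    rows = []
    for (g, c, region), (mean, sem, bsem, count) in sorted(stats.items()):
        ref_mean, ref_sem, _, _ = stats[(g, ref_label, region)]
        if c == ref_label:
            pct, pct_sem = 0.0, 0.0
        else:
            pct, pct_sem = _ratio_percent(mean, sem, ref_mean, ref_sem)
        row = {
            "region": region,
            "cluster": cname(c),
            "group": g,
            "n_frames": count,
            "mean": mean,
            "sem": sem,
            "block_sem": bsem,
            "pct_diff_vs_reference": pct,
            "pct_diff_sem": pct_sem,
            "is_reference": c == ref_label,
        }
        if reference_group is not None and g != reference_group:
            key = (reference_group, c, region)
            if key in stats:
                o_mean, o_sem, _, _ = stats[key]
                xp, xps = _ratio_percent(mean, sem, o_mean, o_sem)
                row["pct_diff_vs_reference_group"] = xp
                row["pct_diff_vs_reference_group_sem"] = xps
            else:
                row["pct_diff_vs_reference_group"] = np.nan
                row["pct_diff_vs_reference_group_sem"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def residue_profile(sasa: SasaSeries, baseline_frames) -> pd.Series:
    """Per-residue mean SASA difference from a baseline frame set, nm².

    Positive values mark residues that, averaged over the whole
    trajectory, are more exposed than they were in the baseline (e.g. the
    starting closed conformation).
    """
    baseline = np.asarray(list(baseline_frames), dtype=int)
    if baseline.size == 0:
        raise InputError("baseline frame set is empty")
    overall = sasa.values.mean(axis=0)
    base = sasa.values.iloc[baseline].mean(axis=0)
    return overall - base
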