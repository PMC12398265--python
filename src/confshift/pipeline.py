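"""End-to-end orchestration: synthetic or user trajectories through the
full analysis chain, with a run manifest for reproducibility.

The demo builds two synthetic conditions that mirror the biological
contrast of interest: a "wt-like" group that dwells long in the closed
ring state before opening (and alone reaches a second S-like end state),
and a "clipped-like" group that leaves the ring early and favours the
open hook state.  A shield segment hovers over a target region in every
anchor and is rigidly displaced at each repeat's opening transition —
further in the clipped-like group — so the exposure analysis has a planted
answer, as does the correlated-motion analysis.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from confshift import (
    RegionSet,
    Trajectory,
    cluster_frames,
    contact_probability,
    convergence_analysis,
    dccm,
    delta_table,
    directed_hausdorff,  # noqa: F401  (re-exported for scripting convenience)
    find_epitope_motifs,
    fit_landscape,
    generate_trajectory,
    load_regions,
    local_density,
    make_anchor,
    motif_report,
    pairwise_rmsd_matrix,
    plant_correlated_motion,
    plant_exposure_change,
    population_table,
    psa_matrix,
    region_distance_series,
    region_series,
    representative_frame,
    rg_series,
    sasa_series,
    windowed_rmsf,
    write_structure,
    write_table,
)
from confshift.errors import ConfigError
from confshift.model_io import read_trajectory
from confshift.synthetic_data import (
    AnchorConformation,
    SyntheticSpec,
    TransitionSchedule,
)

DEMO_DEFAULTS = dict(
    n_beads=60,
    bond_length=0.38,
    noise_sigma=0.03,
    n_repeats=5,
    shield_hover=0.55,
    displacement_wt=0.15,
    displacement_clipped=0.35,
    correlated_pair=(5, 35, -1),
    correlated_amplitude=0.25,
)

DEMO_REGIONS_YAML = """
target: 8-14
shield: 44-50
flank: 20-26
remote: 54-58
"""


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run."""

    trajectories: dict[str, Trajectory]
    groups: dict[str, str]  # trajectory name -> group label
    regions: RegionSet
    output_dir: Path
    sequence: str | None = None
    n_pc: int = 4
    k: int = 5
    rmsf_window: int = 50
    probe_radius: float = 0.14
    sasa_points: int = 960
    contact_cutoff: float = 0.24
    psa_stride: int = 3
    reference_cluster: int = 1
    reference_group: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.trajectories:
            raise ConfigError("at least one trajectory is required")
        missing = [n for n in self.trajectories if n not in self.groups]
        if missing:
            raise ConfigError(f"trajectories without a group: {missing}")
        if not set(self.groups.values()):
            raise ConfigError("at least one group is required")

    def parameter_record(self) -> dict:
        return {
            "n_pc": self.n_pc, "k": self.k, "rmsf_window": self.rmsf_window,
            "probe_radius": self.probe_radius, "sasa_points": self.sasa_points,
            "contact_cutoff": self.contact_cutoff, "psa_stride": self.psa_stride,
            "reference_cluster": self.reference_cluster,
            "reference_group": self.reference_group, "seed": self.seed,
            "groups": dict(self.groups),
            "regions": {n: [min(self.regions.residues(n)),
                            max(self.regions.residues(n))]
                        for n in self.regions.names()},
        }


@dataclass
class RunManifest:
    """What a run produced: parameters per stage and every emitted file."""

    version: str
    config_hash: str
    parameters: dict
    stages: dict[str, list[str]] = field(default_factory=dict)
    findings: dict = field(default_factory=dict)
    failed_stages: list[str] = field(default_factory=list)

    def record(self, stage: str, *paths: Path) -> None:
        self.stages.setdefault(stage, []).extend(str(p) for p in paths)

    def all_files(self) -> list[str]:
        return [f for files in self.stages.values() for f in files]

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def config_from_yaml(text: str, base_dir: Path | None = None) -> RunConfig:
    """Build a RunConfig from a YAML document naming trajectory files."""
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "trajectories" not in data:
        raise ConfigError("config must define a 'trajectories' mapping")
    base = base_dir or Path(".")
    trajectories, groups = {}, {}
    for name, entry in data["trajectories"].items():
        path = base / entry["path"]
        if not path.exists():
            raise ConfigError(f"trajectory file not found: {path}")
        trajectories[name] = read_trajectory(str(path))
        groups[name] = str(entry.get("group", "all"))
    regions = load_regions(yaml.safe_dump(data.get("regions", {})))
    params = data.get("parameters", {})
    return RunConfig(
        trajectories=trajectories,
        groups=groups,
        regions=regions,
        output_dir=Path(data.get("output_dir", "confshift_out")),
        sequence=data.get("sequence"),
        seed=int(data.get("seed", 0)),
        **{k: v for k, v in params.items() if k in RunConfig.__dataclass_fields__},
    )


def _hash_config(config: RunConfig) -> str:
    blob = json.dumps(config.parameter_record(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def bundled_sequence() -> str:
    """The domain I-II fragment sequence shipped for motif scanning."""
    text = (resources.files("confshift") / "data" / "b2gpi_di_dii.fasta").read_text()
    return "".join(l.strip() for l in text.splitlines() if not l.startswith(">"))


def run_pipeline(config: RunConfig, log=None) -> RunManifest:
    """Execute every stage in order, writing one subdirectory per stage.

    Required stages raise on failure; optional downstream stages are
    logged, skipped and flagged in the manifest instead.
    """
    import sys

    def note(msg: str) -> None:
        t = time.strftime("%H:%M:%S")
        print(f"[{t}] {msg}", file=log or sys.stderr)

    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version="0.1.0",
        config_hash=_hash_config(config),
        parameters=config.parameter_record(),
    )
    names = list(config.trajectories)
    group_names = sorted(set(config.groups.values()))

    # --- superposition metrics -------------------------------------------
    note("stage superpose: pairwise RMSD + radius of gyration")
    d = out / "superpose"; d.mkdir(exist_ok=True)
    rg_rows = []
    for name in names:
        traj = config.trajectories[name]
        series, slope = rg_series(traj)
        rg_rows.append({"trajectory": name, "rg_mean": series.mean(),
                        "rg_final": series[-1], "plateau_slope": slope})
        mat = pairwise_rmsd_matrix(traj, selection="ca")
        np.savetxt(d / f"rmsd_{name}.tsv", mat, delimiter="\t", fmt="%.5f")
        manifest.record("superpose", d / f"rmsd_{name}.tsv")
    write_table(pd.DataFrame(rg_rows), d / "radius_of_gyration.tsv")
    manifest.record("superpose", d / "radius_of_gyration.tsv")

    # --- path similarity --------------------------------------------------
    note("stage psa: Hausdorff path-similarity matrix")
    d = out / "psa"; d.mkdir(exist_ok=True)
    stride = max(1, config.psa_stride)
    strided = {
        n: t.with_coords(t.coords[::stride]) for n, t in config.trajectories.items()
    }
    grouping = {g: [n for n in names if config.groups[n] == g] for g in group_names}
    pdm = psa_matrix(strided, selection="ca", groups=grouping)
    pdm.to_frame().to_csv(d / "psa_matrix.tsv", sep="\t", float_format="%.5f")
    (d / "psa_group_means.json").write_text(json.dumps(pdm.group_means(), indent=2))
    manifest.record("psa", d / "psa_matrix.tsv", d / "psa_group_means.json")
    manifest.findings["psa_group_means"] = pdm.group_means()

    # --- landscape --------------------------------------------------------
    note("stage landscape: combined PCA + hierarchical clustering")
    d = out / "landscape"; d.mkdir(exist_ok=True)
    model = fit_landscape(config.trajectories, selection="ca")
    assignment = cluster_frames(model, n_pc=config.n_pc, k=config.k)
    frame_groups = [config.groups[t] for t, _ in model.frame_index]
    proj = pd.DataFrame(
        model.projections[:, : config.n_pc],
        columns=[f"PC{i+1}" for i in range(min(config.n_pc,
                                               model.projections.shape[1]))],
    )
    proj.insert(0, "trajectory", [t for t, _ in model.frame_index])
    proj.insert(1, "frame", [f for _, f in model.frame_index])
    proj["cluster"] = assignment.labels
    write_table(proj, d / "projections.tsv")
    manifest.record("landscape", d / "projections.tsv")
    manifest.findings["variance_explained_4pc"] = model.variance_explained(4)

    note("stage populations: cluster shares, density, convergence")
    d = out / "populations"; d.mkdir(exist_ok=True)
    by_group, within_group = population_table(assignment, frame_groups)
    by_group.to_csv(d / "share_of_cluster_by_group.tsv", sep="\t",
                    float_format="%.3f")
    within_group.to_csv(d / "share_of_group_by_cluster.tsv", sep="\t",
                        float_format="%.3f")
    manifest.record("populations", d / "share_of_cluster_by_group.tsv",
                    d / "share_of_group_by_cluster.tsv")
    manifest.findings["population_within_group_pct"] = {
        str(c): {g: float(within_group.loc[c, g]) for g in within_group.columns}
        for c in within_group.index
    }
    try:
        dens = local_density(model, n_pc=2)
        np.savetxt(d / "local_density.tsv", dens, fmt="%.5f")
        manifest.record("populations", d / "local_density.tsv")
    except Exception as exc:  # optional stage
        note(f"  density skipped: {exc}")
        manifest.failed_stages.append("local_density")
    conv = convergence_analysis(model, n_pc=config.n_pc, k=config.k,
                                window=10, seed=config.seed)
    (d / "convergence_frames.json").write_text(json.dumps(conv, indent=2))
    manifest.record("populations", d / "convergence_frames.json")
    group_conv = {
        g: float(np.mean([conv[n] for n in names if config.groups[n] == g]))
        for g in group_names
    }
    manifest.findings["mean_convergence_frame"] = group_conv

    d = out / "representatives"; d.mkdir(exist_ok=True)
    rep_paths = []
    for c in range(1, assignment.k + 1):
        frame_row = representative_frame(model, assignment, c)
        tname, fno = model.frame_index[frame_row]
        traj = config.trajectories[tname]
        rep = traj.topology.with_coords(traj.coords[fno])
        p = d / f"cluster_{c}_midpoint.pdb"
        write_structure(rep, p)
        rep_paths.append(p)
    manifest.record("representatives", *rep_paths)

    # --- exposure ---------------------------------------------------------
    note("stage sasa: per-residue SASA + region delta tables")
    d = out / "sasa"; d.mkdir(exist_ok=True)
    region_frames = []
    for name in names:
        sasa = sasa_series(config.trajectories[name],
                           probe_radius=config.probe_radius,
                           n_points=config.sasa_points)
        region_frames.append(region_series(sasa, config.regions))
    all_regions = pd.concat(region_frames, ignore_index=True)
    deltas = delta_table(
        all_regions, assignment, config.reference_cluster,
        group_of=frame_groups, reference_group=config.reference_group,
    )
    write_table(deltas, d / "region_delta_table.tsv")
    manifest.record("sasa", d / "region_delta_table.tsv")
    manifest.findings["exposure_deltas"] = {
        f"{r.group}/{r.cluster}/{r.region}": round(float(r.pct_diff_vs_reference), 3)
        for r in deltas.itertuples() if not r.is_reference
    }

    # --- distances --------------------------------------------------------
    note("stage distances: inter-region distances + contacts")
    d = out / "distances"; d.mkdir(exist_ok=True)
    rnames = config.regions.names()
    dist_rows = []
    contact_rows = []
    for name in names:
        traj = config.trajectories[name]
        for i, ra in enumerate(rnames):
            for rb in rnames[i + 1 :]:
                if config.regions.residues(ra) & config.regions.residues(rb):
                    continue
                series = region_distance_series(traj, config.regions, ra, rb)
                dist_rows.append({
                    "trajectory": name, "region_a": ra, "region_b": rb,
                    "mode": "centroid", "mean_nm": float(series.mean()),
                    "first_nm": float(series[0]), "last_nm": float(series[-1]),
                })
        frac, _ = contact_probability(traj, config.regions, rnames[0], rnames[1],
                                      cutoff=config.contact_cutoff)
        contact_rows.append({"trajectory": name, "region_a": rnames[0],
                             "region_b": rnames[1], "contact_fraction": frac})
    write_table(pd.DataFrame(dist_rows), d / "region_distances.tsv")
    write_table(pd.DataFrame(contact_rows), d / "contact_fractions.tsv")
    manifest.record("distances", d / "region_distances.tsv",
                    d / "contact_fractions.tsv")

    # --- rmsf -------------------------------------------------------------
    note("stage rmsf: windowed per-residue fluctuations")
    d = out / "rmsf"; d.mkdir(exist_ok=True)
    rmsf_by_traj = {}
    for name in names:
        rw = windowed_rmsf(config.trajectories[name], window=config.rmsf_window)
        rmsf_by_traj[name] = rw
        rw.values.to_csv(d / f"rmsf_{name}.tsv", sep="\t", float_format="%.5f")
        manifest.record("rmsf", d / f"rmsf_{name}.tsv")

    # --- dccm -------------------------------------------------------------
    note("stage dccm: dynamic cross-correlation")
    d = out / "dccm"; d.mkdir(exist_ok=True)
    first_traj = config.trajectories[names[0]]
    corr = dccm(first_traj)
    corr.values.to_csv(d / "dccm_first_repeat.tsv", sep="\t", float_format="%.4f")
    manifest.record("dccm", d / "dccm_first_repeat.tsv")

    # --- motif ------------------------------------------------------------
    note("stage motif: amphipathic epitope-motif scan")
    d = out / "motif"; d.mkdir(exist_ok=True)
    sequence = config.sequence or bundled_sequence()
    matches = find_epitope_motifs(sequence)
    match_rows = pd.DataFrame([
        {"start": m.start, "end": m.end, "direction": m.direction,
         "variant": m.variant, "mismatches": m.mismatches}
        for m in matches
    ])
    if not match_rows.empty:
        write_table(match_rows, d / "motif_matches.tsv")
        manifest.record("motif", d / "motif_matches.tsv")
    manifest.findings["motif_spans"] = [
        [m.start, m.end] for m in matches
    ]
    try:
        rmsf_first = rmsf_by_traj[names[0]]
        covered = set(int(r) for r in rmsf_first.values.columns)
        if any(set(range(m.start, m.end + 1)) - covered for m in matches):
            rmsf_first = None  # sequence numbering exceeds the trajectory's
        report = motif_report(matches, deltas, config.regions, rmsf_first)
        if not report.empty:
            write_table(report, d / "motif_report.tsv")
            manifest.record("motif", d / "motif_report.tsv")
    except Exception as exc:
        note(f"  motif report skipped: {exc}")
        manifest.failed_stages.append("motif_report")

    manifest.record("manifest", out / "manifest.json")
    manifest.write(out / "manifest.json")
    note("pipeline complete")
    return manifest


# ---------------------------------------------------------------------------
# Demo: two synthetic conditions with planted ground truth
# ---------------------------------------------------------------------------


def demo_anchors(n_beads: int, bond: float, shield: range, target: range,
                 hover: float) -> dict[str, AnchorConformation]:
    """Anchor shapes with the shield segment hovering over the target.

    In every anchor the shield beads are relocated to sit ``hover`` nm
    above the target beads, so region burial is identical across states
    until a displacement is planted — isolating the planted effect from
    shape-driven exposure changes.
    """
    anchors = {}
    for label, shape in [("O", "ring"), ("transitional", "hook"),
                         ("J", "hook"), ("S1", "extended"), ("S2", "scurve")]:
        coords = make_anchor(shape, n_beads, bond).coordinates.copy()
        if label == "transitional":
            ring = make_anchor("ring", n_beads, bond).coordinates
            coords = 0.5 * ring + 0.5 * coords
        for k, bead in enumerate(shield):
            src = target[min(k, len(target) - 1)]
            coords[bead] = coords[src] + np.array([0.0, 0.0, hover])
        anchors[label] = AnchorConformation(label, coords)
    return anchors


def demo_config(seed: int, output_dir: Path, n_repeats: int | None = None,
                n_beads: int | None = None, dwell_scale: float = 1.0,
                sasa_points: int = 240) -> RunConfig:
    """Build the demo's two-condition synthetic dataset.

    wt-like repeats dwell long in the O ring and end in an S shape (one
    repeat reaches the S2 shape exclusively); clipped-like repeats leave
    the ring early and favour the J hook.  The planted shield displacement
    is larger in the clipped-like group.
    """
    p = DEMO_DEFAULTS
    n_repeats = n_repeats or p["n_repeats"]
    n_beads = n_beads or p["n_beads"]
    regions = load_regions(DEMO_REGIONS_YAML)
    target = range(min(regions.residues("target")) - 1,
                   max(regions.residues("target")))
    shield = range(min(regions.residues("shield")) - 1,
                   max(regions.residues("shield")))
    anchors = demo_anchors(n_beads, p["bond_length"], shield, target,
                           p["shield_hover"])

    def scaled(x: int) -> int:
        return max(2, int(round(x * dwell_scale)))

    trajectories, groups = {}, {}
    for group, displacement in [("wt-like", p["displacement_wt"]),
                                ("clipped-like", p["displacement_clipped"])]:
        for rep in range(n_repeats):
            if group == "wt-like":
                end_label = "S2" if rep == 0 else "S1"
                segments = (
                    ("O", scaled(120), scaled(12)),
                    ("transitional", scaled(18), scaled(12)),
                    ("J", scaled(60), scaled(12)),
                    (end_label, scaled(46), 0),
                )
            else:
                segments = (
                    ("O", scaled(40), scaled(12)),
                    ("transitional", scaled(18), scaled(12)),
                    ("J", scaled(130), scaled(12)),
                    ("S1", scaled(46), 0),
                )
            schedule = TransitionSchedule(segments)
            spec = SyntheticSpec(
                n_beads=n_beads, schedule=schedule,
                seed=(seed * 1000 + rep * 2 +
                      (0 if group == "wt-like" else 1)) % (2**31 - 1),
                noise_sigma=p["noise_sigma"], bond_length=p["bond_length"],
            )
            traj, _ = generate_trajectory(spec, anchors)
            switch = segments[0][1]  # end of the O dwell
            traj = plant_exposure_change(traj, regions, "shield", "target",
                                         displacement, switch)
            traj = plant_correlated_motion(
                traj, [p["correlated_pair"]], p["correlated_amplitude"],
                seed=spec.seed + 7,
            )
            name = f"{group}-{rep}"
            trajectories[name] = traj
            groups[name] = group
    return RunConfig(
        trajectories=trajectories, groups=groups, regions=regions,
        output_dir=Path(output_dir), n_pc=4, k=5,
        rmsf_window=max(10, scaled(50)), sasa_points=sasa_points,
        reference_cluster=1, reference_group="wt-like", seed=seed,
    )


def demo(seed: int = 1, output_dir: str | Path = "confshift_demo",
         **kwargs) -> RunManifest:
    """Generate the two-condition synthetic dataset, run the full pipeline
    and print a findings summary (population shift, exposure deltas,
    convergence frames)."""
    config = demo_config(seed, Path(output_dir), **kwargs)
    manifest = run_pipeline(config)
    f = manifest.findings
    print("=== demo findings ===")
    print(f"PSA group means (nm): {f['psa_group_means']}")
    print(f"variance explained by 4 PCs: {f['variance_explained_4pc']:.3f}")
    print(f"mean convergence frame: {f['mean_convergence_frame']}")
    print("population share within each group (%):")
    for cluster, shares in f["population_within_group_pct"].items():
        print(f"  state {cluster}: " + ", ".join(
            f"{g}={v:.1f}" for g, v in shares.items()))
    print("exposure deltas vs reference state (%):")
    for key, val in sorted(f["exposure_deltas"].items()):
        print(f"  {key}: {val:+.2f}")
    print(f"motif spans on bundled sequence: {f['motif_spans']}")
    return manifest
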