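# confshift

Trajectory analysis for proteins whose antibody-binding surfaces are
*cryptic*: hidden in one conformation and exposed in another. The
motivating system is β2-glycoprotein I (β2GPI), the main autoantigen of
the antiphospholipid syndrome, which circulates as a closed ring
("O-shape") that buries the pathogenic epitope on domain I under domain V,
and opens through a transition state into fishhook ("J") and sigmoidal
("S") conformations that expose it. `confshift` implements the complete
analysis chain used to characterise such a transition from molecular
dynamics repeats — and a synthetic-trajectory generator with planted
ground truth, so every stage of the chain can be validated against a known
answer before it is trusted on real data.

## What it computes

* **Path similarity** between repeat trajectories via the Hausdorff
  distance, δ_H(P|Q) = max_{p∈P} min_{q∈Q} rmsd(p, q), under superposed
  Cα RMSD; symmetric by default. Higher values mean more dissimilar paths.
* **Conformational states**: coordinate PCA on all repeats combined,
  then agglomerative clustering (average linkage, first 4 PCs, 5 states by
  default), population tables normalised by state and by condition, local
  point density in PC space, representative mid-point frames, and a
  K-means rolling-window convergence frame per repeat.
* **Epitope exposure**: per-residue Shrake–Rupley solvent-accessible
  surface area (probe 0.14 nm, 960 deterministic sphere points), region
  totals, and delta tables — mean ± SEM per (condition, state, region)
  with percent differences against a reference state and across
  conditions, SEMs propagated in quadrature on the ratio.
* **Flexibility and coupling**: windowed per-residue RMSF (each window
  superposed to its own mean), dynamic cross-correlation matrices
  C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), inter-region distances, and
  contact probabilities (any atom pair strictly below 0.24 nm).
* **Interface scanning**: rigid pose grids (3 axial positions × 8
  angles = 24 orientations by default) with contact-specificity ranking,
  and the flat-bottom closure restraint E = ½k·Δd² outside walls at
  0.15/0.4 nm with k = 1000 kJ/mol/nm².
* **Motif detection**: fuzzy bidirectional scanning for the amphipathic
  epitope pattern family ϕϕϕζζFxϕ / ϕϕϕζζFxC / ϕϕϕζζϕxϕ (ϕ nonpolar,
  ζ polar, x spacer), including the curated family rule that locates the
  five motif sites in β2GPI domains I–II.

I/O: PDB structures and multi-model PDB trajectories (DCD through an
MDAnalysis adapter), YAML region definitions, FASTA sequences, TSV/JSON
results. All internal coordinates are nanometres.

## Worked example

The bundled demo generates two synthetic conditions of a 60-bead chain —
"wt-like" repeats that dwell long in the closed ring, and "clipped-like"
repeats that open early — with a shield segment hovering over a target
region and rigidly displaced at the opening transition (further in the
clipped-like group), plus one planted anticorrelated residue pair:

```bash
confshift demo --seed 1 --out demo_out
```

prints, among the stage logs:

```
=== demo findings ===
PSA group means (nm): {'clipped-like': 0.161..., 'wt-like': 1.025...}
variance explained by 4 PCs: 0.998
mean convergence frame: {'clipped-like': 214.0, 'wt-like': 223.2}
population share within each group (%):
  state 1: clipped-like=15.6, wt-like=43.6
  state 3: clipped-like=54.4, wt-like=27.7
  ...
exposure deltas vs reference state (%):
  clipped-like/3/target: +31.35
  wt-like/3/target: +5.74
  ...
motif spans on bundled sequence: [[10, 17], [16, 24], [40, 47], [53, 60], [65, 72]]
```

Reading: the early-opening group leaves the closed state sooner (smaller
convergence frame, smaller share of state 1), its repeats follow one
another more closely (smaller path-similarity mean), and the planted
unburial of the target region shows up as a positive exposure delta in
the open state, larger where the planted displacement was larger. The
motif scan locates the five family sites of the domain I–II fragment.

Per-stage subcommands (`confshift psa|rmsd|rmsf|dccm|motif|scan|run`)
operate on user files; `confshift run -c config.yaml` drives the full
pipeline over your own trajectories and writes a manifest of every output.

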