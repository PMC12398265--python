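# Methods

## Scope and conventions

`confshift` analyses conformational-transition trajectories of
multi-domain proteins, with the O→J→S opening of β2-glycoprotein I as the
motivating case. All internal coordinates are **nanometres** (PDB I/O
converts from/to angstroms at the boundary), residue numbering is 1-based
mature-protein numbering, and region spans are inclusive on both ends.
Atomic radii come from a single Bondi-style table pinned in
`model_io.VDW_RADII_NM` (C 0.170, N 0.155, O 0.152, S 0.180, H 0.120 nm,
…); hydrogens, when present in the input, keep their own radius and are
never merged into heavy atoms. SASA is computed over whatever atoms the
input contains; the parameter record of each run captures that choice.

## Superposition and RMSD

Rigid superposition is the Kabsch solution from the SVD of the weighted
cross-covariance, with the reflection branch removed by flipping the
smallest singular vector when det < 0. Exactly collinear point sets are
rejected as degenerate (the rotation is under-determined); in practice
only noise-free synthetic frames trigger this. Pairwise frame-vs-frame
RMSD matrices use a batched formulation — rmsd²(p,q) = (tr PcPcᵀ + tr QcQcᵀ
− 2Σσᵢ)/n from the singular values of every pairwise cross-covariance —
which agrees with a per-pair Kabsch loop to 1e-8 nm and carries ~1e-7 nm
of batched-SVD noise, the tolerance used wherever an exact zero is
expected. RMSD defaults to Cα atoms (bead models fall back to all beads);
whether the original analyses used all atoms is not knowable from their
description, so an all-atom selection remains available.

The radius of gyration is the mass-weighted RMS distance from the centre
of mass (uniform masses when none are given). `rg_series` also reports
the least-squares slope over the final third of the trajectory as a
plateau diagnostic: near-zero slope indicates the repeat has settled.

## Path similarity

Two trajectories are compared as frame sets under superposed-RMSD with
the directed Hausdorff value δ_H(P|Q) = max_p min_q rmsd(p,q). The
directed value is what the formula above defines, but the symmetric
max(δ_H(P|Q), δ_H(Q|P)) is a pseudometric and standard practice, so both
are provided; **symmetric is the default** and the
method name is recorded in every output. Group means of off-diagonal
entries put two conditions of repeats on a common scale.

## Conformational landscape

All repeats are concatenated and superposed to an iteratively refined
mean (two refinement passes — the reference for the original analyses is
unstated, and the iterative mean is the least arbitrary choice). PCA is
solved on whichever side of the duality is smaller: the 3N×3N coordinate
covariance when 3N ≤ F, else the F×F Gram matrix (identical spectra by
construction; verified by orthonormality and completeness tests).
Sample covariance uses F−1.

Clustering is agglomerative with **average linkage on Euclidean distance
in the first 4 PCs, cut to 5 clusters** by default, matching the study
design this pipeline re-implements; k is exposed and never auto-selected.
Labels are renumbered by first appearance so identical inputs give
bit-identical assignments. Local density is a Gaussian KDE (Scott's rule
bandwidth by default) over the first 2 PCs, normalised to a maximum
of 1. The representative frame of a state minimises distance to the
state centroid in PC space, ties to the lowest frame index.

Convergence analysis labels all frames by K-means (k-means++, 10
restarts, fixed seed) and reports, per repeat, the earliest frame after
which every rolling 10-frame window's majority label equals the final
window's majority — early-opening trajectories converge at smaller frame
numbers.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-spiral point set: each atom's
probe-expanded sphere (r + 0.14 nm) carries 960 test points; a point is
accessible if outside every neighbour's expanded sphere, and the atom's
area is the accessible fraction of 4π(r+probe)². Neighbour search uses a
k-d tree. Accuracy characteristics measured by the test suite: isolated
atoms match the closed form to the quadrature resolution (<0.5%),
two-sphere overlaps agree with a 10⁶-point Monte-Carlo estimate within
2%, doubling the point count changes a 50-atom cluster's total by <0.5%,
and rigid rotations move totals by <0.5% (the angular anisotropy of the
point set at 960 points; use more points where tighter rotational
invariance matters).

Delta tables report, per (condition, state, region), the mean region SASA
over member frames, its SEM, and 100×(mean_state − mean_ref)/mean_ref
against the reference (closed) state within the same condition, plus the
analogous cross-condition difference at fixed state. The "±" on a percent
difference propagates the two SEMs in quadrature on the ratio:
σ% = 100·|r|·√((σ_c/m_c)² + (σ_ref/m_ref)²). Because consecutive frames
are autocorrelated, a block-averaged SEM (10-frame blocks) is emitted
alongside the plain frames-independent SEM; which convention the original
tables used is not stated, so both are reported.

## Flexibility and correlated motion

Windowed RMSF splits a trajectory into fixed-length fragments (default
matches six fragments on a 150-frame repeat), superposes **each fragment
to its own mean** (local flexibility, not drift), and reports per-residue
RMSF plus percent differences of later windows against the first —
negative values mean stabilisation. The DCCM uses the isotropic
scalar-product convention C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) about
the superposed mean; residues with zero variance are reported as NaN
(undefined), never as 0. Inter-region distances offer centroid and
minimum-atom modes (the mode is recorded in output; which one the source
figures used is unstated). A frame is "in contact" when any inter-region
atom pair is strictly below the 0.24 nm cutoff; the frame counts once
toward the probability, while the residue-pair map preserves
multiplicity.

## Interface scanning

Pose grids place the mobile selection at n_axial evenly spaced positions
along the target's principal axis (largest-variance direction — the
working definition of a domain's "main axis") × n_angles evenly spaced
rotations about it; defaults 3 × 8 = 24. Contact specificity of a residue
pair is max-pose frequency / total frequency (1.0 = single-pose contact),
ranked with total frequency as tie-break; the score is this package's
construction, chosen as the simplest statistic that separates a geometric
binding site from promiscuous contact. The flat-bottom restraint uses the
½k(Δd)² convention (zero between walls, harmonic outside, force
continuous at the walls); users of the k(Δd)² convention should double k.
Defaults: k = 1000 kJ/mol/nm², walls 0.15/0.40 nm. The scanner scores
static poses; it does not generate dynamics for them.

## Motif scanning

Residues are classified nonpolar ϕ = {A,V,L,I,M,F,W,C,G,P} or polar
ζ = {S,T,N,Q,Y,H,K,R,D,E}; only F and C are fixed by the published
pattern family, the remainder follows the common hydropathy-style
partition and is overridable. The generic scanner matches class/literal
patterns at every offset in both chain directions (an epitope is a
surface; reading direction is not meaningful a priori), with a per-symbol
mismatch count and an optionally elastic spacer `x` (1..x_max residues).

The curated family search (`find_epitope_motifs`) encodes how the five
published sites in β2GPI domains I–II relate to the canonical patterns
ϕϕϕζζFxϕ / ϕϕϕζζFxC / ϕϕϕζζϕxϕ. No published rule defines "closely
related", so the rule here was designed once against the published site
list and is documented as an interpretation: scan the simplified core
ϕϕϕζζϕxϕ (elastic spacer, both directions) and accept a window according
to its literal anchors — with both F (slot 6) and C (slot 8) up to 3
class mismatches are allowed provided the leading ϕϕϕ block keeps at
most one; with F alone, one mismatch; with C alone, none (canonical
spacer only); with neither anchor the window is rejected. Overlapping
candidates are pruned keeping the best (fewest mismatches, more anchors,
shorter) while allowing up to two shared residues, which is what lets the
adjacent 10–17 and 16–24 sites coexist. On the bundled domain I–II
fragment (mature residues 1–125, UniProt P02749) this yields exactly the
five sites 10–17, 16–24, 40–47, 53–60 and 65–72 with the published
variant annotations; on other sequences it should be read as a
hypothesis generator, not a validated classifier.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *statistical* shape of an opening transition:
a bead-per-residue chain (bond 0.38 nm) that dwells in anchor shapes —
ring (closed O), hook (J), extended and S-curve, all built with exact
bond lengths — plus isotropic Gaussian coordinate noise, linear
interpolation over transition frames, and per-frame ground-truth labels.
Planted effects give downstream stages an answer key: a shield segment
rigidly displaced away from a target region at a chosen frame (the
analogue of one domain unblocking another's surface), and a shared
scalar drive added to a residue pair with chosen sign. One RNG stream
per trajectory derives from (seed, repeat), so repeats are independent
but byte-reproducible.

It contains **no physics**: no bonded or non-bonded forces, no solvent,
no thermostat, no kinetics beyond the schedule. Passing the planted-
recovery tests therefore establishes that the *analysis chain* is
correct and sensitive at the planted effect sizes — it does not validate
any force field or sampling protocol, and real trajectories with
autocorrelated, anisotropic fluctuations may need larger effect sizes or
block statistics to reach the same confidence.

Demo conditions (fixed as the package's study design): 60 beads, noise
σ = 0.03 nm, 5 repeats per condition of ~300 frames; "wt-like" repeats
dwell 120 frames in the ring before opening and end in an S shape (one
repeat reaches the second S shape exclusively), "clipped-like" repeats
leave after 40 frames and favour the hook; the shield hovers 0.55 nm
above the target in every anchor and is displaced a further 0.15 nm
(wt-like) or 0.35 nm (clipped-like) at each repeat's opening transition
— both within the partial-burial range of the 0.3 nm bead radius, so the
exposure delta remains monotone in the displacement; one anticorrelated
pair (5, 35) with amplitude 0.25 nm. Anchor shapes are ≥ 1 nm apart in
RMSD and the noise is well below that separation, the regime in which
state recovery is expected to be essentially exact (ARI ≥ 0.95).

## Problem sizes and numerical choices

Tests and the acceptance script run at reduced sizes chosen to exercise
every code path while keeping the whole suite in seconds: oracle
comparisons use 5–10 frames of 5–12 beads; planted-recovery runs use
30–40 beads, 80–160 frames and 2–3 repeats; the demo pipeline defaults to
the full two×five×~300-frame design with 240 SASA points per sphere
(the 960-point default is used wherever an absolute area is asserted).
Ties in clustering and representative-frame selection break to the lowest
index; zero-variance residues are masked, not zeroed; percent differences
against a zero reference mean raise rather than returning infinities;
KDE degeneracy (zero spread in the chosen components) raises a dedicated
error. All randomness in any pipeline flows from a single integer seed.

## Known limitations

* Multi-chain region handling is minimal (single-chain assumed when chain
  ids are blank); mmCIF and topology formats (PSF/PRMTOP) are not read.
* SASA has no polar/apolar split and no relative-exposure normalisation.
* The Hausdorff comparison treats trajectories as unordered frame sets;
  no time warping or Fréchet distance.
* No kinetic models (MSMs, tICA) and no free-energy surfaces.
* The motif family rule is calibrated to one published site list; treat
  cross-protein application as exploratory.
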