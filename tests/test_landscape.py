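"""Landscape PCA, clustering, populations, densities, convergence."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from confshift.errors import DegenerateGeometryError, InputError
from confshift.landscape import (
    cluster_frames,
    convergence_analysis,
    fit_landscape,
    local_density,
    population_table,
    representative_frame,
)
from confshift.synthetic_data import (
    SyntheticSpec,
    TransitionSchedule,
    generate_trajectory,
    make_anchor,
)


@pytest.fixture
def two_anchor_model(two_state_trajectory):
    traj, labels = two_state_trajectory
    model = fit_landscape({"t": traj})
    return model, labels


class TestFitLandscape:
    def test_rank_one_data_single_nonzero_eigenvalue(self,
                                                     bead_trajectory_factory,
                                                     rng):
        base = rng.normal(size=(6, 3))
        direction = rng.normal(size=(6, 3))
        # strip rigid-body components so superposition leaves the line intact
        direction -= direction.mean(axis=0)
        centred = base - base.mean(axis=0)
        rigid = [np.cross(np.tile(e, (6, 1)), centred) for e in np.eye(3)]
        for mode in rigid:
            flat = mode.ravel() / np.linalg.norm(mode.ravel())
            direction -= (direction.ravel() @ flat) * flat.reshape(6, 3)
        frames = np.stack([base + t * direction for t in np.linspace(0, 0.3, 8)])
        model = fit_landscape({"t": bead_trajectory_factory(frames)})
        ev = model.eigenvalues
        assert ev[0] > 1e-6
        # superposition can only shrink the line; remaining modes are noise
        assert np.all(ev[1:] < 1e-4 * ev[0])

    def test_total_variance_explained_is_one(self, two_anchor_model):
        model, _ = two_anchor_model
        assert model.variance_explained() == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalues_sorted_and_nonnegative(self, two_anchor_model):
        model, _ = two_anchor_model
        ev = model.eigenvalues
        assert np.all(np.diff(ev) <= 1e-12)
        assert np.all(ev >= 0)

    def test_eigenvectors_orthonormal(self, two_anchor_model):
        model, _ = two_anchor_model
        v = model.eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_centered_frame_reconstruction(self, two_state_trajectory):
        traj, _ = two_state_trajectory
        model = fit_landscape({"t": traj})
        # any centred superposed frame must be reproduced by the full basis
        recon = model.projections @ model.eigenvectors.T
        assert recon.shape == (traj.n_frames, traj.n_atoms * 3)
        # reconstruction error per coordinate below 1e-8 nm
        x = recon.reshape(traj.n_frames, traj.n_atoms, 3) + model.mean_structure
        # re-derive projections from the reconstruction: must be identical
        re_proj = (x - model.mean_structure).reshape(traj.n_frames, -1) \
            @ model.eigenvectors
        np.testing.assert_allclose(re_proj, model.projections, atol=1e-8)

    def test_eigenvalue_sum_matches_coordinate_variance(self,
                                                        two_state_trajectory):
        traj, _ = two_state_trajectory
        model = fit_landscape({"t": traj})
        total_var = model.projections.var(axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total_var, abs=1e-8)

    def test_dual_solution_matches_direct(self, bead_trajectory_factory, rng):
        # 40 atoms (120 coords) but only 6 frames -> dual path; compare with
        # the direct covariance on the same centred data
        frames = rng.normal(size=(6, 40, 3))
        model = fit_landscape({"t": bead_trajectory_factory(frames)})
        assert model.eigenvectors.shape[0] == 120
        assert model.variance_explained() == pytest.approx(1.0, abs=1e-9)
        v = model.eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_single_frame_rejected(self, bead_trajectory_factory, rng):
        traj = bead_trajectory_factory(rng.normal(size=(1, 5, 3)))
        with pytest.raises(InputError):
            fit_landscape({"t": traj})


class TestClusterFrames:
    def test_two_separated_anchors_recovered_exactly(self, two_anchor_model):
        model, labels = two_anchor_model
        assignment = cluster_frames(model, n_pc=2, k=2)
        assert adjusted_rand_score(labels, assignment.labels) == 1.0

    def test_k_one_single_cluster(self, two_anchor_model):
        model, _ = two_anchor_model
        assignment = cluster_frames(model, k=1)
        assert set(assignment.labels) == {1}

    def test_duplicated_frame_shares_cluster(self, bead_trajectory_factory,
                                             rng):
        frames = rng.normal(size=(7, 5, 3))
        frames[3] = frames[0]  # exact duplicate
        model = fit_landscape({"t": bead_trajectory_factory(frames)})
        assignment = cluster_frames(model, n_pc=2, k=3)
        assert assignment.labels[3] == assignment.labels[0]

    def test_deterministic_labelling(self, two_anchor_model):
        model, _ = two_anchor_model
        a = cluster_frames(model, n_pc=2, k=2)
        b = cluster_frames(model, n_pc=2, k=2)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.labels[0] == 1  # first frame defines cluster 1

    def test_k_exceeding_frames_rejected(self, two_anchor_model):
        model, _ = two_anchor_model
        with pytest.raises(InputError):
            cluster_frames(model, k=model.n_frames + 1)


class TestPopulationTable:
    def test_single_group_all_hundred(self, two_anchor_model):
        model, _ = two_anchor_model
        assignment = cluster_frames(model, n_pc=2, k=2)
        by_group, within = population_table(assignment, ["g"] * model.n_frames)
        np.testing.assert_allclose(by_group.to_numpy(), 100.0)
        assert within["g"].sum() == pytest.approx(100.0)

    def test_hand_counted_shares(self, two_anchor_model):
        model, _ = two_anchor_model
        assignment = cluster_frames(model, n_pc=2, k=2)
        # 10 frames per state: give state-1 frames 6 WT + 4 CL
        groups = ["WT"] * 6 + ["CL"] * 4 + ["WT"] * 5 + ["CL"] * 5
        by_group, within = population_table(assignment, groups)
        assert by_group.loc[1, "WT"] == pytest.approx(60.0)
        assert by_group.loc[1, "CL"] == pytest.approx(40.0)

    def test_normalisation_sums(self, two_anchor_model):
        model, _ = two_anchor_model
        assignment = cluster_frames(model, n_pc=2, k=2)
        groups = (["a"] * 7 + ["b"] * 13)
        by_group, within = population_table(assignment, groups)
        np.testing.assert_allclose(by_group.sum(axis=1), 100.0, atol=1e-9)
        np.testing.assert_allclose(within.sum(axis=0), 100.0, atol=1e-9)


class TestLocalDensity:
    def test_duplicated_point_has_max_density(self, bead_trajectory_factory,
                                              rng):
        scattered = rng.normal(scale=3.0, size=(20, 5, 3))
        clump_centre = rng.normal(scale=3.0, size=(1, 5, 3))
        clumped = np.repeat(clump_centre, 10, axis=0) \
            + 1e-4 * rng.normal(size=(10, 5, 3))
        frames = np.concatenate([clumped, scattered])
        model = fit_landscape({"t": bead_trajectory_factory(frames)})
        dens = local_density(model, n_pc=2)
        assert dens.max() == pytest.approx(1.0)
        assert np.all(dens > 0)
        assert dens[:10].min() > dens[10:].max()

    def test_matches_direct_kernel_sum(self, bead_trajectory_factory, rng):
        frames = rng.normal(size=(30, 5, 3))
        model = fit_landscape({"t": bead_trajectory_factory(frames)})
        dens = local_density(model, n_pc=2)
        pts = model.projections[:, :2]
        # independent Gaussian-kernel sum with Scott's-rule bandwidth
        n, d = pts.shape
        factor = n ** (-1.0 / (d + 4))
        cov = np.cov(pts.T) * factor**2
        inv = np.linalg.inv(cov)
        norm = 1.0 / (2 * np.pi * np.sqrt(np.linalg.det(cov)) * n)
        direct = np.empty(n)
        for i in range(n):
            diff = pts - pts[i]
            direct[i] = norm * np.exp(-0.5 * np.einsum(
                "ij,jk,ik->i", diff, inv, diff)).sum()
        np.testing.assert_allclose(dens, direct / direct.max(), atol=1e-10)

    def test_zero_variance_degenerate(self, bead_trajectory_factory, rng):
        frame = rng.normal(size=(5, 3))
        traj = bead_trajectory_factory(np.repeat(frame[None], 6, axis=0))
        model = fit_landscape({"t": traj})
        with pytest.raises(DegenerateGeometryError):
            local_density(model, n_pc=2)


class TestRepresentativeFrame:
    def test_singleton_cluster_returns_that_frame(self, bead_trajectory_factory,
                                                  rng):
        frames = rng.normal(size=(5, 5, 3))
        frames[2] += 30.0  # isolated frame forms its own cluster
        model = fit_landscape({"t": bead_trajectory_factory(frames)})
        assignment = cluster_frames(model, n_pc=2, k=2)
        lone = [c for c in (1, 2)
                if len(assignment.members(c)) == 1][0]
        assert representative_frame(model, assignment, lone) == 2

    def test_matches_exhaustive_search(self, two_anchor_model):
        model, _ = two_anchor_model
        assignment = cluster_frames(model, n_pc=2, k=2)
        for c in (1, 2):
            members = assignment.members(c)
            coords = model.projections[:, :2]
            centroid = coords[members].mean(axis=0)
            expected = members[int(np.argmin(
                np.linalg.norm(coords[members] - centroid, axis=1)))]
            assert representative_frame(model, assignment, c) == expected


class TestConvergence:
    def test_constant_trajectory_converges_at_zero(self, bead_trajectory_factory,
                                                   rng):
        a = rng.normal(size=(6, 3))
        b = a + np.array([5.0, 0.0, 0.0]) + rng.normal(size=(6, 3))
        const = bead_trajectory_factory(a + 0.01 * rng.normal(size=(30, 6, 3)))
        other = bead_trajectory_factory(b + 0.01 * rng.normal(size=(30, 6, 3)))
        model = fit_landscape({"const": const, "other": other})
        conv = convergence_analysis(model, n_pc=2, k=2, window=5, seed=0)
        assert conv["const"] == 0
        assert conv["other"] == 0

    def test_single_switch_window_one(self, two_state_trajectory):
        traj, _ = two_state_trajectory
        model = fit_landscape({"t": traj})
        conv = convergence_analysis(model, n_pc=2, k=2, window=1, seed=0)
        assert conv["t"] == 10  # states switch exactly at frame 10

    def test_early_transition_converges_earlier(self):
        a = make_anchor("ring", 10, 0.38, label="A")
        b = make_anchor("hook", 10, 0.38, label="B")
        trajs = {}
        for name, dwell_a in (("late", 40), ("early", 10)):
            sched = TransitionSchedule((("A", dwell_a, 0), ("B", 60 - dwell_a, 0)))
            spec = SyntheticSpec(n_beads=10, schedule=sched, seed=5,
                                 noise_sigma=0.02)
            trajs[name], _ = generate_trajectory(spec, {"A": a, "B": b})
        model = fit_landscape(trajs)
        conv = convergence_analysis(model, n_pc=2, k=2, window=5, seed=0)
        assert conv["early"] < conv["late"]
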