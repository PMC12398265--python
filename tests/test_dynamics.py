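"""Windowed RMSF, DCCM, inter-region distances and contact probabilities."""

import numpy as np
import pytest

from confshift.dynamics import (
    contact_probability,
    dccm,
    region_distance_series,
    windowed_rmsf,
)
from confshift.errors import InputError
from confshift.model_io import RegionSet
from confshift.superposition import kabsch_superpose
from confshift.synthetic_data import plant_correlated_motion


class TestWindowedRmsf:
    def test_static_trajectory_zero_rmsf(self, bead_trajectory_factory, rng):
        frame = rng.normal(size=(6, 3))
        traj = bead_trajectory_factory(np.repeat(frame[None], 20, axis=0))
        rw = windowed_rmsf(traj, window=10)
        np.testing.assert_allclose(rw.values.to_numpy(), 0.0, atol=1e-9)

    def test_150_frames_25_window_gives_6_fragments(self,
                                                    bead_trajectory_factory,
                                                    rng):
        traj = bead_trajectory_factory(rng.normal(size=(150, 5, 3)))
        rw = windowed_rmsf(traj, window=25)
        assert rw.n_windows == 6

    def test_trailing_partial_window_dropped(self, bead_trajectory_factory,
                                             rng):
        traj = bead_trajectory_factory(rng.normal(size=(37, 5, 3)))
        assert windowed_rmsf(traj, window=10).n_windows == 3

    def test_alternating_bead_closed_form(self, bead_trajectory_factory, rng):
        # bead 0 alternates +/-a about its mean along a direction with the
        # rigid-body (translation/rotation) components projected out, so the
        # per-window superposition is a no-op and RMSF = a exactly
        scaffold = rng.normal(scale=2.0, size=(10, 3))
        v = np.zeros((10, 3))
        v[0] = [1.0, 0.0, 0.0]
        centred = scaffold - scaffold.mean(axis=0)
        modes = [np.tile(e, (10, 1)) for e in np.eye(3)]
        modes += [np.cross(np.tile(e, (10, 1)), centred) for e in np.eye(3)]
        for mode in modes:
            flat = mode.ravel() / np.linalg.norm(mode.ravel())
            v -= (v.ravel() @ flat) * flat.reshape(10, 3)
        a = 0.05 / np.linalg.norm(v[0])  # bead-0 amplitude exactly 0.05
        frames = np.repeat(scaffold[None], 20, axis=0)
        frames[::2] += a * v
        frames[1::2] -= a * v
        rw = windowed_rmsf(bead_trajectory_factory(frames), window=10)
        assert rw.values.iloc[0][1] == pytest.approx(0.05, rel=0.02)

    def test_window_exceeding_frames_rejected(self, bead_trajectory_factory,
                                              rng):
        traj = bead_trajectory_factory(rng.normal(size=(5, 5, 3)))
        with pytest.raises(InputError):
            windowed_rmsf(traj, window=10)

    def test_percent_difference_detects_stabilisation(self,
                                                      bead_trajectory_factory,
                                                      rng):
        scaffold = rng.normal(scale=2.0, size=(8, 3))
        frames = np.repeat(scaffold[None], 40, axis=0)
        noise = rng.normal(size=(40, 1))
        # bead 0 fluctuates strongly in window 0, weakly afterwards
        frames[:20, 0, 0] += 0.4 * noise[:20, 0]
        frames[20:, 0, 0] += 0.04 * noise[20:, 0]
        rw = windowed_rmsf(bead_trajectory_factory(frames), window=20)
        pct = rw.percent_difference()
        assert pct.iloc[0][1] < -50.0


class TestDccm:
    def test_diagonal_unity_and_range(self, random_walk_trajectory):
        matrix = dccm(random_walk_trajectory).values.to_numpy()
        np.testing.assert_allclose(np.diag(matrix), 1.0, atol=1e-9)
        assert np.nanmax(np.abs(matrix)) <= 1.0 + 1e-9
        np.testing.assert_allclose(matrix, matrix.T, atol=1e-9)

    def test_matches_direct_covariance_sums(self, bead_trajectory_factory,
                                            rng):
        frames = rng.normal(size=(10, 5, 3))
        traj = bead_trajectory_factory(frames)
        matrix = dccm(traj).values.to_numpy()
        # independent oracle: replicate on the superposed frames with plain
        # python loops over the covariance definition
        aligned = frames.copy()
        ref = aligned[0]
        for _ in range(3):
            for i in range(10):
                aligned[i] = kabsch_superpose(aligned[i], ref).transformed
            ref = aligned.mean(axis=0)
        dev = aligned - aligned.mean(axis=0)
        expected = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                cij = np.mean([dev[f, i] @ dev[f, j] for f in range(10)])
                cii = np.mean([dev[f, i] @ dev[f, i] for f in range(10)])
                cjj = np.mean([dev[f, j] @ dev[f, j] for f in range(10)])
                expected[i, j] = cij / np.sqrt(cii * cjj)
        np.testing.assert_allclose(matrix, expected, atol=1e-8)

    def test_planted_anticorrelated_pair_recovered(self,
                                                   bead_trajectory_factory,
                                                   rng):
        base = rng.normal(scale=2.0, size=(10, 3))
        frames = base + 0.01 * rng.normal(size=(60, 10, 3))
        traj = bead_trajectory_factory(frames)
        planted = plant_correlated_motion(traj, [(2, 8, -1)], amplitude=0.5,
                                          seed=3)
        matrix = planted.dccm_values = dccm(planted).values
        assert matrix.loc[2, 8] <= -0.8

    def test_planted_positive_pair_recovered(self, bead_trajectory_factory,
                                             rng):
        base = rng.normal(scale=2.0, size=(10, 3))
        frames = base + 0.01 * rng.normal(size=(60, 10, 3))
        planted = plant_correlated_motion(bead_trajectory_factory(frames),
                                          [(2, 8, 1)], amplitude=0.5, seed=3)
        assert dccm(planted).values.loc[2, 8] >= 0.8

    def test_fewer_than_two_frames_rejected(self, bead_trajectory_factory,
                                            rng):
        traj = bead_trajectory_factory(rng.normal(size=(1, 5, 3)))
        with pytest.raises(InputError):
            dccm(traj)

    def test_rigid_translation_leaves_rmsf_and_dccm_unchanged(
            self, bead_trajectory_factory, rng):
        frames = rng.normal(size=(12, 6, 3))
        shifted = frames + np.arange(12)[:, None, None] * np.array([1.0, 0, 0])
        a = dccm(bead_trajectory_factory(frames)).values.to_numpy()
        b = dccm(bead_trajectory_factory(shifted)).values.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-6)
        ra = windowed_rmsf(bead_trajectory_factory(frames), window=6)
        rb = windowed_rmsf(bead_trajectory_factory(shifted), window=6)
        np.testing.assert_allclose(ra.values.to_numpy(), rb.values.to_numpy(),
                                   atol=1e-6)


class TestRegionDistances:
    def test_two_single_atom_regions(self, bead_trajectory_factory):
        frames = np.zeros((3, 4, 3))
        frames[:, 1] = [2.0, 0, 0]
        traj = bead_trajectory_factory(frames)
        rs = RegionSet({"a": frozenset({1}), "b": frozenset({2})})
        series = region_distance_series(traj, rs, "a", "b")
        np.testing.assert_allclose(series, 2.0)

    def test_min_atom_never_exceeds_centroid(self, random_walk_trajectory):
        rs = RegionSet({"a": frozenset({1, 2, 3}), "b": frozenset({8, 9, 10})})
        cen = region_distance_series(random_walk_trajectory, rs, "a", "b",
                                     mode="centroid")
        mn = region_distance_series(random_walk_trajectory, rs, "a", "b",
                                    mode="min_atom")
        assert np.all(mn <= cen + 1e-12)

    def test_overlapping_regions_rejected(self, random_walk_trajectory):
        rs = RegionSet({"a": frozenset({1, 2}), "b": frozenset({2, 3})})
        with pytest.raises(InputError):
            region_distance_series(random_walk_trajectory, rs, "a", "b")


class TestContactProbability:
    def test_always_in_contact(self, bead_trajectory_factory):
        frames = np.zeros((4, 2, 3))
        frames[:, 1] = [0.1, 0, 0]
        rs = RegionSet({"a": frozenset({1}), "b": frozenset({2})})
        frac, pairs = contact_probability(bead_trajectory_factory(frames),
                                          rs, "a", "b")
        assert frac == 1.0
        assert pairs.iloc[0]["frequency"] == 1.0

    def test_never_in_contact(self, bead_trajectory_factory):
        frames = np.zeros((4, 2, 3))
        frames[:, 1] = [0.5, 0, 0]
        rs = RegionSet({"a": frozenset({1}), "b": frozenset({2})})
        frac, pairs = contact_probability(bead_trajectory_factory(frames),
                                          rs, "a", "b")
        assert frac == 0.0
        assert pairs.empty

    def test_half_of_frames_hand_count(self, bead_trajectory_factory):
        frames = np.zeros((10, 2, 3))
        frames[:, 1] = [0.5, 0, 0]
        frames[1::2, 1] = [0.1, 0, 0]  # contact in exactly 5 of 10 frames
        rs = RegionSet({"a": frozenset({1}), "b": frozenset({2})})
        frac, _ = contact_probability(bead_trajectory_factory(frames),
                                      rs, "a", "b")
        assert frac == 0.5

    def test_cutoff_is_strict_inequality(self, bead_trajectory_factory):
        frames = np.zeros((2, 2, 3))
        frames[:, 1] = [0.24, 0, 0]  # exactly at the cutoff: no contact
        rs = RegionSet({"a": frozenset({1}), "b": frozenset({2})})
        frac, _ = contact_probability(bead_trajectory_factory(frames),
                                      rs, "a", "b", cutoff=0.24)
        assert frac == 0.0
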