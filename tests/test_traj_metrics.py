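"""Superposition, RMSD/RMSF estimators and the difference-RMSF pipeline."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rigidiscope import (
    Trajectory,
    average_over_chains,
    delta_rmsf,
    kabsch_superpose,
    make_reference_structure,
    rmsd_series,
    rmsf_per_residue,
)


def _rigidly_moved(frame, rng):
    rot = Rotation.random(rng=rng)
    trans = rng.normal(0, 10, 3)
    return frame.with_coords(frame.coords @ rot.as_matrix().T + trans)


class TestKabsch:
    def test_self_superposition_zero(self, ref_tetramer):
        _, rmsd = kabsch_superpose(ref_tetramer, ref_tetramer)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_removed(self, ref_tetramer):
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = ref_tetramer.with_coords(
            ref_tetramer.coords @ rot.as_matrix().T + np.array([5.0, 5.0, 5.0])
        )
        fitted, rmsd = kabsch_superpose(moved, ref_tetramer)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.abs(fitted.coords - ref_tetramer.coords).max() < 1e-9

    def test_matches_brute_force_rotation_grid(self, ref_monomer):
        # 4-atom toy: one atom displaced by 1 Å; oracle = dense Euler-angle
        # grid search after centroid alignment
        frame = make_reference_structure(1, 4, seed=1)
        xyz = frame.coords.copy()
        xyz[2] += np.array([1.0, 0.0, 0.0])
        mobile = frame.with_coords(xyz)
        _, rmsd = kabsch_superpose(mobile, frame, subset=None)

        mob_c = xyz - xyz.mean(axis=0)
        ref_c = frame.coords - frame.coords.mean(axis=0)

        def msd_of(euler):
            r = Rotation.from_euler("zyz", euler).as_matrix()
            d = mob_c @ r.T - ref_c
            return np.mean(np.sum(d * d, axis=1))

        # coarse grid over all orientations, then local simplex refinement
        step = np.deg2rad(15.0)
        best_msd, best_euler = np.inf, None
        for a in np.arange(0, 2 * np.pi, step):
            for b in np.arange(0, np.pi + 1e-9, step):
                for c in np.arange(0, 2 * np.pi, step):
                    m = msd_of([a, b, c])
                    if m < best_msd:
                        best_msd, best_euler = m, [a, b, c]
        from scipy.optimize import minimize

        res = minimize(msd_of, best_euler, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        oracle = np.sqrt(res.fun)
        assert rmsd == pytest.approx(oracle, abs=1e-3)

    def test_too_few_or_collinear_atoms_rejected(self, ref_monomer):
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(ref_monomer, ref_monomer, subset=[0, 1])
        line = ref_monomer.with_coords(
            np.column_stack([np.arange(12.0), np.zeros(12), np.zeros(12)])
        )
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line, subset=None)


class TestRMSDSeries:
    def test_rigid_copies_give_zero(self, ref_tetramer, rigid_rng):
        frames = [_rigidly_moved(ref_tetramer, rigid_rng) for _ in range(10)]
        series = rmsd_series(Trajectory(frames), ref_tetramer)
        assert np.abs(series).max() < 1e-9

    def test_constant_frame_constant_series(self, ref_tetramer):
        xyz = ref_tetramer.coords + np.random.default_rng(0).normal(0, 0.5, (120, 3))
        frame = ref_tetramer.with_coords(xyz)
        series = rmsd_series(Trajectory([frame] * 8), ref_tetramer)
        assert np.ptp(series) < 1e-12
        assert series[0] > 0

    def test_matches_independent_per_frame_recomputation(
        self, ref_tetramer, block_traj_factory
    ):
        traj = block_traj_factory(sigma_block=0.0, sigma_local=0.1, n_frames=500)
        series = rmsd_series(traj, ref_tetramer)

        # independent re-implementation of the same definition via the
        # closed-form Kabsch on each frame (numpy SVD, no shared code path)
        def kabsch_rmsd(p, q):
            p = p - p.mean(axis=0)
            q = q - q.mean(axis=0)
            h = p.T @ q
            u, s, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            e = np.sum(p**2) + np.sum(q**2) - 2 * (s[0] + s[1] + d * s[2])
            return np.sqrt(max(e, 0.0) / len(p))

        oracle = np.array(
            [kabsch_rmsd(xyz, ref_tetramer.coords) for xyz in traj.coords]
        )
        assert series.mean() == pytest.approx(oracle.mean(), rel=0.10)
        assert np.abs(series - oracle).max() < 1e-8

    def test_incompatible_reference_rejected(self, ref_tetramer, ref_monomer):
        traj = Trajectory([ref_tetramer] * 2)
        with pytest.raises(ValueError, match="incompatible"):
            rmsd_series(traj, ref_monomer)


class TestRMSF:
    def test_rigid_trajectory_all_zero(self, ref_tetramer, rigid_rng):
        frames = [_rigidly_moved(ref_tetramer, rigid_rng) for _ in range(6)]
        prof = rmsf_per_residue(Trajectory(frames))
        assert prof.values.max() < 1e-9

    def test_single_alternating_atom(self, ref_tetramer):
        a = 0.4
        up, down = ref_tetramer.coords.copy(), ref_tetramer.coords.copy()
        up[0, 0] += a
        down[0, 0] -= a
        traj = Trajectory(
            [ref_tetramer.with_coords(up), ref_tetramer.with_coords(down)] * 3
        )
        prof = rmsf_per_residue(traj)
        # two-point variance about the mean: fluctuation ±a along x
        assert prof.values[0] == pytest.approx(a, rel=0.05)
        assert np.median(prof.values) < 0.05 * a

    def test_isotropic_gaussian_rmsf_is_sigma_sqrt3(self, ref_tetramer,
                                                    block_traj_factory):
        sigma = 0.3
        traj = block_traj_factory(sigma_block=0.0, sigma_local=sigma,
                                  n_frames=5000, seed=17)
        prof = rmsf_per_residue(traj)
        assert prof.values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_single_frame_rejected(self, ref_tetramer):
        with pytest.raises(ValueError, match=">= 2"):
            rmsf_per_residue(Trajectory([ref_tetramer]))

    def test_invariant_under_global_rigid_motion(self, block_traj_factory):
        plain = block_traj_factory(n_frames=200, seed=23, rigid_motion=False)
        moved = block_traj_factory(n_frames=200, seed=23, rigid_motion=True)
        p1 = rmsf_per_residue(plain)
        p2 = rmsf_per_residue(moved)
        assert p1.values == pytest.approx(p2.values, abs=1e-6)


class TestChainAveraging:
    def test_identical_profiles_unchanged(self, block_traj_factory):
        prof = rmsf_per_residue(block_traj_factory(n_frames=100))
        avg = average_over_chains(prof)
        assert avg.averaged and avg.n_chains_averaged == 4
        assert len(avg.values) == 30

    def test_two_chain_mean(self):
        from rigidiscope import RMSFProfile

        prof = RMSFProfile(labels=[("A", 1), ("B", 1)], values=[1.0, 3.0])
        avg = average_over_chains(prof)
        assert avg.values[0] == pytest.approx(2.0)

    def test_residue_set_mismatch_lists_positions(self):
        from rigidiscope import RMSFProfile

        prof = RMSFProfile(labels=[("A", 1), ("A", 2), ("B", 1)],
                           values=[1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match=r"\('B', 2\)"):
            average_over_chains(prof)

    def test_averaging_reduces_sampling_variance(self, ref_tetramer):
        # empirical across 20 seeds: the chain-averaged estimate of a flat
        # ground truth scatters less than single-chain estimates
        from rigidiscope import BlockSpec, simulate_block_trajectory, uniform_blocks

        spec = BlockSpec(uniform_blocks(ref_tetramer, 4), 0.0, 0.3)
        sd_single, sd_avg = [], []
        for seed in range(20):
            traj = simulate_block_trajectory(ref_tetramer, spec, 60, seed)
            prof = rmsf_per_residue(traj)
            chain_a = [v for (c, _), v in zip(prof.labels, prof.values) if c == "A"]
            sd_single.append(np.std(chain_a))
            sd_avg.append(np.std(average_over_chains(prof).values))
        assert np.mean(sd_avg) < np.mean(sd_single)


class TestDeltaRMSF:
    def test_identical_profiles_zero(self, block_traj_factory):
        prof = average_over_chains(rmsf_per_residue(block_traj_factory(n_frames=80)))
        delta = delta_rmsf(prof, prof)
        assert np.all(delta.deltas == 0)
        assert delta.summary["fraction_negative"] == 0.0  # ties non-negative

    def test_scaled_mutant_mostly_negative(self, block_traj_factory):
        wt = block_traj_factory(scale=1.0, n_frames=2000, seed=31)
        mut = block_traj_factory(scale=0.8, n_frames=2000, seed=32)
        d = delta_rmsf(
            average_over_chains(rmsf_per_residue(mut)),
            average_over_chains(rmsf_per_residue(wt)),
        )
        assert d.summary["fraction_negative"] > 0.9

    def test_antisymmetric_under_swap(self, block_traj_factory):
        a = average_over_chains(rmsf_per_residue(block_traj_factory(seed=1, n_frames=80)))
        b = average_over_chains(rmsf_per_residue(block_traj_factory(seed=2, n_frames=80)))
        d_ab = delta_rmsf(a, b)
        d_ba = delta_rmsf(b, a)
        assert d_ab.deltas == pytest.approx(-d_ba.deltas)

    def test_requires_averaged_profiles(self, block_traj_factory):
        prof = rmsf_per_residue(block_traj_factory(n_frames=50))
        with pytest.raises(ValueError, match="averaged"):
            delta_rmsf(prof, prof)

    def test_scale_recovered_from_median_ratio(self, block_traj_factory):
        # scale-s mutant vs scale-1 WT: median(delta)/median(WT RMSF) -> s-1
        s = 0.8
        wt = block_traj_factory(scale=1.0, n_frames=2000, seed=41)
        mut = block_traj_factory(scale=s, n_frames=2000, seed=42)
        wt_prof = average_over_chains(rmsf_per_residue(wt))
        d = delta_rmsf(average_over_chains(rmsf_per_residue(mut)), wt_prof)
        ratio = np.median(d.deltas) / np.median(wt_prof.values)
        assert ratio == pytest.approx(s - 1.0, abs=0.1 * abs(s - 1.0) + 0.02)
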