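"""Trajectory reading, superposition, and conformational statistics."""

import numpy as np
import pytest

from stereoscreen import (
    Trajectory,
    com_distance_series,
    delta_d_profile,
    read_trajectory,
    residue_distance_profile,
    rmsd_series,
    rmsf_profile,
)
from stereoscreen.synthetic_data import TrajSimConfig, generate_trajectory_pair, write_trajectory_pdb
from stereoscreen.trajectory_metrics import (
    ResidueDistanceProfile,
    TrajectoryFormatError,
    kabsch_superpose,
)


def _toy_traj(coords, is_ligand=None, names=None, time_step=1.0):
    coords = np.asarray(coords, float)
    n = coords.shape[1]
    return Trajectory(
        coords=coords,
        resindex=np.arange(1, n + 1),
        resnames=np.array(["LIG" if (is_ligand is not None and is_ligand[i]) else "ALA"
                           for i in range(n)], dtype=object),
        atom_names=np.array(names or ["CA"] * n, dtype=object),
        masses=np.full(n, 12.011),
        is_ligand=np.asarray(is_ligand if is_ligand is not None else [False] * n, bool),
        time_step=time_step,
    )


def _rigid(coords, seed=0):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.uniform(-10, 10, 3)
    return coords @ rot.T + shift


class TestReadTrajectory:
    def test_two_frame_three_atom_pdb(self, tmp_path):
        path = tmp_path / "t.pdb"
        traj = _toy_traj(np.arange(18, dtype=float).reshape(2, 3, 3))
        write_trajectory_pdb(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 2
        assert back.n_atoms == 3
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)

    def test_missing_atom_names_the_frame(self, tmp_path):
        path = tmp_path / "bad.pdb"
        traj = _toy_traj(np.zeros((3, 4, 3)))
        write_trajectory_pdb(traj, path)
        lines = [l for l in path.read_text().splitlines()]
        # drop one ATOM line from the second MODEL block
        second_model = [i for i, l in enumerate(lines) if l.startswith("MODEL")][1]
        del lines[second_model + 1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrajectoryFormatError, match="frame 2"):
            read_trajectory(path)

    def test_zero_frames_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(TrajectoryFormatError, match="no frames"):
            read_trajectory(path)

    def test_ligand_flagged_by_residue_name(self, tmp_path):
        cfg = TrajSimConfig(n_residues=10, n_frames=3, fluctuation_sd=0.0, seed=1)
        bound, _ = generate_trajectory_pair(cfg)
        path = tmp_path / "b.pdb"
        write_trajectory_pdb(bound, path)
        back = read_trajectory(path, ligand_selector="LIG")
        assert back.is_ligand.sum() == 1
        assert back.resnames[back.is_ligand][0] == "LIG"

    def test_xyz_round_trip_one_residue_per_atom(self, tmp_path):
        path = tmp_path / "t.xyz"
        coords = np.arange(18, dtype=float).reshape(2, 3, 3)
        with open(path, "w") as fh:
            for frame in coords:
                fh.write("3\nframe\n")
                for name, (x, y, z) in zip(["C", "C", "O"], frame):
                    fh.write(f"{name} {x:.3f} {y:.3f} {z:.3f}\n")
        back = read_trajectory(path, format="xyz", ligand_selector="O")
        assert back.n_frames == 2
        assert list(back.resindex) == [1, 2, 3]
        assert back.is_ligand.tolist() == [False, False, True]
        np.testing.assert_allclose(back.coords, coords, atol=1e-3)


class TestSuperposition:
    def test_recovers_rigid_motion_exactly(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(40, 3))
        moved = _rigid(ref, seed=4)
        back = kabsch_superpose(moved, ref)
        np.testing.assert_allclose(back, ref, atol=1e-9)

    def test_matches_mdanalysis_rmsd(self):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        rng = np.random.default_rng(8)
        ref = rng.normal(size=(30, 3))
        mob = ref + rng.normal(0, 0.5, size=(30, 3))
        ours = kabsch_superpose(mob, ref)
        our_rmsd = np.sqrt(((ours - ref) ** 2).sum(axis=1).mean())
        theirs = mda_rmsd(mob, ref, superposition=True)
        assert our_rmsd == pytest.approx(float(theirs), rel=1e-8)


class TestRmsd:
    def test_identical_frames_all_zero(self):
        traj = _toy_traj(np.tile(np.random.default_rng(0).normal(size=(5, 3)), (4, 1, 1)))
        np.testing.assert_allclose(rmsd_series(traj).rmsd, 0.0, atol=1e-12)

    def test_rigid_motion_invariance(self):
        base = np.random.default_rng(1).normal(size=(6, 3))
        traj = _toy_traj(np.stack([base, _rigid(base, seed=2)]))
        assert rmsd_series(traj, reference=0, superpose=True).rmsd[1] < 1e-9

    def test_hand_computed_unsuperposed_value(self):
        base = np.zeros((2, 3))
        base[1, 0] = 5.0
        frame2 = base + np.array([[1.0, 0, 0], [0, 1.0, 0]])
        traj = _toy_traj(np.stack([base, frame2]))
        rs = rmsd_series(traj, selection="all", superpose=False)
        assert rs.rmsd[1] == pytest.approx(1.0)  # √((1+1)/2)

    def test_superposed_never_exceeds_unsuperposed(self):
        cfg = TrajSimConfig(n_residues=20, n_frames=50, fluctuation_sd=0.5, seed=6)
        _, traj = generate_trajectory_pair(cfg)
        with_sup = rmsd_series(traj, superpose=True).rmsd
        without = rmsd_series(traj, superpose=False).rmsd
        assert np.all(with_sup <= without + 1e-9)

    def test_bad_reference_rejected(self):
        traj = _toy_traj(np.zeros((2, 3, 3)))
        with pytest.raises(IndexError):
            rmsd_series(traj, reference=5)


class TestRmsf:
    def test_static_trajectory_zero(self):
        traj = _toy_traj(np.tile(np.random.default_rng(2).normal(size=(8, 3)), (10, 1, 1)))
        np.testing.assert_allclose(rmsf_profile(traj).rmsf, 0.0, atol=1e-12)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self):
        sigma = 0.2
        cfg = TrajSimConfig(n_residues=50, n_frames=5000, fluctuation_sd=sigma, seed=3)
        _, traj = generate_trajectory_pair(cfg)
        rf = rmsf_profile(traj)
        np.testing.assert_allclose(rf.rmsf, sigma * np.sqrt(3), rtol=0.05)

    def test_planted_amplitude_ordering(self):
        sd = np.full(30, 0.1)
        sd[9:20] = 0.2  # residues 10–20 at double amplitude
        cfg = TrajSimConfig(n_residues=30, n_frames=2000, fluctuation_sd=sd, seed=4)
        _, traj = generate_trajectory_pair(cfg)
        rf = rmsf_profile(traj)
        top11 = set(rf.residue_ids[np.argsort(rf.rmsf)[-11:]])
        assert top11 == set(range(10, 21))

    def test_invariant_under_global_rigid_motion(self):
        cfg = TrajSimConfig(n_residues=15, n_frames=200, fluctuation_sd=0.3, seed=5)
        _, traj = generate_trajectory_pair(cfg)
        moved = Trajectory(
            np.stack([_rigid(f, seed=9) for f in traj.coords]),
            traj.resindex, traj.resnames, traj.atom_names,
            traj.masses, traj.is_ligand, traj.time_step,
        )
        np.testing.assert_allclose(
            rmsf_profile(moved).rmsf, rmsf_profile(traj).rmsf, atol=1e-6
        )


class TestComDistance:
    def test_ligand_at_protein_center_zero(self):
        prot = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        frames = np.tile(np.vstack([prot, [[0.0, 0, 0]]]), (3, 1, 1))
        traj = _toy_traj(frames, is_ligand=[False] * 4 + [True])
        np.testing.assert_allclose(com_distance_series(traj).distances, 0.0, atol=1e-12)

    def test_three_four_five_offset(self):
        prot = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        frames = np.tile(np.vstack([prot, [[3.0, 4.0, 0]]]), (5, 1, 1))
        traj = _toy_traj(frames, is_ligand=[False, False, True])
        np.testing.assert_allclose(com_distance_series(traj).distances, 5.0, atol=1e-12)

    def test_drift_slope_recovered(self):
        cfg = TrajSimConfig(
            n_residues=30, n_frames=300, fluctuation_sd=0.1, ligand_drift=0.05, seed=7
        )
        bound, _ = generate_trajectory_pair(cfg)
        assert com_distance_series(bound).slope == pytest.approx(0.05, rel=0.10)

    def test_no_ligand_rejected(self):
        traj = _toy_traj(np.zeros((2, 3, 3)))
        with pytest.raises(ValueError, match="ligand"):
            com_distance_series(traj)


class TestResidueDistanceProfile:
    def test_single_frame_instantaneous(self):
        coords = np.array([[[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]]])
        traj = _toy_traj(coords)
        prof = residue_distance_profile(traj, window=None)
        np.testing.assert_allclose(prof.d, [5.0, 0.0, 5.0], atol=1e-12)

    def test_full_window_is_weighted_mean_of_halves(self):
        cfg = TrajSimConfig(n_residues=10, n_frames=40, fluctuation_sd=0.2, seed=8)
        _, traj = generate_trajectory_pair(cfg)
        full = residue_distance_profile(traj, window=(0, 40)).d
        first = residue_distance_profile(traj, window=(0, 20)).d
        second = residue_distance_profile(traj, window=(20, 40)).d
        np.testing.assert_allclose(full, 0.5 * (first + second), atol=1e-10)


class TestDeltaD:
    def test_identical_profiles_all_unchanged(self):
        cfg = TrajSimConfig(n_residues=12, n_frames=10, fluctuation_sd=0.0, seed=1)
        _, free = generate_trajectory_pair(cfg)
        prof = residue_distance_profile(free, window=None)
        dd = delta_d_profile(prof, prof)
        np.testing.assert_allclose(dd.delta_d, 0.0)
        assert set(dd.classes) == {"unchanged"}

    def test_classification_thresholds(self):
        ids = np.array([1, 2, 3])
        bound = ResidueDistanceProfile(ids, np.array([12.5, 10.0, 7.5]), "ligand-bound")
        free = ResidueDistanceProfile(ids, np.array([10.0, 10.0, 10.0]), "ligand-free")
        dd = delta_d_profile(bound, free, threshold=2.0)
        np.testing.assert_allclose(dd.delta_d, [2.5, 0.0, -2.5])
        assert list(dd.classes) == ["further", "unchanged", "closer"]

    def test_exactly_at_threshold_is_unchanged(self):
        ids = np.array([1])
        bound = ResidueDistanceProfile(ids, np.array([12.0]), "ligand-bound")
        free = ResidueDistanceProfile(ids, np.array([10.0]), "ligand-free")
        dd = delta_d_profile(bound, free, threshold=2.0)
        assert list(dd.classes) == ["unchanged"]  # strict inequality

    def test_antisymmetry(self):
        cfg = TrajSimConfig(
            n_residues=20, n_frames=50, fluctuation_sd=0.3,
            planted_shift={5: 3.0}, seed=2,
        )
        bound, free = generate_trajectory_pair(cfg)
        pb = residue_distance_profile(bound)
        pf = residue_distance_profile(free)
        fwd = delta_d_profile(pb, pf)
        rev = delta_d_profile(pf, pb)
        np.testing.assert_allclose(fwd.delta_d, -rev.delta_d, atol=1e-12)
        assert fwd.residues_classified("further") == rev.residues_classified("closer")

    def test_planted_shift_classified_with_zero_false_positives(self):
        cfg = TrajSimConfig(
            n_residues=50, n_frames=1000, fluctuation_sd=0.2,
            planted_shift={15: 3.0}, seed=7,
        )
        bound, free = generate_trajectory_pair(cfg)
        dd = delta_d_profile(
            residue_distance_profile(bound, state="ligand-bound"),
            residue_distance_profile(free, state="ligand-free"),
        )
        assert dd.residues_classified("further") == [15]
        assert dd.residues_classified("closer") == []

    def test_residue_mismatch_rejected(self):
        bound = ResidueDistanceProfile(np.array([1, 2]), np.array([1.0, 2.0]), "ligand-bound")
        free = ResidueDistanceProfile(np.array([1, 3]), np.array([1.0, 2.0]), "ligand-free")
        with pytest.raises(ValueError, match="residue sets differ"):
            delta_d_profile(bound, free)

    def test_invariant_under_global_rigid_motion(self):
        cfg = TrajSimConfig(
            n_residues=15, n_frames=100, fluctuation_sd=0.2,
            planted_shift={4: 2.5}, seed=12,
        )
        bound, free = generate_trajectory_pair(cfg)
        moved = Trajectory(
            np.stack([_rigid(f, seed=13) for f in bound.coords]),
            bound.resindex, bound.resnames, bound.atom_names,
            bound.masses, bound.is_ligand, bound.time_step,
        )
        dd_a = delta_d_profile(residue_distance_profile(bound), residue_distance_profile(free))
        dd_b = delta_d_profile(residue_distance_profile(moved), residue_distance_profile(free))
        np.testing.assert_allclose(dd_a.delta_d, dd_b.delta_d, atol=1e-9)
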