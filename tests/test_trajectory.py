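"""Superposition, RMSD/RMSF/Rg series, and Shrake-Rupley SASA."""

import numpy as np
import pytest

from thermotriage import synthetic
from thermotriage.structure import Atom, Residue, Structure, read_structure
from thermotriage.synthetic import _random_rotation
from thermotriage.trajectory import (
    DegenerateGeometryError,
    Trajectory,
    coordinate_rmsd,
    gyration_series,
    kabsch_superpose,
    radius_of_gyration,
    read_trajectory,
    region_stats,
    rmsd_series,
    rmsf_per_residue,
    sasa_series,
    shrake_rupley_sasa,
    write_trajectory,
)


def atom_cloud_structure(coords, element="C"):
    """One residue per atom, single-atom residues."""
    residues = []
    for i, xyz in enumerate(coords, start=1):
        residues.append(Residue("A", i, "", "GLY", [
            Atom(serial=i, name="CA", element=element,
                 residue_ref=("A", i, ""), coords=np.asarray(xyz, float))]))
    return Structure(id="cloud", residues=residues)


class TestKabsch:
    def test_rigid_copy_superposes_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 3))
        rot = _random_rotation(rng)
        moved = pts @ rot.T + np.array([4.0, -2.0, 7.0])
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd < 1e-6

    def test_displaced_point_closed_form(self):
        # one of four pre-aligned points displaced by 1 A:
        # rmsd = sqrt(1/4) = 0.5 on the aligned coordinates
        ref = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]], float)
        mobile = ref.copy()
        mobile[0] += [1.0, 0.0, 0.0]
        assert coordinate_rmsd(mobile, ref) == pytest.approx(0.5)
        # an optimal rigid fit can only do at least as well
        _, _, fitted = kabsch_superpose(mobile, ref)
        assert fitted <= 0.5 + 1e-12

    def test_optimality_against_random_rotations(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        _, _, best = kabsch_superpose(a, b)
        bc = b - b.mean(axis=0)
        for _ in range(100):
            rot = _random_rotation(rng)
            trial = (a - a.mean(axis=0)) @ rot.T
            assert best <= coordinate_rmsd(trial, bc) + 1e-12

    def test_agrees_with_scipy_alignment(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        rot, t, rmsd = kabsch_superpose(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        _, scipy_rssd = Rotation.align_vectors(bc, ac)
        assert rmsd == pytest.approx(scipy_rssd / np.sqrt(len(a)), rel=1e-9)

    def test_collinear_points_are_degenerate(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    def test_point_count_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


@pytest.fixture(scope="module")
def ref_structure():
    pdb, _ = synthetic.make_structure(seed=30, n_residues=24)
    return read_structure(pdb)


class TestRmsdSeries:
    def test_identical_frames_all_zero(self, ref_structure):
        traj, _ = synthetic.make_trajectory(ref_structure, seed=0, n_frames=5,
                                            sigma_bg=0.0)
        assert rmsd_series(traj).values.max() < 1e-9

    def test_rigid_motion_removed(self, ref_structure):
        traj, _ = synthetic.make_trajectory(ref_structure, seed=1, n_frames=5,
                                            sigma_bg=0.0, rigid_motion=True)
        assert rmsd_series(traj).values.max() < 1e-9

    def test_global_rigid_motion_invariance(self, ref_structure):
        traj, _ = synthetic.make_trajectory(ref_structure, seed=2, n_frames=6,
                                            sigma_bg=0.3)
        base = rmsd_series(traj).values
        rng = np.random.default_rng(9)
        rot = _random_rotation(rng)
        moved = Trajectory(topology=traj.topology,
                           coords=traj.coords @ rot.T + np.array([3.0, 1.0, -2.0]),
                           times=traj.times)
        np.testing.assert_allclose(rmsd_series(moved).values, base, atol=1e-9)

    def test_gaussian_jitter_matches_analytic_expectation(self, ref_structure):
        # vs the unperturbed reference, E[rmsd] ~ sigma * sqrt(3)
        sigma = 0.5
        traj, _ = synthetic.make_trajectory(ref_structure, seed=3, n_frames=2000,
                                            sigma_bg=sigma)
        series = rmsd_series(traj, ref=ref_structure, selection="heavy")
        assert series.values.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)


class TestRmsf:
    def test_static_trajectory_zero(self, ref_structure):
        traj, _ = synthetic.make_trajectory(ref_structure, seed=4, n_frames=4,
                                            sigma_bg=0.0)
        profile = rmsf_per_residue(traj)
        assert max(profile.values.values()) < 1e-9

    def test_planted_sinusoid_amplitude(self):
        # residue 1 oscillates with amplitude A along x; the rest are a
        # static 3D scaffold: RMSF(residue 1) = A / sqrt(2)
        # scaffold large enough that the fit cannot absorb the oscillation
        rng = np.random.default_rng(5)
        base = np.vstack([[0.0, 0.0, 0.0], rng.normal(0, 6, size=(149, 3))])
        s = atom_cloud_structure(base)
        amp = 1.2
        n_frames = 1200
        phases = 2 * np.pi * np.arange(n_frames) / n_frames * 7  # whole periods
        coords = np.repeat(base[None, :, :], n_frames, axis=0)
        coords[:, 0, 0] += amp * np.sin(phases)
        traj = Trajectory(topology=s, coords=coords,
                          times=np.arange(n_frames, dtype=float))
        profile = rmsf_per_residue(traj, selection="heavy")
        assert profile.values[("A", 1, "")] == pytest.approx(amp / np.sqrt(2), rel=0.02)

    def test_planted_flexible_regions_ordering(self, ref_structure):
        # two elevated regions over background; region means must exceed
        # background and order by planted amplitude
        traj, truth = synthetic.make_trajectory(
            ref_structure, seed=6, n_frames=600, sigma_bg=0.05,
            region_sigmas={(5, 8): 0.3, (15, 20): 0.5})
        profile = rmsf_per_residue(traj)
        stats = region_stats(profile, {"I": (5, 8), "II": (15, 20), "bg": (21, 24)})
        assert stats["bg"].mean < stats["I"].mean < stats["II"].mean

    def test_duplicated_trajectory_same_rmsf(self, ref_structure):
        traj, _ = synthetic.make_trajectory(ref_structure, seed=7, n_frames=40,
                                            sigma_bg=0.2)
        doubled = Trajectory(
            topology=traj.topology,
            coords=np.concatenate([traj.coords, traj.coords]),
            times=np.arange(2 * traj.n_frames, dtype=float))
        a = rmsf_per_residue(traj)
        b = rmsf_per_residue(doubled)
        for key in a.values:
            assert b.values[key] == pytest.approx(a.values[key], rel=1e-6)

    def test_too_few_frames(self, ref_structure):
        traj, _ = synthetic.make_trajectory(ref_structure, seed=8, n_frames=2,
                                            sigma_bg=0.1)
        with pytest.raises(ValueError):
            rmsf_per_residue(traj, equilibration_skip=1)


class TestGyration:
    def test_unit_cube_corners(self):
        corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                            for sz in (-1, 1)], float)
        assert radius_of_gyration(corners) == pytest.approx(np.sqrt(3))
        s = atom_cloud_structure(corners)
        traj = Trajectory(topology=s, coords=corners[None], times=np.array([0.0]))
        series = gyration_series(traj, mass_weighted=False)
        assert series.values[0] == pytest.approx(np.sqrt(3) / 10.0)  # nm
        assert series.units == "nm"

    def test_single_atom_zero(self):
        assert radius_of_gyration(np.array([[5.0, 5.0, 5.0]])) == 0.0

    def test_matches_direct_formula_with_masses(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(30, 3))
        masses = rng.uniform(1, 16, size=30)
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        direct = np.sqrt((masses * ((coords - com) ** 2).sum(1)).sum() / masses.sum())
        assert radius_of_gyration(coords, masses) == pytest.approx(direct)

    def test_invariance_and_scaling(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(20, 3))
        rot = _random_rotation(rng)
        rg = radius_of_gyration(coords)
        assert radius_of_gyration(coords @ rot.T + 7.0) == pytest.approx(rg)
        assert radius_of_gyration(coords * 3.0) == pytest.approx(3.0 * rg)


class TestSasa:
    LONE = 4 * np.pi * (1.7 + 1.4) ** 2 / 100.0  # nm^2, carbon + water probe

    def test_lone_atom_analytic_sphere(self):
        s = atom_cloud_structure([[0.0, 0.0, 0.0]])
        result = shrake_rupley_sasa(s)
        assert result.total == pytest.approx(self.LONE, rel=0.01)

    def test_distant_atoms_additive(self):
        s = atom_cloud_structure([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        result = shrake_rupley_sasa(s)
        assert result.total == pytest.approx(2 * self.LONE, rel=0.01)

    def test_two_overlapping_spheres_analytic(self):
        # equal expanded radii R at separation d: each sphere loses a cap of
        # area 2 pi R (R - d/2)
        d = 3.0
        R = 1.7 + 1.4
        s = atom_cloud_structure([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        exposed_one = 4 * np.pi * R ** 2 - 2 * np.pi * R * (R - d / 2)
        expected = 2 * exposed_one / 100.0
        result = shrake_rupley_sasa(s, n_points=4000)
        assert result.total == pytest.approx(expected, rel=0.02)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(12)
        s = atom_cloud_structure(rng.normal(0, 3, size=(15, 3)))
        coarse = shrake_rupley_sasa(s, n_points=960).total
        fine = shrake_rupley_sasa(s, n_points=1920).total
        assert abs(fine - coarse) / fine < 0.005
        # never exceeds the sum of isolated-atom areas
        assert 0 < coarse <= 15 * self.LONE * 1.01

    def test_matches_independent_reference_implementation(self):
        mdtraj = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(13)
        coords = rng.normal(0, 3, size=(12, 3))
        s = atom_cloud_structure(coords)
        ours = shrake_rupley_sasa(s, probe=1.4, n_points=960).total

        top = mdtraj.Topology()
        chain = top.add_chain()
        for i in range(len(coords)):
            res = top.add_residue("GLY", chain)
            top.add_atom("CA", mdtraj.element.carbon, res)
        mtraj = mdtraj.Trajectory(coords[None] / 10.0, top)  # nm
        theirs = mdtraj.shrake_rupley(
            mtraj, probe_radius=0.14, n_sphere_points=960,
            change_radii={"C": 0.17})[0].sum()
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_unknown_element_warns_and_uses_fallback(self):
        s = atom_cloud_structure([[0.0, 0.0, 0.0]], element="XX")
        with pytest.warns(UserWarning, match="vdW"):
            result = shrake_rupley_sasa(s)
        assert result.total > 0


class TestRegionStats:
    def test_uniform_region_mean(self):
        from thermotriage.trajectory import RMSFProfile

        profile = RMSFProfile(values={("A", i, ""): 1.0 for i in range(1, 11)})
        stats = region_stats(profile, {"R": (3, 7)})
        assert stats["R"].mean == 1.0 and stats["R"].max == 1.0

    def test_delta_between_profiles(self):
        from thermotriage.trajectory import RMSFProfile

        wt = RMSFProfile(values={("A", i, ""): 2.0 for i in range(1, 11)})
        mu = RMSFProfile(values={("A", i, ""): 0.5 for i in range(1, 11)})
        stats = region_stats(wt, {"I": (1, 5), "II": (6, 10)}, other=mu)
        assert stats["I"].delta_mean == pytest.approx(-1.5)
        assert stats["II"].delta_mean == pytest.approx(-1.5)

    def test_region_outside_coverage_is_error(self):
        from thermotriage.trajectory import RMSFProfile

        profile = RMSFProfile(values={("A", 1, ""): 1.0})
        with pytest.raises(ValueError, match="region"):
            region_stats(profile, {"X": (50, 60)})


class TestTrajectoryIO:
    def test_multi_model_roundtrip(self, ref_structure):
        traj, _ = synthetic.make_trajectory(ref_structure, seed=14, n_frames=4,
                                            sigma_bg=0.2)
        text = write_trajectory(traj)
        back = read_trajectory(text)
        assert back.n_frames == 4
        assert back.topology.n_atoms == traj.topology.n_atoms
        np.testing.assert_allclose(back.coords, traj.coords, atol=1.5e-3)

    def test_mismatched_model_sizes_rejected(self):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n")
        with pytest.raises(Exception):
            read_trajectory(text)
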