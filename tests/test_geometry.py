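"""Superposition, RMSF, SASA and secondary-structure checks."""

import numpy as np
import pytest

from mdcompare import geometry
from mdcompare.geometry import (DegenerateSelectionError, FlexibilityProfile,
                                assign_ss, flag_flexible_regions, kabsch_fit,
                                rmsd_series, rmsf_profile, shrake_rupley_sasa,
                                ss_fractions)
from mdcompare.model_io import Trajectory
from mdcompare.synthetic_data import build_toy_topology, ideal_helix_backbone

from conftest import make_trajectory, random_rotation


class TestKabsch:
    POINTS = np.array([[0.0, 0, 0], [3, 0, 0], [0, 2, 0], [1, 1, 4]])

    def test_identity_on_equal_sets(self):
        r = kabsch_fit(self.POINTS, self.POINTS)
        assert r.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(r.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered_exactly(self):
        rot = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about z
        moved = self.POINTS @ rot.T + np.array([5.0, -2.0, 7.0])
        r = kabsch_fit(moved, self.POINTS)
        assert r.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_rotation_grid_search_oracle(self):
        """Optimal RMSD equals a coarse-to-fine rotation search on 4 points."""
        from conftest import grid_search_min_rmsd

        rng = np.random.default_rng(42)
        perturbed = self.POINTS + rng.normal(0, 0.4, self.POINTS.shape)
        ours = kabsch_fit(perturbed, self.POINTS).rmsd
        best = grid_search_min_rmsd(perturbed, self.POINTS, rng)
        assert ours <= best + 1e-12
        assert ours == pytest.approx(best, rel=1e-3)

    def test_degenerate_selection_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateSelectionError):
            kabsch_fit(line, line + 1.0)

    def test_rotation_is_orthonormal(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(6, 3))
        r = kabsch_fit(m, rng.normal(size=(6, 3)))
        assert np.allclose(r.rotation @ r.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(r.rotation) == pytest.approx(1.0, abs=1e-8)


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self, toy_complex):
        top, ref = toy_complex
        traj = make_trajectory(top, np.repeat(ref[None], 5, axis=0))
        assert np.allclose(rmsd_series(traj, ref), 0.0, atol=1e-10)

    def test_rigid_motions_are_zero(self, toy_complex):
        top, ref = toy_complex
        rng = np.random.default_rng(0)
        frames = np.stack([ref @ random_rotation(rng).T + rng.normal(size=3)
                           for _ in range(4)])
        traj = make_trajectory(top, frames)
        assert np.allclose(rmsd_series(traj, ref), 0.0, atol=1e-8)

    def test_planted_ligand_displacement(self, toy_complex):
        """Ligand RMSD after exact backbone fit equals the planted shift."""
        top, ref = toy_complex
        backbone = top.atom_indices(chain_id="A")
        ligand = top.atom_indices(chain_id="B")
        d = 2.5
        frame = ref.copy()
        frame[ligand] += np.array([0.0, 0.0, d])
        traj = make_trajectory(top, frame[None])
        series = rmsd_series(traj, ref, fit_selection=backbone,
                             measure_selection=ligand)
        assert series[0] == pytest.approx(d, abs=1e-10)

    def test_empty_selection_rejected(self, toy_complex):
        top, ref = toy_complex
        traj = make_trajectory(top, ref[None])
        with pytest.raises(ValueError):
            rmsd_series(traj, ref, fit_selection=np.array([], dtype=int))


class TestRmsf:
    def test_static_trajectory_zero(self, toy_complex):
        top, ref = toy_complex
        traj = make_trajectory(top, np.repeat(ref[None], 6, axis=0))
        prof = rmsf_profile(traj, ref)
        assert np.allclose(prof.rmsf, 0.0, atol=1e-10)

    def test_isotropic_jitter_matches_sqrt3_sigma(self, toy_complex):
        """sigma=0.5 A per axis over 1e4 frames -> RMSF = sqrt(3)*sigma +/-2%."""
        top, ref = toy_complex
        rng = np.random.default_rng(12)
        sigma = 0.5
        frames = ref[None] + rng.normal(0, sigma, size=(10_000,) + ref.shape)
        traj = make_trajectory(top, frames)
        prof = rmsf_profile(traj, ref, prefit=False)
        expected = np.sqrt(3) * sigma
        assert np.all(np.abs(prof.rmsf - expected) / expected < 0.02)

    def test_matches_bruteforce_per_frame_oracle(self, toy_complex):
        """Two planted amplitude groups recovered; equals direct recomputation."""
        top, ref = toy_complex
        rng = np.random.default_rng(4)
        n_res = top.n_residues
        sig = np.where(np.arange(n_res) < n_res // 2, 0.2, 0.9)
        frames = np.repeat(ref[None], 400, axis=0)
        for a in top.atoms:
            frames[:, a.index, :] += rng.normal(
                0, sig[a.residue_index], size=(400, 3))
        traj = make_trajectory(top, frames)
        prof = rmsf_profile(traj, ref, prefit=False)

        # brute force, residue by residue
        for k, rid in enumerate(prof.residue_indices):
            ca = int(top.atom_indices(residue_index=int(rid), name="CA")[0])
            expected = np.sqrt(np.mean(
                np.sum((frames[:, ca, :] - ref[ca]) ** 2, axis=1)))
            assert prof.rmsf[k] == pytest.approx(expected, abs=1e-12)
        low = prof.rmsf[np.array(prof.residue_indices) < n_res // 2]
        high = prof.rmsf[np.array(prof.residue_indices) >= n_res // 2]
        assert low.max() < high.min()

    def test_invariant_under_global_rigid_motion(self, toy_complex):
        top, ref = toy_complex
        rng = np.random.default_rng(9)
        frames = ref[None] + rng.normal(0, 0.3, size=(50,) + ref.shape)
        traj = make_trajectory(top, frames)
        base = rmsf_profile(traj, ref).rmsf

        rot = random_rotation(rng)
        shift = np.array([3.0, -8.0, 2.0])
        moved = make_trajectory(top, frames @ rot.T + shift)
        ref_moved = ref @ rot.T + shift
        assert np.allclose(rmsf_profile(moved, ref_moved).rmsf, base, atol=1e-6)


class TestFlagFlexibleRegions:
    def _profile(self, values):
        n = len(values)
        return FlexibilityProfile(residue_indices=np.arange(n),
                                  labels=[f"A:ALA {i + 1}" for i in range(n)],
                                  rmsf=np.asarray(values, dtype=float))

    def test_identical_profiles_no_flags(self):
        p = self._profile([1.0, 2.0, 3.0])
        out, regions = flag_flexible_regions(p, p)
        assert not out.flags.any() and regions == []

    def test_threshold_is_inclusive_at_1A_ordered(self):
        a = self._profile([1.0, 1.0])
        b = self._profile([2.0, 1.5])
        out, regions = flag_flexible_regions(a, b)
        assert list(out.flags) == [True, False]
        assert regions == [(0, 0, 1.0)]

    def test_disordered_uses_3A_threshold(self):
        a = self._profile([1.0, 1.0])
        b = self._profile([3.5, 4.5])
        out, _ = flag_flexible_regions(a, b, disordered_mask=[True, True])
        assert list(out.flags) == [False, True]

    def test_contiguous_regions_are_maximal_runs(self):
        a = self._profile([0.0] * 6)
        b = self._profile([1.5, 2.0, 0.0, 1.2, 1.1, 0.0])
        _, regions = flag_flexible_regions(a, b)
        assert regions == [(0, 1, 2.0), (3, 4, 1.2)]

    def test_residue_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            flag_flexible_regions(self._profile([1.0]), self._profile([1.0, 2.0]))


class TestSasa:
    def test_single_atom_closed_form(self):
        """Isolated r=1.9 atom, probe 1.4 -> 4*pi*(3.3)^2 ~ 136.85 A^2."""
        res = shrake_rupley_sasa(np.zeros((1, 3)), radii=np.array([1.9]))
        assert res.total_A2 == pytest.approx(4 * np.pi * 3.3**2, rel=0.005)

    def test_coincident_atoms_bury_fully(self):
        res = shrake_rupley_sasa(np.zeros((2, 3)), radii=np.array([1.7, 1.7]))
        one = shrake_rupley_sasa(np.zeros((1, 3)), radii=np.array([1.7]))
        assert res.total_A2 == pytest.approx(one.total_A2, rel=1e-9)

    def test_distant_atoms_add(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        res = shrake_rupley_sasa(coords, radii=np.array([1.7, 1.52]))
        singles = sum(
            shrake_rupley_sasa(np.zeros((1, 3)), radii=np.array([r])).total_A2
            for r in (1.7, 1.52))
        assert res.total_A2 == pytest.approx(singles, rel=1e-9)

    def test_monotone_decrease_on_approach(self):
        prev = np.inf
        for d in (8.0, 6.0, 4.0, 3.0, 2.0, 1.0):
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            total = shrake_rupley_sasa(coords, radii=np.array([1.7, 1.7])).total_A2
            assert total <= prev + 1e-9
            prev = total

    def test_unknown_element_rejected(self, toy_complex):
        top, ref = toy_complex
        top2, _ = build_toy_topology(
            __import__("mdcompare.synthetic_data", fromlist=["SyntheticSpec"])
            .SyntheticSpec(residues_per_chain=4, frames_per_replicate=1))
        top2.atoms[0].element = "XX"
        with pytest.raises(ValueError, match="radius"):
            shrake_rupley_sasa(ref[: top2.n_atoms], topology=top2)

    def test_agrees_with_biotite_on_toy_complex(self, toy_complex):
        """Independent Shrake-Rupley implementation as cross-check."""
        import biotite.structure as struc

        top, ref = toy_complex
        ours = shrake_rupley_sasa(ref, topology=top, n_points=960)

        arr = struc.AtomArray(top.n_atoms)
        arr.coord = ref.astype(np.float32)
        arr.chain_id = np.array([a.chain_id for a in top.atoms])
        arr.res_id = np.array([a.res_seq for a in top.atoms])
        arr.res_name = np.array([a.residue_name for a in top.atoms])
        arr.atom_name = np.array([a.name for a in top.atoms])
        arr.element = np.array([a.element for a in top.atoms])
        radii = np.array([geometry.DEFAULT_RADII[a.element] for a in top.atoms])
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                            vdw_radii=radii)
        assert ours.total_A2 == pytest.approx(float(np.nansum(theirs)), rel=0.01)

    def test_residue_sums_match_atoms(self, toy_complex):
        top, ref = toy_complex
        res = shrake_rupley_sasa(ref, topology=top, n_points=120)
        assert sum(res.residue_sasa.values()) == pytest.approx(res.total_A2,
                                                               abs=1e-9)
        assert res.total_nm2 == pytest.approx(res.total_A2 / 100.0)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_H(self, toy_complex):
        top, ref = toy_complex
        codes = assign_ss(ref, top)
        # two chains of 10; interiors of each
        assert all(c == "H" for c in codes[2:8])
        assert all(c == "H" for c in codes[12:18])

    def test_extended_chain_has_no_E(self):
        from mdcompare.model_io import Atom, Topology

        # fully extended single strand: no partner -> no bridges
        n = 8
        atoms, coords, bonds = [], [], set()
        for i in range(n):
            x = 3.5 * i
            for j, (name, pos) in enumerate([
                    ("N", [x, 0.0, 0.0]), ("H", [x, -1.0, 0.0]),
                    ("CA", [x + 1.2, 0.8, 0.0]), ("C", [x + 2.4, 0.0, 0.0]),
                    ("O", [x + 2.4, -1.2, 0.0])]):
                atoms.append(Atom(len(atoms), name, name[0], i, "GLY", "A",
                                  res_seq=i + 1))
                coords.append(pos)
            base = 5 * i
            bonds.update({(base, base + 1), (base, base + 2),
                          (base + 2, base + 3), (base + 3, base + 4)})
        top = Topology(atoms=atoms, bonds=bonds)
        codes = assign_ss(np.array(coords), top)
        assert "E" not in codes and "H" not in codes

    def test_antiparallel_strands_assign_E(self):
        """Two ideal antiparallel strands H-bond into paired E residues."""
        from mdcompare.model_io import Atom, Topology

        atoms, coords, bonds = [], [], set()

        def add_residue(chain, rid, rows):
            base = len(atoms)
            for name, pos in rows:
                atoms.append(Atom(len(atoms), name, name[0], rid, "GLY",
                                  chain, res_seq=rid + 1))
                coords.append(pos)
            bonds.update({(base, base + 1), (base, base + 2),
                          (base + 2, base + 3), (base + 3, base + 4)})

        # strand A: N-H and C=O point +y toward strand B at y=4, whose
        # reciprocal N-H/C=O point back down (ladder of mutual H-bonds)
        for k in range(5):
            x = 3.5 * k
            add_residue("A", k, [("N", [x, 0.0, 0.0]), ("H", [x, 1.0, 0.0]),
                                 ("CA", [x + 1.2, -0.5, 0.0]),
                                 ("C", [x + 2.4, 0.0, 0.0]),
                                 ("O", [x + 2.4, 1.2, 0.0])])
        for k in range(5):
            x = 3.5 * k
            add_residue("B", 5 + k, [("N", [x + 2.4, 4.0, 0.0]),
                                     ("H", [x + 2.4, 3.0, 0.0]),
                                     ("CA", [x + 1.2, 4.5, 0.0]),
                                     ("C", [x, 4.0, 0.0]),
                                     ("O", [x, 3.0, 0.0])])
        top = Topology(atoms=atoms, bonds=bonds)
        codes = assign_ss(np.array(coords), top)
        assert (codes == "E").sum() >= 4

    def test_fractions_sum_to_100(self, toy_complex):
        top, ref = toy_complex
        rng = np.random.default_rng(2)
        frames = ref[None] + rng.normal(0, 0.3, size=(5,) + ref.shape)
        traj = make_trajectory(top, frames)
        prof = ss_fractions(traj)
        assert np.allclose(prof.fractions.sum(axis=1), 100.0, atol=1e-6)

    def test_half_helix_half_coil_mixture(self, toy_complex):
        """50/50 helix/scrambled frames -> interior H fraction ~50 %."""
        top, ref = toy_complex
        rng = np.random.default_rng(8)
        scrambled = ref + rng.normal(0, 3.0, size=ref.shape)
        frames = np.stack([ref, scrambled] * 3)
        traj = make_trajectory(top, frames)
        prof = ss_fractions(traj)
        interior = slice(3, 7)
        h_frac = prof.fractions[interior, 0]
        assert np.all(h_frac >= 40.0) and np.all(h_frac <= 60.0)
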