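import biotite.structure as struc
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cdrflex import ConformationalEnsemble, RegionSet, rmsd_matrix, rmsf, superpose
from cdrflex.geometry import (backbone_dihedrals, contact_trajectory,
                              dihedral_angle, residue_contacts)
from cdrflex.io import Topology
from cdrflex.synthetic import backbone_topology, build_backbone


def _random_structure(rng, n=8):
    return rng.normal(size=(n, 3))


class TestSuperpose:
    def test_identical_structures(self):
        rng = np.random.default_rng(0)
        x = _random_structure(rng)
        R, t, rmsd = superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_rotation_gives_zero_rmsd(self):
        rng = np.random.default_rng(1)
        x = _random_structure(rng)
        rot = Rotation.from_euler("z", 90, degrees=True)
        y = rot.apply(x) + np.array([1.0, -2.0, 0.5])
        R, t, rmsd = superpose(y, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_matches_numerical_minimisation_oracle(self):
        # independent oracle: direct minimisation over rotation vectors
        rng = np.random.default_rng(2)
        a = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.3, 1.0]])
        b = a + rng.normal(0, 0.3, a.shape)

        def objective(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            am = a - a.mean(0)
            bm = b - b.mean(0)
            return np.sqrt(np.mean(np.sum((am @ R.T - bm) ** 2, axis=1)))

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for x0 in [np.zeros(3), [3, 0, 0], [0, 3, 0], [0, 0, 3], [1, 1, 1]]
        )
        _, _, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(best, abs=1e-4)

    def test_proper_rotation_for_mirror_input(self):
        rng = np.random.default_rng(3)
        x = _random_structure(rng)
        y = x * np.array([-1.0, 1.0, 1.0])  # reflected copy
        R, _, rmsd = superpose(y, x)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0  # a proper rotation cannot undo a reflection

    def test_too_few_atoms_is_error(self):
        with pytest.raises(ValueError, match="3 atoms"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_selection_is_error(self):
        line = np.outer(np.arange(4.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


class TestRmsdMatrix:
    def _ensemble(self, frames):
        topo = backbone_topology(frames.shape[1] // 4)
        return ConformationalEnsemble(topology=topo, frames=frames)

    def test_identical_frames_give_zero_matrix(self):
        frame = build_backbone(np.full(6, -1.0), np.full(6, -0.8))
        ens = self._ensemble(np.repeat(frame[None], 4, axis=0))
        m = rmsd_matrix(ens)
        assert np.allclose(m.values, 0.0, atol=1e-9)

    def test_rotated_frame_has_zero_distance(self):
        frame = build_backbone(np.full(6, -1.0), np.full(6, -0.8))
        rot = Rotation.from_euler("xyz", [30, -60, 10], degrees=True)
        ens = self._ensemble(np.stack([frame, rot.apply(frame) + 0.7]))
        m = rmsd_matrix(ens)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_matrix_matches_per_pair_superposition(self):
        rng = np.random.default_rng(4)
        frames = np.stack([
            build_backbone(rng.uniform(-np.pi, np.pi, 6),
                           rng.uniform(-np.pi, np.pi, 6))
            for _ in range(5)
        ])
        ens = self._ensemble(frames)
        m = rmsd_matrix(ens)
        ca = ens.topology.ca_indices()
        for i in range(5):
            for j in range(5):
                _, _, expected = superpose(frames[i], frames[j], selection=ca)
                assert m.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_symmetric_zero_diagonal_nonnegative(self, basin_matrix):
        v = basin_matrix.values
        assert np.allclose(v, v.T, atol=1e-9)
        assert np.allclose(np.diag(v), 0.0)
        assert v.min() >= 0


class TestDihedrals:
    def test_cis_arrangement_is_zero(self):
        p = np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 1], [1.0, 0, 1]])
        assert dihedral_angle(*p) == pytest.approx(0.0, abs=1e-12)

    def test_trans_arrangement_is_pi(self):
        p = np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 1], [-1.0, 0, 1]])
        assert abs(dihedral_angle(*p)) == pytest.approx(np.pi, abs=1e-12)

    def test_matches_independent_library_on_random_geometry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.normal(size=(4, 3))
            ours = dihedral_angle(*p)
            ref = struc.dihedral(*(p.astype(np.float64)))
            # reference library computes in single precision internally
            assert ours == pytest.approx(float(ref), abs=1e-5)

    def test_builder_round_trip(self):
        rng = np.random.default_rng(6)
        phi = rng.uniform(-np.pi, np.pi, 8)
        psi = rng.uniform(-np.pi, np.pi, 8)
        coords = build_backbone(phi, psi)
        ens = ConformationalEnsemble(topology=backbone_topology(8),
                                     frames=coords[None])
        _, P, S = backbone_dihedrals(ens)
        assert np.allclose(P[0, 1:], phi[1:], atol=1e-9)
        assert np.allclose(S[0, :-1], psi[:-1], atol=1e-9)

    def test_chain_termini_are_missing(self):
        coords = build_backbone(np.full(5, -1.0), np.full(5, 2.0))
        ens = ConformationalEnsemble(topology=backbone_topology(5),
                                     frames=coords[None])
        _, P, S = backbone_dihedrals(ens)
        assert np.isnan(P[0, 0]) and np.isnan(S[0, -1])
        assert np.all(np.isfinite(P[0, 1:])) and np.all(np.isfinite(S[0, :-1]))

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        coords = build_backbone(rng.uniform(-3, 3, 6), rng.uniform(-3, 3, 6))
        rot = Rotation.random(random_state=1)
        moved = rot.apply(coords) + np.array([5.0, -3.0, 2.0])
        topo = backbone_topology(6)
        _, P0, S0 = backbone_dihedrals(
            ConformationalEnsemble(topology=topo, frames=coords[None]))
        _, P1, S1 = backbone_dihedrals(
            ConformationalEnsemble(topology=topo, frames=moved[None]))
        assert np.allclose(P0, P1, atol=1e-9, equal_nan=True)
        assert np.allclose(S0, S1, atol=1e-9, equal_nan=True)


def _point_topology(n_res):
    """One heavy atom per residue, for controlled contact geometries."""
    return Topology(
        atom_name=np.array(["CA"] * n_res), element=np.array(["C"] * n_res),
        is_heavy=np.ones(n_res, bool), res_id=np.arange(1, n_res + 1),
        res_name=np.array(["ALA"] * n_res), chain_id=np.array(["A"] * n_res),
    )


class TestContacts:
    @pytest.fixture
    def line_system(self):
        topo = _point_topology(6)
        regions = RegionSet(ranges={"A": (1, 3), "B": (4, 6)}, n_residues=6,
                            all_residue_ids=topo.residue_ids)
        return topo, regions

    @pytest.mark.parametrize("gap, expected", [(0.44, True), (0.46, False)])
    def test_cutoff_is_strict_at_045(self, line_system, gap, expected):
        topo, regions = line_system
        frame = np.full((6, 3), 10.0) * np.arange(6)[:, None]  # far apart
        frame[0] = [0.0, 0.0, 0.0]
        frame[3] = [gap, 0.0, 0.0]   # residues 1 and 4, seq sep 3
        contacts, ua, ub = residue_contacts(frame, topo, regions, "A", "B")
        assert contacts[0, 0] == expected

    def test_sequence_neighbours_never_contact(self, line_system):
        topo, regions = line_system
        frame = np.zeros((6, 3))
        frame[:, 0] = np.arange(6) * 0.1   # everyone within 0.45 of neighbours
        contacts, ua, ub = residue_contacts(frame, topo, regions, "A", "B")
        # residue 3 (region A) vs residue 4 (region B): |Δres| = 1 → excluded
        assert not contacts[2, 0]
        # residue 2 vs residue 4: |Δres| = 2, distance 0.2 → contact
        assert contacts[1, 0]

    def test_intra_region_matrix_is_symmetric(self, basin_ensemble, basin_spec):
        ensemble, _ = basin_ensemble
        regions = basin_spec.region_set()
        contacts, ua, ub = contact_trajectory(
            ensemble.frames[:20], ensemble.topology, regions, "CDR3", "CDR3")
        assert np.array_equal(contacts, contacts.transpose(0, 2, 1))

    def test_contacts_monotone_in_cutoff(self, basin_ensemble, basin_spec):
        ensemble, _ = basin_ensemble
        regions = basin_spec.region_set()
        tight, _, _ = contact_trajectory(
            ensemble.frames[:20], ensemble.topology, regions,
            "CDR3", "scaffold", cutoff=0.40)
        loose, _, _ = contact_trajectory(
            ensemble.frames[:20], ensemble.topology, regions,
            "CDR3", "scaffold", cutoff=0.45)
        assert np.all(loose[tight])   # every 0.40-contact is a 0.45-contact

    def test_non_positive_cutoff_is_error(self, line_system):
        topo, regions = line_system
        with pytest.raises(ValueError, match="cutoff"):
            residue_contacts(np.zeros((6, 3)), topo, regions, "A", "B",
                             cutoff=0.0)


class TestRmsf:
    def test_identical_frames_give_zero(self):
        frame = build_backbone(np.full(10, -1.0), np.full(10, -0.8))
        ens = ConformationalEnsemble(topology=backbone_topology(10),
                                     frames=np.repeat(frame[None], 5, 0))
        _, f = rmsf(ens)
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_jittered_residue_matches_gaussian_closed_form(self):
        rng = np.random.default_rng(8)
        sigma = 0.02
        frame = build_backbone(np.full(10, -1.0), np.full(10, -0.8))
        frames = np.repeat(frame[None], 4000, 0)
        jit = slice(8 * 4, 10 * 4)  # all atoms of residues 9-10
        frames[:, jit, :] += rng.normal(0, sigma, size=frames[:, jit, :].shape)
        topo = backbone_topology(10)
        regions = RegionSet(ranges={"CDR3": (9, 10)}, n_residues=10,
                            all_residue_ids=topo.residue_ids)
        ens = ConformationalEnsemble(topology=topo, frames=frames)
        rids, f = rmsf(ens, regions=regions)
        loop = np.isin(rids, [9, 10])
        assert np.allclose(f[loop], sigma * np.sqrt(3), rtol=0.1)
        assert np.all(f[~loop] < 0.005)

    def test_weight_scale_invariance(self, basin_ensemble, basin_spec):
        ensemble, _ = basin_ensemble
        regions = basin_spec.region_set()
        w = np.full(ensemble.n_frames, 1.0)
        _, f1 = rmsf(ensemble, w, regions)
        _, f2 = rmsf(ensemble, 2.0 * w, regions)
        assert np.allclose(f1, f2, atol=1e-12)

    def test_single_frame_warns_and_returns_zero(self):
        frame = build_backbone(np.full(5, -1.0), np.full(5, 2.0))
        ens = ConformationalEnsemble(topology=backbone_topology(5),
                                     frames=frame[None])
        with pytest.warns(UserWarning, match="single frame"):
            _, f = rmsf(ens)
        assert np.allclose(f, 0.0)
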