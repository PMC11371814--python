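import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from metadesk.core import ReferencePair, Selection, Trajectory
from metadesk.cv import (
    antisym_stretch,
    backbone_dihedrals,
    com_torsion,
    coordination_count,
    delta_rmsd,
    dihedral,
    superpose_rmsd,
)
from metadesk.exceptions import CongruenceError, GeometryError
from metadesk.synth import (
    TwoDomainSpec,
    gen_peptide_backbone,
    gen_reaction_center,
    gen_two_domain,
)

from oracles import projection_dihedral, quaternion_rmsd


@pytest.fixture(scope="module")
def bead_pair():
    return gen_two_domain(TwoDomainSpec(beads_per_domain=12, seed=11)).pair


def _rigid(coords, seed):
    r = Rotation.random(random_state=seed).as_matrix()
    t = np.random.default_rng(seed).normal(size=3)
    return coords @ r.T + t


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        rot, trans, rmsd = superpose_rmsd(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(15, 3))
        moved = _rigid(pts, 3)
        rot, _, rmsd = superpose_rmsd(moved, pts)
        assert rmsd <= 1e-9
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        ref = rng.normal(size=(10, 3))
        mobile = _rigid(ref + 0.1 * rng.normal(size=(10, 3)), 5)
        _, _, rmsd = superpose_rmsd(mobile, ref)
        assert rmsd == pytest.approx(quaternion_rmsd(mobile, ref), abs=1e-10)

    def test_rotation_is_proper(self, rng):
        # a near-reflection arrangement must still yield det = +1
        ref = rng.normal(size=(6, 3))
        mobile = ref * np.array([1, 1, -1])
        rot, _, _ = superpose_rmsd(mobile, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_geometry_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError):
            superpose_rmsd(line, line)
        with pytest.raises(GeometryError):
            superpose_rmsd(line[:2], line[:2])


class TestDeltaRmsd:
    def test_endpoint_values(self, bead_pair):
        _, _, d = superpose_rmsd(
            bead_pair.inactive.coords, bead_pair.active.coords,
            bead_pair.align_selection,
        )
        assert delta_rmsd(bead_pair.inactive.coords, bead_pair) == pytest.approx(-d, abs=1e-12)
        assert delta_rmsd(bead_pair.active.coords, bead_pair) == pytest.approx(d, abs=1e-12)

    def test_antisymmetry_under_endpoint_swap(self, bead_pair, rng):
        frame = bead_pair.inactive.coords + 0.05 * rng.normal(
            size=bead_pair.inactive.coords.shape
        )
        assert delta_rmsd(frame, bead_pair.swapped()) == pytest.approx(
            -delta_rmsd(frame, bead_pair), abs=1e-12
        )

    def test_midpoint_interpolation_near_zero(self, bead_pair):
        mid = 0.5 * (bead_pair.inactive.coords + bead_pair.active.coords)
        value = delta_rmsd(mid, bead_pair)
        # direct-evaluation oracle: difference of independently computed RMSDs
        oracle = quaternion_rmsd(mid, bead_pair.inactive.coords) - quaternion_rmsd(
            mid, bead_pair.active.coords
        )
        assert value == pytest.approx(oracle, abs=1e-9)
        assert abs(value) < 0.05

    def test_topology_mismatch_rejected(self, bead_pair):
        with pytest.raises(CongruenceError):
            delta_rmsd(bead_pair.inactive.coords[:-1], bead_pair)


class TestComTorsion:
    def _single_atom_groups(self):
        return [Selection([i]) for i in range(4)]

    def test_planar_cis_is_zero(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert com_torsion(pts, self._single_atom_groups()) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_pi(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]])
        assert com_torsion(pts, self._single_atom_groups()) == pytest.approx(np.pi, abs=1e-12)

    def test_perpendicular_matches_oracle(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]])
        value = com_torsion(pts, self._single_atom_groups())
        assert abs(value) == pytest.approx(np.pi / 2, abs=1e-12)
        assert value == pytest.approx(projection_dihedral(*pts), abs=1e-12)

    def test_random_configs_match_oracle(self, rng):
        for _ in range(25):
            pts = rng.normal(size=(4, 3))
            assert com_torsion(pts, self._single_atom_groups()) == pytest.approx(
                projection_dihedral(*pts), abs=1e-10
            )

    def test_group_coms_define_the_angle(self, rng):
        pts = rng.normal(size=(8, 3))
        groups = [Selection([0, 1]), Selection([2, 3]), Selection([4, 5]), Selection([6, 7])]
        coms = np.array([pts[g.atom_indices].mean(axis=0) for g in groups])
        assert com_torsion(pts, groups) == pytest.approx(
            projection_dihedral(*coms), abs=1e-10
        )

    def test_coincident_consecutive_coms_rejected(self):
        pts = np.array([[0.0, 0, 0], [0, 0, 0], [1, 1, 0], [0, 1, 0]])
        with pytest.raises(GeometryError):
            com_torsion(pts, self._single_atom_groups())


class TestAntisymStretch:
    def test_equidistant_is_zero(self):
        pts = np.array([[-0.2, 0, 0], [0.0, 0, 0], [0.2, 0, 0]])
        assert antisym_stretch(pts, 0, 1, 2) == pytest.approx(0.0, abs=1e-15)

    def test_known_distances(self):
        pts = np.array([[-0.16, 0, 0], [0.0, 0, 0], [0.30, 0, 0]])
        assert antisym_stretch(pts, 0, 1, 2) == pytest.approx(-0.14, abs=1e-12)

    def test_reaction_center_fixture_vs_distances(self):
        s = gen_reaction_center("ts_like")
        o, p, n = 1, 0, 2  # bridging O, transferring P, acceptor N
        d_po = np.linalg.norm(s.coords[p] - s.coords[o])
        d_pn = np.linalg.norm(s.coords[p] - s.coords[n])
        assert antisym_stretch(s.coords, o, p, n) == pytest.approx(d_po - d_pn, abs=1e-12)
        assert antisym_stretch(s.coords, o, p, n) == pytest.approx(-0.036, abs=1e-12)

    def test_duplicate_atoms_rejected(self, rng):
        pts = rng.normal(size=(3, 3))
        with pytest.raises(ValueError):
            antisym_stretch(pts, 0, 0, 2)


class TestCoordination:
    def test_octahedral_shell(self):
        s = gen_reaction_center("ts_like")
        oxygens = Selection([i for i in range(s.n_atoms) if s.elements[i] == "O"])
        count, ligands = coordination_count(s.coords, 3, oxygens, 0.25)
        assert count == 6 and len(ligands) == 6

    def test_displaced_ligand_drops_out(self):
        s = gen_reaction_center("ts_like")
        coords = s.coords.copy()
        coords[4] = coords[3] + np.array([0.30, 0.0, 0.0])  # push one ligand out
        oxygens = Selection([i for i in range(s.n_atoms) if s.elements[i] == "O"])
        count, _ = coordination_count(coords, 3, oxygens, 0.25)
        assert count == 5

    def test_monotone_in_cutoff(self, rng):
        pts = rng.normal(size=(30, 3))
        cand = Selection(np.arange(1, 30))
        counts = [
            coordination_count(pts, 0, cand, c)[0] for c in np.linspace(0.05, 3.0, 40)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_empty_candidates_gives_zero(self, rng):
        pts = rng.normal(size=(3, 3))
        assert coordination_count(pts, 0, Selection([]), 0.5)[0] == 0


class TestGradients:
    """Analytic gradients vs central finite differences (step 1e-6 nm)."""

    @staticmethod
    def _fd_check(value_fn, grad, frame, atoms, rel_tol=1e-5, eps=1e-6):
        num = np.zeros_like(frame)
        for i in atoms:
            for k in range(3):
                fp = frame.copy()
                fp[i, k] += eps
                fm = frame.copy()
                fm[i, k] -= eps
                num[i, k] = (value_fn(fp) - value_fn(fm)) / (2 * eps)
        scale = max(np.abs(num).max(), 1e-12)
        assert np.abs(grad[atoms] - num[atoms]).max() / scale <= rel_tol

    def test_delta_rmsd_gradient(self, bead_pair, rng):
        frame = bead_pair.inactive.coords + 0.05 * rng.normal(
            size=bead_pair.inactive.coords.shape
        )
        _, grad = delta_rmsd(frame, bead_pair, gradient=True)
        self._fd_check(lambda f: delta_rmsd(f, bead_pair), grad, frame, range(0, len(frame), 5))

    def test_com_torsion_gradient(self, rng):
        frame = rng.normal(size=(8, 3))
        groups = [Selection([0, 1]), Selection([2, 3]), Selection([4, 5]), Selection([6, 7])]
        _, grad = com_torsion(frame, groups, gradient=True)
        self._fd_check(lambda f: com_torsion(f, groups), grad, frame, range(8))

    def test_antisym_stretch_gradient(self, rng):
        frame = rng.normal(size=(5, 3))
        _, grad = antisym_stretch(frame, 0, 2, 4, gradient=True)
        self._fd_check(lambda f: antisym_stretch(f, 0, 2, 4), grad, frame, [0, 2, 4])


class TestRigidMotionInvariance:
    def test_all_cvs_invariant(self, bead_pair, rng):
        frame = bead_pair.inactive.coords + 0.03 * rng.normal(
            size=bead_pair.inactive.coords.shape
        )
        moved = _rigid(frame, 9)
        groups = [Selection([0, 1, 2]), Selection([3, 4]), Selection([5, 6]), Selection([7, 8])]
        assert delta_rmsd(moved, bead_pair) == pytest.approx(
            delta_rmsd(frame, bead_pair), abs=1e-9
        )
        assert com_torsion(moved, groups) == pytest.approx(
            com_torsion(frame, groups), abs=1e-9
        )
        assert antisym_stretch(moved, 0, 1, 2) == pytest.approx(
            antisym_stretch(frame, 0, 1, 2), abs=1e-9
        )
        cand = Selection(np.arange(1, len(frame)))
        assert coordination_count(moved, 0, cand, 0.5)[0] == coordination_count(
            frame, 0, cand, 0.5
        )[0]


class TestBackboneDihedrals:
    def test_helical_torsions_recovered(self):
        phi, psi = np.radians(-60.0), np.radians(-45.0)
        s = gen_peptide_backbone([phi] * 9, [psi] * 9)
        traj = Trajectory(s, s.coords[None], [0.0])
        ph, ps = backbone_dihedrals(traj, range(1, 11))
        np.testing.assert_allclose(ph[0, 1:], phi, atol=0.05)
        np.testing.assert_allclose(ps[0, :-1], psi, atol=0.05)

    def test_terminal_residues_reported_absent(self):
        s = gen_peptide_backbone([np.radians(-60)] * 2, [np.radians(-45)] * 2)
        traj = Trajectory(s, s.coords[None], [0.0])
        ph, ps = backbone_dihedrals(traj, range(1, 4))
        assert np.isnan(ph[0, 0]) and not np.isnan(ph[0, 1])
        assert np.isnan(ps[0, -1]) and not np.isnan(ps[0, 1])

    def test_agrees_with_com_torsion_cross_oracle(self):
        s = gen_peptide_backbone([np.radians(-120)] * 3, [np.radians(130)] * 3)
        traj = Trajectory(s, s.coords[None], [0.0])
        ph, _ = backbone_dihedrals(traj, [2])
        # φ(2) = dihedral C(1)-N(2)-CA(2)-C(2): atoms 2, 3, 4, 5
        groups = [Selection([2]), Selection([3]), Selection([4]), Selection([5])]
        assert ph[0, 0] == pytest.approx(com_torsion(s.coords, groups), abs=1e-10)

    def test_missing_backbone_atom_named(self):
        s = gen_peptide_backbone([np.radians(-60)] * 2, [np.radians(-45)] * 2)
        # drop CA of residue 2 (atom index 4)
        keep = [i for i in range(s.n_atoms) if i != 4]
        from conftest import make_structure

        sub = make_structure(
            list(
                zip(
                    s.atom_names[keep],
                    s.residue_names[keep],
                    s.residue_indices[keep],
                    s.chain_ids[keep],
                    s.elements[keep],
                )
            ),
            s.coords[keep],
        )
        traj = Trajectory(sub, sub.coords[None], [0.0])
        with pytest.raises(CongruenceError, match="CA"):
            backbone_dihedrals(traj, [2])
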