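"""Molecular data model: combining rules, rigid superposition RMSD,
mirror images and the plain-text formats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from rigidcsp.chem import (Atom, ForceField, MultipoleSet, PairParams,
                           ParameterMissingError, RigidMolecule,
                           TOY_FORCE_FIELD, combine_params, load_force_field,
                           load_molecule_xyz, mirror_image, molecular_rmsd,
                           write_molecule_xyz)


def two_atom(d=1.1, q=0.2):
    return RigidMolecule("pair", [
        Atom("C", (0.0, 0.0, 0.0), "C", q),
        Atom("O", (d, 0.0, 0.0), "O", -q),
    ])


class TestCombineParams:
    @pytest.mark.parametrize("aii,ajj,expect", [
        (100.0, 100.0, 100.0),     # identity under any mean
        (100.0, 400.0, 200.0),     # geometric mean
    ])
    def test_a_combination(self, aii, ajj, expect):
        ff = ForceField({"X": PairParams(aii, 3.0, 10.0),
                         "Y": PairParams(ajj, 4.0, 40.0)})
        assert combine_params("X", "Y", ff).A == pytest.approx(expect)

    def test_b_arithmetic_c_geometric(self):
        ff = ForceField({"X": PairParams(1.0, 3.0, 10.0),
                         "Y": PairParams(1.0, 4.0, 40.0)})
        p = combine_params("X", "Y", ff)
        assert p.B == pytest.approx(3.5)
        assert p.C == pytest.approx(20.0)

    def test_symmetric_in_arguments(self):
        for ti in TOY_FORCE_FIELD.params:
            for tj in TOY_FORCE_FIELD.params:
                pij = combine_params(ti, tj, TOY_FORCE_FIELD)
                pji = combine_params(tj, ti, TOY_FORCE_FIELD)
                assert pij == pji

    def test_unknown_type_names_the_type(self):
        with pytest.raises(ParameterMissingError, match="Zz"):
            combine_params("C", "Zz", TOY_FORCE_FIELD)


class TestMolecularRmsd:
    def test_identical_conformers(self, bent3):
        assert molecular_rmsd(bent3, bent3) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self, bent3):
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7])
        moved = bent3.with_positions(rot.apply(bent3.positions) + [5.0, -2.0, 1.0])
        assert molecular_rmsd(bent3, moved) == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_bond_stretch(self):
        # one atom displaced 0.2 Å along the bond: after optimal
        # superposition each atom sits 0.1 Å from its partner
        a = two_atom(1.1)
        b = two_atom(1.3)
        expected = _brute_force_min_rmsd(a.positions, b.positions)
        assert expected == pytest.approx(0.1, abs=1e-3)
        assert molecular_rmsd(a, b) == pytest.approx(expected, abs=1e-6)

    def test_atom_count_mismatch(self, bent3):
        with pytest.raises(ValueError, match="mismatch"):
            molecular_rmsd(bent3, two_atom())

    def test_invariant_to_simultaneous_rigid_motion(self, bent3, chiral5):
        r1 = molecular_rmsd(bent3, R := _jitter(bent3, 0.1))
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5])
        a2 = bent3.with_positions(rot.apply(bent3.positions) + 3.0)
        b2 = R.with_positions(rot.apply(R.positions) + 3.0)
        assert molecular_rmsd(a2, b2) == pytest.approx(r1, abs=1e-9)


def _jitter(mol, scale, seed=4):
    rng = np.random.default_rng(seed)
    return mol.with_positions(mol.positions + scale * rng.standard_normal(mol.positions.shape))


def _brute_force_min_rmsd(xa, xb, n_rot=800, seed=0):
    """Independent oracle: minimise RMSD over proper rotations + optimal
    translation — random rotation starts refined by a local simplex search
    over the rotation vector."""
    from scipy.optimize import minimize as _nm

    rng = np.random.default_rng(seed)
    a = xa - xa.mean(axis=0)
    b = xb - xb.mean(axis=0)

    def rmsd_of(rotvec):
        d = a - Rotation.from_rotvec(rotvec).apply(b)
        return float(np.sqrt((d**2).sum(axis=1).mean()))

    best = np.inf
    starts = Rotation.random(n_rot, random_state=rng).as_rotvec()
    coarse = sorted(starts, key=rmsd_of)[:5]
    for rv in coarse:
        res = _nm(rmsd_of, rv, method="Nelder-Mead",
                  options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, float(res.fun))
    return best


class TestMirrorImage:
    def test_achiral_planar_superimposable(self, bent3):
        # a planar molecule coincides with its mirror image under a proper
        # rotation (flip in the molecular plane)
        assert molecular_rmsd(bent3, mirror_image(bent3)) == pytest.approx(0.0, abs=1e-9)

    def test_chiral_tetrahedron_not_superimposable(self, chiral5):
        mirror = mirror_image(chiral5)
        best = _brute_force_min_rmsd(chiral5.positions, mirror.positions, n_rot=2000)
        assert best > 0.15
        assert molecular_rmsd(chiral5, mirror) > 0.15

    def test_involution(self, chiral5):
        twice = mirror_image(mirror_image(chiral5))
        assert np.allclose(twice.positions, chiral5.positions)
        assert twice.multipoles == chiral5.multipoles

    def test_preserves_interatomic_distances(self, chiral5):
        def dmat(m):
            d = m.positions[:, None, :] - m.positions[None, :, :]
            return np.sqrt((d**2).sum(axis=2))
        assert np.allclose(dmat(chiral5), dmat(mirror_image(chiral5)))

    def test_multipole_parity(self):
        mp = MultipoleSet(np.array([0.1, -0.1]),
                          dipoles=[[0.1, 0.2, 0.3], [0.0, -0.1, 0.0]],
                          quadrupoles=np.stack([np.diag([0.1, 0.1, -0.2])] * 2))
        mol = RigidMolecule("m", [
            Atom("C", (0, 0, 0), "C", 0.1), Atom("O", (1.2, 0, 0), "O", -0.1),
        ], mp)
        inv = mirror_image(mol)
        assert np.allclose(inv.multipoles.dipoles, -mp.dipoles)
        assert np.allclose(inv.multipoles.quadrupoles, mp.quadrupoles)

    def test_stereo_label_swapped(self, chiral5):
        assert chiral5.stereo_label == "R"
        assert mirror_image(chiral5).stereo_label == "S"


class TestMultipoleSet:
    def test_spherical_dipole_conversion(self):
        mp = MultipoleSet.from_spherical([0.0], dipoles_sph=[[0.3, 0.1, -0.2]])
        # (Q10, Q11c, Q11s) -> (z, x, y)
        assert np.allclose(mp.dipoles[0], [0.1, -0.2, 0.3])

    def test_spherical_quadrupole_traceless(self):
        mp = MultipoleSet.from_spherical(
            [0.0], quadrupoles_sph=[[0.4, 0.1, -0.2, 0.3, 0.05]])
        q = mp.quadrupoles[0]
        assert np.trace(q) == pytest.approx(0.0, abs=1e-12)
        assert q[2, 2] == pytest.approx(0.4)
        assert np.allclose(q, q.T)

    def test_rank0_must_match_charges(self):
        with pytest.raises(ValueError, match="rank-0"):
            RigidMolecule("bad", [
                Atom("C", (0, 0, 0), "C", 0.1),
                Atom("O", (1, 0, 0), "O", -0.1),
            ], MultipoleSet(np.array([0.2, -0.2])))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rotation_preserves_invariants(self, seed):
        rng = np.random.default_rng(seed)
        mp = MultipoleSet(np.array([0.2, -0.2]),
                          dipoles=rng.standard_normal((2, 3)) * 0.1,
                          quadrupoles=_sym_traceless(rng, 2))
        rot = Rotation.random(random_state=rng).as_matrix()
        out = mp.rotated(rot)
        assert np.allclose(out.charges, mp.charges)
        # dipole norms and quadrupole eigenvalues are rotation invariants
        assert np.allclose(np.linalg.norm(out.dipoles, axis=1),
                           np.linalg.norm(mp.dipoles, axis=1))
        for a, b in zip(out.quadrupoles, mp.quadrupoles):
            assert np.allclose(np.sort(np.linalg.eigvalsh(a)),
                               np.sort(np.linalg.eigvalsh(b)), atol=1e-10)


def _sym_traceless(rng, n):
    out = np.zeros((n, 3, 3))
    for i in range(n):
        m = rng.standard_normal((3, 3)) * 0.1
        m = 0.5 * (m + m.T)
        out[i] = m - np.eye(3) * np.trace(m) / 3.0
    return out


class TestFileFormats:
    def test_force_field_round_trip(self, tmp_path):
        path = tmp_path / "ff.params"
        path.write_text("# toy table\nC 226000.0 3.6 2200.0\nH 11000 3.74 130\n")
        ff = load_force_field(path)
        assert ff.params["C"] == PairParams(226000.0, 3.6, 2200.0)
        assert combine_params("C", "H", ff).B == pytest.approx((3.6 + 3.74) / 2)

    def test_molecule_xyz_round_trip(self, tmp_path, chiral5):
        path = tmp_path / "mol.xyz"
        write_molecule_xyz(chiral5, path)
        back = load_molecule_xyz(path)
        assert back.is_chiral
        assert back.elements == chiral5.elements
        assert back.ff_types == chiral5.ff_types
        assert np.allclose(back.positions, chiral5.positions, atol=1e-9)
        assert np.allclose(back.charges, chiral5.charges, atol=1e-6)

    def test_molecule_xyz_multipoles_round_trip(self, tmp_path):
        mol = R_mol_with_multipoles()
        path = tmp_path / "mp.xyz"
        write_molecule_xyz(mol, path)
        back = load_molecule_xyz(path)
        assert back.multipoles.rank == 2
        assert np.allclose(back.multipoles.dipoles, mol.multipoles.dipoles, atol=1e-9)
        assert np.allclose(back.multipoles.quadrupoles, mol.multipoles.quadrupoles,
                           atol=1e-9)


def R_mol_with_multipoles():
    import rigidcsp.synthetic as syn

    return syn.make_toy_molecule(
        syn.ToyMoleculeSpec("bent3", with_multipoles=True))
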