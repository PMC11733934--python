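import numpy as np
import pytest

from hbdiff.complexes import (
    EmptyPocketError,
    HBondCriteria,
    HydrogenBond,
    LigandMolecule,
    detect_hydrogen_bonds,
    extract_pocket,
    load_complex,
    place_interaction_particles,
    to_calpha,
)
from hbdiff.fixtures import FixtureSpec, make_toy_complex, write_fixture_files
from tests.conftest import protein_from_atoms, random_rotation

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.220   1.320   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.220   2.320   0.710  1.00  0.00           O
END
"""

SINGLE_ATOM_SDF = """\
methane
  test

  1  0  0  0  0  0  0  0  0  0999 V2000
    3.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
$$$$
"""

ETHANOL_WITH_H_SDF = """\
ethanol
  test

  9  8  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    1.3000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4000    1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4000   -0.5000    0.9000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4000   -0.5000   -0.9000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.9000   -0.5000    0.9000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.9000   -0.5000   -0.9000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.9700    1.2500    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  1  4  1  0
  1  5  1  0
  1  6  1  0
  2  7  1  0
  2  8  1  0
  3  9  1  0
M  END
$$$$
"""


class TestLoadComplex:
    def test_minimal_pair(self, tmp_path):
        (tmp_path / "p.pdb").write_text(MINIMAL_PDB)
        (tmp_path / "l.sdf").write_text(SINGLE_ATOM_SDF)
        rec = load_complex(tmp_path / "p.pdb", tmp_path / "l.sdf")
        assert len(rec.protein.residue_keys()) == 1
        assert rec.ligand.n_atoms == 1
        assert rec.ligand.elements == ["C"]

    def test_hydrogens_stripped_with_record(self, tmp_path):
        (tmp_path / "p.pdb").write_text(MINIMAL_PDB)
        (tmp_path / "l.sdf").write_text(ETHANOL_WITH_H_SDF)
        rec = load_complex(tmp_path / "p.pdb", tmp_path / "l.sdf")
        assert rec.ligand.n_atoms == 3  # 9 atoms - 6 hydrogens
        # the hydroxyl O carried one H
        assert rec.ligand.h_counts[rec.ligand.elements.index("O")] == 1

    def test_fixture_round_trip(self, tmp_path, toy_record):
        paths = write_fixture_files(toy_record, tmp_path)
        rec = load_complex(paths["pdb"], paths["sdf"])
        np.testing.assert_allclose(
            rec.protein.positions, toy_record.protein.positions, atol=1e-3
        )
        np.testing.assert_allclose(
            rec.ligand.positions, toy_record.ligand.positions, atol=1e-3
        )
        assert rec.ligand.elements == toy_record.ligand.elements

    def test_unreadable_ligand(self, tmp_path):
        (tmp_path / "p.pdb").write_text(MINIMAL_PDB)
        (tmp_path / "l.sdf").write_text("not a molfile\n")
        with pytest.raises(ValueError):
            load_complex(tmp_path / "p.pdb", tmp_path / "l.sdf")


def _one_atom_ligand(xyz=(0.0, 0.0, 0.0)):
    return LigandMolecule(elements=["C"], positions=np.array([xyz]), bonds=[])


class TestExtractPocket:
    def _protein_with_residue_at(self, d):
        return protein_from_atoms(
            [
                ("C", "CA", "ALA", 1, "A", (d, 0, 0)),
                ("C", "CB", "ALA", 1, "A", (d + 1.5, 0, 0)),
            ]
        )

    def test_within_radius_retained(self):
        pocket = extract_pocket(self._protein_with_residue_at(9.9), _one_atom_ligand())
        assert pocket.n_atoms == 2  # whole residue kept

    def test_beyond_radius_dropped(self):
        with pytest.raises(EmptyPocketError):
            extract_pocket(self._protein_with_residue_at(10.1), _one_atom_ligand())

    def test_whole_residue_kept_if_any_atom_close(self):
        protein = protein_from_atoms(
            [
                ("C", "CA", "ALA", 1, "A", (9.0, 0, 0)),
                ("C", "CB", "ALA", 1, "A", (14.0, 0, 0)),
            ]
        )
        pocket = extract_pocket(protein, _one_atom_ligand())
        assert pocket.n_atoms == 2

    def test_matches_brute_force_scan(self, rng):
        atoms = []
        for r in range(20):
            for k in range(3):
                atoms.append(("C", "CA" if k == 0 else "CB", "GLY", r + 1, "A",
                              tuple(rng.uniform(-15, 15, 3))))
        protein = protein_from_atoms(atoms)
        ligand = LigandMolecule(
            elements=["C"] * 4, positions=rng.uniform(-3, 3, (4, 3)), bonds=[]
        )
        expected = set()
        for i in range(protein.n_atoms):
            for lx in ligand.positions:
                if np.linalg.norm(protein.positions[i] - lx) <= 10.0:
                    expected.add(protein.atom_residue_key(i))
        pocket = extract_pocket(protein, ligand, radius=10.0)
        assert set(pocket.residue_keys()) == expected


class TestToCalpha:
    def test_three_residues_distinct_onehots(self):
        atoms = []
        for r, name in enumerate(["ALA", "GLY", "SER"], start=1):
            atoms.append(("N", "N", name, r, "A", (r * 4.0, 0, 0)))
            atoms.append(("C", "CA", name, r, "A", (r * 4.0 + 1.5, 0, 0)))
        pocket = to_calpha(protein_from_atoms(atoms))
        assert pocket.n_nodes == 3
        assert len({tuple(row) for row in pocket.one_hot}) == 3

    def test_nonstandard_residue_maps_to_unknown(self):
        atoms = [("C", "CA", "MSE", 1, "A", (0, 0, 0))]
        pocket = to_calpha(protein_from_atoms(atoms))
        assert pocket.one_hot[0, -1] == 1.0

    def test_positions_bit_exact(self, toy_record):
        pocket_atoms = extract_pocket(toy_record.protein, toy_record.ligand)
        cap = to_calpha(pocket_atoms)
        ca = {
            pocket_atoms.atom_residue_key(i): pocket_atoms.positions[i]
            for i in range(pocket_atoms.n_atoms)
            if pocket_atoms.atom_names[i] == "CA"
        }
        for node, key in zip(cap.positions, pocket_atoms.residue_keys()):
            assert np.array_equal(node, ca[key])

    def test_missing_calpha_raises(self):
        atoms = [("N", "N", "ALA", 7, "A", (0, 0, 0))]
        with pytest.raises(ValueError, match="7"):
            to_calpha(protein_from_atoms(atoms))


def _carbonyl_protein(o_xyz, c_xyz):
    """Backbone carbonyl: C=O at 1.23 A -> O is acceptor only."""
    return protein_from_atoms(
        [
            ("C", "C", "ALA", 1, "A", c_xyz),
            ("O", "O", "ALA", 1, "A", o_xyz),
        ]
    )


class TestDetectHydrogenBonds:
    def test_hydroxyl_to_carbonyl(self):
        # ligand C-O(H) donor; protein carbonyl O acceptor at 2.9 A, angle 150
        lig = LigandMolecule(
            elements=["C", "O"],
            positions=np.array([[0.0, 0.0, 0.0], [1.43, 0.0, 0.0]]),
            bonds=[(0, 1, 1.0)],
            h_counts=[3, 1],
        )
        ang = np.radians(180 - 150)
        xo = np.array([1.43, 0, 0]) + 2.9 * np.array([np.cos(ang), np.sin(ang), 0])
        protein = _carbonyl_protein(tuple(xo), tuple(xo + [1.23, 0, 0]))
        bonds = detect_hydrogen_bonds(protein, lig)
        assert len(bonds) == 1
        assert bonds[0].ligand_role == "donor"
        assert bonds[0].donor_acceptor_distance == pytest.approx(2.9)

    def test_angle_below_minimum_rejected(self):
        lig = LigandMolecule(
            elements=["C", "O"],
            positions=np.array([[0.0, 0.0, 0.0], [1.43, 0.0, 0.0]]),
            bonds=[(0, 1, 1.0)],
            h_counts=[3, 1],
        )
        ang = np.radians(180 - 90)  # neighbor-donor-acceptor angle 90 < 120
        xo = np.array([1.43, 0, 0]) + 2.9 * np.array([np.cos(ang), np.sin(ang), 0])
        protein = _carbonyl_protein(tuple(xo), tuple(xo + [1.23, 0, 0]))
        assert detect_hydrogen_bonds(protein, lig) == []

    def test_beyond_cutoff(self):
        lig = _one_atom_ligand()
        lig = LigandMolecule(
            elements=["O"], positions=np.array([[0.0, 0.0, 0.0]]), bonds=[], h_counts=[1]
        )
        protein = protein_from_atoms([("N", "N", "ALA", 1, "A", (5.0, 0, 0))])
        assert detect_hydrogen_bonds(protein, lig) == []

    def test_carbons_never_bond(self):
        lig = _one_atom_ligand()
        protein = protein_from_atoms([("C", "CA", "ALA", 1, "A", (2.9, 0, 0))])
        assert detect_hydrogen_bonds(protein, lig) == []

    def test_criteria_cutoff_configurable(self):
        lig = LigandMolecule(
            elements=["O"], positions=np.array([[0.0, 0.0, 0.0]]), bonds=[], h_counts=[1]
        )
        protein = protein_from_atoms([("N", "N", "ALA", 1, "A", (3.2, 0, 0))])
        assert len(detect_hydrogen_bonds(protein, lig)) > 0
        assert detect_hydrogen_bonds(protein, lig, HBondCriteria(max_da_distance=3.0)) == []

    def test_rigid_transform_covariance(self, toy_record, rng):
        R = random_rotation(rng)
        b = rng.uniform(-10, 10, 3)
        bonds0 = detect_hydrogen_bonds(toy_record.protein, toy_record.ligand)
        bonds1 = detect_hydrogen_bonds(
            toy_record.protein.transformed(R, b), toy_record.ligand.transformed(R, b)
        )
        key = lambda hb: (hb.protein_atom_index, hb.ligand_atom_index, hb.ligand_role)
        assert [key(h) for h in bonds0] == [key(h) for h in bonds1]
        for h0, h1 in zip(bonds0, bonds1):
            assert h0.donor_acceptor_distance == pytest.approx(
                h1.donor_acceptor_distance, abs=1e-9
            )


class TestInteractionParticles:
    def test_collinear_thirds(self, toy_record):
        hb = HydrogenBond(0, 0, "donor", 3.0)
        protein = protein_from_atoms([("O", "O", "ALA", 1, "A", (0, 0, 0))])
        lig = LigandMolecule(
            elements=["O"], positions=np.array([[3.0, 0.0, 0.0]]), bonds=[], h_counts=[1]
        )
        p1, p2 = place_interaction_particles(hb, protein, lig)
        np.testing.assert_allclose(p1.position, (1, 0, 0))
        np.testing.assert_allclose(p2.position, (2, 0, 0))
        assert p1.label == p2.label == "donor"
        assert (p1.j, p2.j) == (1, 2)

    def test_direct_evaluation(self):
        hb = HydrogenBond(0, 0, "acceptor", 1.0)
        protein = protein_from_atoms([("N", "N", "ALA", 1, "A", (1, 2, 3))])
        lig = LigandMolecule(
            elements=["O"], positions=np.array([[4.0, 5.0, 9.0]]), bonds=[]
        )
        p1, p2 = place_interaction_particles(hb, protein, lig)
        np.testing.assert_allclose(p1.position, (2, 3, 5))
        np.testing.assert_allclose(p2.position, (3, 4, 7))
        assert p1.label == "acceptor"

    def test_degenerate_endpoints_raise(self):
        hb = HydrogenBond(0, 0, "donor", 1.0)
        protein = protein_from_atoms([("O", "O", "ALA", 1, "A", (1, 1, 1))])
        lig = LigandMolecule(elements=["O"], positions=np.array([[1.0, 1.0, 1.0]]), bonds=[])
        with pytest.raises(ValueError, match="degenerate"):
            place_interaction_particles(hb, protein, lig)

    def test_trisection_exactness(self, toy_record):
        for p1, p2 in zip(toy_record.particles[::2], toy_record.particles[1::2]):
            hb = toy_record.hbonds[p1.bond_id]
            xp = toy_record.protein.positions[hb.protein_atom_index]
            xl = toy_record.ligand.positions[hb.ligand_atom_index]
            a = np.linalg.norm(np.array(p1.position) - xp)
            b = np.linalg.norm(np.array(p2.position) - np.array(p1.position))
            c = np.linalg.norm(xl - np.array(p2.position))
            assert a == pytest.approx(b, rel=1e-9)
            assert b == pytest.approx(c, rel=1e-9)

    def test_particle_covariance(self, toy_record, rng):
        R = random_rotation(rng)
        b = rng.uniform(-5, 5, 3)
        prot = toy_record.protein.transformed(R, b)
        lig = toy_record.ligand.transformed(R, b)
        for k, hb in enumerate(toy_record.hbonds):
            orig = place_interaction_particles(hb, toy_record.protein, toy_record.ligand, k)
            moved = place_interaction_particles(hb, prot, lig, k)
            for o, m in zip(orig, moved):
                np.testing.assert_allclose(
                    np.array(o.position) @ R.T + b, m.position, atol=1e-6
                )
                assert o.label == m.label


def test_detection_symmetric_in_scan_order(toy_record):
    # reversing ligand atom order relabels indices but yields the same bond set
    lig = toy_record.ligand
    n = lig.n_atoms
    perm = list(range(n))[::-1]
    inv = {old: new for new, old in enumerate(perm)}
    rev = LigandMolecule(
        elements=[lig.elements[i] for i in perm],
        positions=lig.positions[perm],
        bonds=[(inv[i], inv[j], o) for i, j, o in lig.bonds],
        h_counts=[lig.h_counts[i] for i in perm],
    )
    fwd = {
        (hb.protein_atom_index, hb.ligand_atom_index, hb.ligand_role)
        for hb in detect_hydrogen_bonds(toy_record.protein, lig)
    }
    bwd = {
        (hb.protein_atom_index, perm[hb.ligand_atom_index], hb.ligand_role)
        for hb in detect_hydrogen_bonds(toy_record.protein, rev)
    }
    assert fwd == bwd


def test_pocket_radius_must_be_positive(toy_record):
    with pytest.raises(ValueError):
        extract_pocket(toy_record.protein, toy_record.ligand, radius=-1.0)
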