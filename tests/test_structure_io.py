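"""Structure and molecule parsing, writing, and pocket extraction."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from dtbind.fixtures import make_toy_protein
from dtbind.structure_io import (AtomRecord, EmptyStructureError,
                                 MoleculeParseError, PocketSelection,
                                 ProteinStructure, ResidueRecord,
                                 StructureFormatError, extract_pocket,
                                 parse_protein_structure, parse_small_molecule,
                                 pocket_from_ligand, read_pocket_selection,
                                 write_mmcif, write_pdb)


class TestProteinParsing:
    def test_pdb_round_trip_preserves_residues_and_ca(self, tmp_path):
        protein = make_toy_protein(20, seed=3)
        path = tmp_path / "toy.pdb"
        write_pdb(protein, path)
        parsed = parse_protein_structure(path)
        assert parsed.n_residues == 20
        np.testing.assert_allclose(parsed.ca_coordinates(),
                                   protein.ca_coordinates(), atol=1e-3)
        assert parsed.sequence == protein.sequence

    def test_residue_without_ca_is_dropped(self, tmp_path):
        protein = make_toy_protein(10, seed=3)
        broken = protein.residues[4]
        residues = list(protein.residues)
        residues[4] = ResidueRecord(
            broken.chain_id, broken.resnum, broken.icode, broken.resname,
            atoms=tuple(a for a in broken.atoms if a.name != "CA"))
        path = tmp_path / "broken.pdb"
        write_pdb(ProteinStructure(residues=residues), path)
        parsed = parse_protein_structure(path)
        assert parsed.n_residues == 9
        assert (broken.chain_id, broken.resnum, broken.icode) \
            not in parsed.residue_index()

    def test_mmcif_and_pdb_agree_on_coordinates(self, tmp_path):
        protein = make_toy_protein(15, seed=4)
        write_pdb(protein, tmp_path / "t.pdb")
        write_mmcif(protein, tmp_path / "t.cif")
        from_pdb = parse_protein_structure(tmp_path / "t.pdb")
        from_cif = parse_protein_structure(tmp_path / "t.cif")
        assert from_pdb.n_residues == from_cif.n_residues
        np.testing.assert_allclose(from_pdb.ca_coordinates(),
                                   from_cif.ca_coordinates(), atol=1e-3)

    def test_waters_and_ligands_are_excluded(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C\n"
            "HETATM    4  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O\n"
            "HETATM    5  C1  LIG A 201       8.000   8.000   8.000  1.00  0.00           C\n"
            "END\n")
        parsed = parse_protein_structure(path)
        assert parsed.n_residues == 1
        assert parsed.residues[0].resname == "ALA"

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.70  0.00           C\n"
            "ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C\n"
            "END\n")
        parsed = parse_protein_structure(path)
        np.testing.assert_allclose(parsed.residues[0].ca, [2.0, 0.0, 0.0])

    def test_unparseable_and_empty_inputs_raise(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyStructureError):
            parse_protein_structure(empty)
        with pytest.raises(StructureFormatError):
            parse_protein_structure(tmp_path / "missing.pdb")

    def test_model_index_selects_model(self, tmp_path):
        protein = make_toy_protein(5, seed=5)
        path = tmp_path / "m.pdb"
        write_pdb(protein, path)
        with pytest.raises(StructureFormatError):
            parse_protein_structure(path, model_index=3)


class TestMoleculeParsing:
    def test_ethane_graph(self):
        mol = parse_small_molecule("CC")
        assert mol.n_atoms == 2
        assert len(mol.bonds) == 1
        assert not any(a["aromatic"] for a in mol.atoms)

    def test_benzene_matches_rdkit_oracle(self):
        mol = parse_small_molecule("c1ccccc1")
        oracle = Chem.MolFromSmiles("c1ccccc1")
        assert mol.n_atoms == oracle.GetNumAtoms() == 6
        assert len(mol.bonds) == oracle.GetNumBonds() == 6
        assert all(a["aromatic"] for a in mol.atoms)
        assert all(b["in_ring"] and b["order"] == "aromatic"
                   for b in mol.bonds)

    def test_sdf_keeps_coordinates(self, tmp_path):
        rd = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1"))
        params = AllChem.ETKDGv3()
        params.randomSeed = 7
        AllChem.EmbedMolecule(rd, params)
        rd = Chem.RemoveHs(rd)
        path = tmp_path / "benzene.sdf"
        w = Chem.SDWriter(str(path))
        w.write(rd)
        w.close()
        mol = parse_small_molecule(path)
        assert mol.n_atoms == 6 and len(mol.bonds) == 6
        assert mol.coords is not None and mol.coords.shape == (6, 3)
        np.testing.assert_allclose(
            mol.coords, np.array(rd.GetConformer().GetPositions()), atol=1e-4)

    def test_invalid_inputs_raise(self, tmp_path):
        with pytest.raises(MoleculeParseError):
            parse_small_molecule("not_a_smiles((")
        with pytest.raises(MoleculeParseError):
            parse_small_molecule(tmp_path / "missing.sdf")


class TestPockets:
    def test_full_selection_is_identity(self):
        protein = make_toy_protein(12, seed=6)
        sel = PocketSelection(tuple(r.key for r in protein.residues))
        pocket = extract_pocket(protein, sel)
        assert pocket.n_residues == protein.n_residues
        np.testing.assert_allclose(pocket.ca_coordinates(),
                                   protein.ca_coordinates())
        assert pocket.parent_indices == list(range(12))
        for a, b in zip(pocket.residues, protein.residues):
            assert a.atoms == b.atoms

    def test_distance_pocket_matches_brute_force(self):
        protein = make_toy_protein(30, seed=7)
        ligand = protein.residues[10].ca + np.array([4.0, 0.0, 0.0])
        sel = pocket_from_ligand(protein, ligand[None, :], cutoff=8.0)
        # O(N*M) oracle
        expected = []
        for r in protein.residues:
            dmin = min(np.linalg.norm(a.xyz - ligand) for a in r.atoms
                       if a.element != "H")
            if dmin <= 8.0:
                expected.append(r.key)
        assert list(sel.members) == expected
        assert len(sel) > 0

    def test_empty_selection_and_missing_residue_errors(self):
        protein = make_toy_protein(5, seed=8)
        with pytest.raises(ValueError):
            extract_pocket(protein, PocketSelection(()))
        with pytest.raises(KeyError, match="Z.*99"):
            extract_pocket(protein, PocketSelection((("Z", 99, ""),)))

    def test_selection_file_round_trip(self, tmp_path):
        path = tmp_path / "pocket.txt"
        path.write_text("# comment\nA:3\nA:7A\nB:12\n")
        sel = read_pocket_selection(path)
        assert sel.members == (("A", 3, ""), ("A", 7, "A"), ("B", 12, ""))
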