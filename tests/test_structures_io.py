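import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hawkrank as hr
from hawkrank.structures_io import PDBParseError

from conftest import random_rigid

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.000   2.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.400   2.000   3.000  1.00  0.00           C
END
"""


class TestReadPdb:
    def test_minimal_atom_records(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        with pytest.warns(UserWarning, match="protonated"):
            s = hr.read_pdb(p)
        assert s.n_atoms == 3
        assert s.n_res == 1
        ca = s.atoms[1]
        assert ca.name == "CA" and ca.res_name == "ALA" and ca.chain_id == "A"
        np.testing.assert_allclose(ca.coords, [1.0, 2.0, 3.0])

    def test_no_atom_records_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nHETATM    1  O   HOH A   1       "
                     "0.000   0.000   0.000  1.00  0.00           O\nEND\n")
        with pytest.raises(PDBParseError, match="no ATOM records"):
            hr.read_pdb(p)

    def test_multi_model_policy(self, tmp_path):
        body = MINIMAL_PDB.replace("END\n", "")
        p = tmp_path / "nmr.pdb"
        p.write_text(
            "MODEL        1\n" + body + "ENDMDL\n"
            "MODEL        2\n" + body + "ENDMDL\nEND\n"
        )
        with pytest.raises(PDBParseError, match="2 models"):
            hr.read_pdb(p, model_policy="error")
        with pytest.warns(UserWarning):
            s = hr.read_pdb(p, model_policy="first")
        assert s.n_atoms == 3

    def test_round_trip_is_coordinate_stable(self, tmp_path, all20_peptide):
        """write -> read -> write -> read agrees to PDB precision (1e-3 A)."""
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        hr.write_pdb(all20_peptide, p1)
        s1 = hr.read_pdb(p1)
        hr.write_pdb(s1, p2)
        s2 = hr.read_pdb(p2)
        assert s1.n_atoms == all20_peptide.n_atoms == s2.n_atoms
        np.testing.assert_allclose(s1.coords, all20_peptide.coords, atol=1e-3)
        np.testing.assert_allclose(s2.coords, s1.coords, atol=1e-9)
        assert [a.name for a in s1.atoms] == [a.name for a in all20_peptide.atoms]


class TestAssignPartners:
    def _chain(self, n_res, chain="A", seed=0):
        return hr.make_toy_protein(hr.ToySpec(n_res, "extended", seed, chain_id=chain))

    def test_smaller_protein_is_ligand(self):
        a = self._chain(12, chain="A")
        b = self._chain(5, chain="B")
        part = hr.assign_partners(a, b)
        assert part.ligand is b and part.receptor is a
        part = hr.assign_partners(b, a)
        assert part.ligand is b and part.receptor is a

    def test_residue_tie_broken_by_atom_count(self):
        a = hr.make_toy_protein(hr.ToySpec(4, "extended", 0, ("TRP",), chain_id="A"))
        b = hr.make_toy_protein(hr.ToySpec(4, "extended", 0, ("GLY",), chain_id="B"))
        part = hr.assign_partners(b, a)  # GLY chain has fewer atoms
        assert part.ligand is b and part.receptor is a

    def test_full_tie_keeps_input_order(self):
        a = self._chain(4, chain="A")
        b = self._chain(4, chain="B")
        part = hr.assign_partners(a, b)
        assert part.receptor is a

    def test_overlapping_chain_ids_rejected(self):
        a = self._chain(4, chain="A")
        b = self._chain(3, chain="A")
        with pytest.raises(ValueError, match="chain ids"):
            hr.assign_partners(a, b)


class TestRigidTransforms:
    def test_identity_leaves_coordinates(self, all20_peptide):
        out = hr.apply_transform(all20_peptide, hr.RigidTransform.identity())
        np.testing.assert_array_equal(out.coords, all20_peptide.coords)

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="reflection"):
            hr.RigidTransform(R, np.zeros(3))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_isometry_and_inverse(self, seed, all20_peptide):
        t = random_rigid(np.random.default_rng(seed))
        moved = hr.apply_transform(all20_peptide, t)
        d0 = np.linalg.norm(all20_peptide.coords[None] - all20_peptide.coords[:, None], axis=-1)
        d1 = np.linalg.norm(moved.coords[None] - moved.coords[:, None], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)
        back = hr.apply_transform(moved, t.inverse())
        np.testing.assert_allclose(back.coords, all20_peptide.coords, atol=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_composition_matches_sequential_application(self, seed, all20_peptide):
        rng = np.random.default_rng(seed)
        t1, t2 = random_rigid(rng), random_rigid(rng)
        seq = hr.apply_transform(hr.apply_transform(all20_peptide, t1), t2)
        once = hr.apply_transform(all20_peptide, t2.compose(t1))
        np.testing.assert_allclose(once.coords, seq.coords, atol=1e-9)


class TestDecoyTransformTable:
    def test_round_trip_and_order(self, tmp_path, rng):
        decoys = [
            hr.DecoyTransform(f"d{k}", random_rigid(rng)) for k in range(100)
        ]
        decoys[0] = hr.DecoyTransform("d0", hr.RigidTransform.identity())
        p = tmp_path / "decoys.tsv"
        hr.write_decoy_transforms(decoys, p)
        back = hr.read_decoy_transforms(p)
        assert [d.decoy_id for d in back] == [d.decoy_id for d in decoys]
        np.testing.assert_array_equal(back[0].transform.rotation, np.eye(3))
        for a, b in zip(back, decoys):
            np.testing.assert_allclose(a.transform.rotation, b.transform.rotation, atol=1e-8)
            np.testing.assert_allclose(a.transform.translation, b.transform.translation, atol=1e-8)

    def test_reflection_row_names_decoy(self, tmp_path):
        p = tmp_path / "bad.tsv"
        cols = "decoy_id\tr11\tr12\tr13\tr21\tr22\tr23\tr31\tr32\tr33\tt1\tt2\tt3\n"
        p.write_text(cols + "mirror\t1\t0\t0\t0\t1\t0\t0\t0\t-1\t0\t0\t0\n")
        with pytest.raises(ValueError, match="mirror"):
            hr.read_decoy_transforms(p)
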