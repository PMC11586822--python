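"""Structure I/O: PDB/XYZ parsing, coarse-graining, topology sidecars,
complex writing and round-trips."""

import numpy as np
import pytest

import graphbnc as g
from graphbnc.geometry import rotation_about_axis
from graphbnc.structures import AtomRecord


def _multi_model_pdb(tmp_path):
    lines = []
    for m, x in ((1, 1.0), (2, 2.0), (3, 3.0)):
        lines.append(f"MODEL     {m:4d}")
        lines.append(f"ATOM      1  CA  GLY A   1    {x:8.3f}{0.0:8.3f}{0.0:8.3f}"
                     f"  1.00  0.00           C")
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "mm.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadProtein:
    def test_three_residue_fixture(self, three_residue_pdb):
        atoms = g.read_protein(three_residue_pdb)
        cp = g.extract_coarse_protein(atoms)
        assert len(cp) == 3
        assert [name for _, _, name in cp.residue_labels] == ["GLY", "ALA", "ARG"]
        np.testing.assert_allclose(cp.ca_coords[0], [1.45, 0.0, 0.0])

    def test_multi_model_selects_requested_model(self, tmp_path):
        path = _multi_model_pdb(tmp_path)
        atoms = g.read_protein(path, model_index=1)
        assert atoms[0].coords[0] == pytest.approx(2.0)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            g.read_protein(tmp_path / "absent.pdb")

    def test_residue_without_ca_excluded_with_warning(self, three_residue_pdb,
                                                      caplog):
        text = three_residue_pdb.read_text()
        # strip the CA line of residue 2
        text = "\n".join(l for l in text.split("\n") if " CA  ALA" not in l)
        path = three_residue_pdb.parent / "noca.pdb"
        path.write_text(text)
        with caplog.at_level("WARNING"):
            cp = g.extract_coarse_protein(g.read_protein(path))
        assert len(cp) == 2
        assert all(name != "ALA" for _, _, name in cp.residue_labels)
        assert any("no CA" in r.message for r in caplog.records)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(
            "ATOM      1  CA AGLY A   1       1.000   0.000   0.000  0.40  0.00"
            "           C\n"
            "ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.60  0.00"
            "           C\n"
            "ATOM      3  CA  GLY A   2       4.500   0.000   0.000  1.00  0.00"
            "           C\nEND\n")
        cp = g.extract_coarse_protein(g.read_protein(path))
        assert cp.ca_coords[0][0] == pytest.approx(9.0)


class TestExtractCoarseProtein:
    def test_chain_then_residue_ordering(self):
        atoms = []
        for chain in ("B", "A"):
            for resid in (2, 1):
                atoms.append(AtomRecord("C", [resid * 5.0, 10.0 * (chain == "B"), 0],
                                        resid, "GLY", chain, "CA"))
        cp = g.extract_coarse_protein(atoms)
        assert [(c, r) for c, r, _ in cp.residue_labels] == \
            [("A", 1), ("A", 2), ("B", 1), ("B", 2)]

    def test_no_ca_anywhere_is_an_error(self):
        atoms = [AtomRecord("N", [0, 0, 0], 1, "GLY", "A", "N")]
        with pytest.raises(ValueError):
            g.extract_coarse_protein(atoms)

    def test_idempotent_under_atom_permutation(self, three_residue_pdb):
        atoms = g.read_protein(three_residue_pdb)
        cp1 = g.extract_coarse_protein(atoms)
        cp2 = g.extract_coarse_protein(atoms[::-1])
        np.testing.assert_allclose(cp1.ca_coords, cp2.ca_coords)
        assert cp1.residue_labels == cp2.residue_labels


class TestCluster:
    def test_tetrahedral_head_centroids(self, tmp_path):
        # 4 single-atom heads at tetrahedron vertices
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         dtype=float) * 4.0
        g.write_xyz(tmp_path / "tet.xyz", ["O"] * 4, verts)
        topo = g.LigandTopology([g.Ligand([i], []) for i in range(4)])
        g.write_topology(tmp_path / "tet.json", topo)
        cm = g.read_cluster(tmp_path / "tet.xyz", tmp_path / "tet.json")
        np.testing.assert_allclose(cm.head_centroids, verts)

    def test_au25_shaped_cluster_parses_18_ligands(self, cluster, tmp_path):
        g.write_xyz(tmp_path / "c.xyz", cluster.model.elements, cluster.model.coords)
        g.write_topology(tmp_path / "c.json", cluster.model.topology)
        cm = g.read_cluster(tmp_path / "c.xyz", tmp_path / "c.json")
        assert cm.n_ligands == 18
        np.testing.assert_allclose(cm.coords, cluster.model.coords, atol=1e-5)

    def test_dangling_topology_index_raises(self, tmp_path):
        g.write_xyz(tmp_path / "one.xyz", ["O"], [[0.0, 0.0, 0.0]])
        g.write_topology(tmp_path / "bad.json",
                         g.LigandTopology([g.Ligand([9999], [])]))
        with pytest.raises(IndexError):
            g.read_cluster(tmp_path / "one.xyz", tmp_path / "bad.json")


class TestWriteComplex:
    @pytest.fixture()
    def tiny_system(self, three_residue_pdb):
        atoms = g.read_protein(three_residue_pdb)
        cm = g.ClusterModel(["O", "O"], np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]),
                            g.LigandTopology([g.Ligand([0], []), g.Ligand([1], [])]))
        return atoms, cm

    def _cluster_coords(self, path):
        atoms = g.read_protein(path)
        return np.array([a.coords for a in atoms if a.residue_name == "CLS"])

    def test_identity_pose_preserves_coordinates(self, tiny_system, tmp_path):
        atoms, cm = tiny_system
        g.write_complex(atoms, cm, g.RigidPose(), tmp_path / "c.pdb")
        np.testing.assert_allclose(self._cluster_coords(tmp_path / "c.pdb"),
                                   cm.coords, atol=1e-3)

    def test_pure_translation_shifts_x(self, tiny_system, tmp_path):
        atoms, cm = tiny_system
        pose = g.RigidPose(translation=np.array([1.0, 0.0, 0.0]))
        g.write_complex(atoms, cm, pose, tmp_path / "c.pdb")
        got = self._cluster_coords(tmp_path / "c.pdb")
        np.testing.assert_allclose(got[:, 0], cm.coords[:, 0] + 1.0, atol=1e-3)

    def test_rotation_about_z(self, tiny_system, tmp_path):
        atoms, cm = tiny_system
        pose = g.RigidPose(rotation=rotation_about_axis([0, 0, 1], np.pi / 2))
        g.write_complex(atoms, cm, pose, tmp_path / "c.pdb")
        got = self._cluster_coords(tmp_path / "c.pdb")
        np.testing.assert_allclose(got[0], [0.0, 1.0, 0.0], atol=1e-3)

    def test_non_orthonormal_rotation_rejected(self, tiny_system, tmp_path):
        atoms, cm = tiny_system
        with pytest.raises(ValueError):
            g.write_complex(atoms, cm, g.RigidPose(rotation=np.eye(3) * 2.0),
                            tmp_path / "c.pdb")

    def test_roundtrip_to_pdb_precision(self, protein, tmp_path):
        g.write_pdb(tmp_path / "p.pdb", protein.atoms[:50])
        back = g.read_protein(tmp_path / "p.pdb")
        orig = np.array([a.coords for a in protein.atoms[:50]])
        got = np.array([a.coords for a in back])
        np.testing.assert_allclose(got, orig, atol=5e-4)


class TestXYZ:
    def test_multiframe_roundtrip(self, tmp_path):
        frames = np.arange(2 * 3 * 3, dtype=float).reshape(2, 3, 3)
        g.write_xyz(tmp_path / "t.xyz", ["C", "N", "O"], frames)
        back = g.read_xyz(tmp_path / "t.xyz")
        assert len(back) == 2
        assert back[1][0] == ["C", "N", "O"]
        np.testing.assert_allclose(back[1][1], frames[1])
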