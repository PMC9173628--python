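import numpy as np
import pytest

from evbmech.structure import (Atom, PDBParseError, SelectionSpec, Structure,
                               StructureError, assess_reactive_geometry,
                               extract_subset, min_residue_distance, read_pdb,
                               write_pdb)

from conftest import make_structure


@pytest.fixture
def small_structure():
    return make_structure([
        ("N", "N", "ALA", 1, "A", (0.0, 0.0, 0.0), -0.4),
        ("CA", "C", "ALA", 1, "A", (1.458, 0.0, 0.0), 0.1),
        ("C", "C", "ALA", 1, "A", (2.1, 1.4, 0.0), 0.6),
        ("O", "O", "HOH", 2, "W", (5.0, 5.0, 5.0), -0.834),
        ("MG", "MG", "MG", 3, "W", (8.0, 1.0, -2.5), 2.0),
    ])


class TestPDBRoundTrip:
    def test_read_write_read_identity(self, small_structure, tmp_path):
        p1 = tmp_path / "a.pdb"
        p2 = tmp_path / "b.pdb"
        write_pdb(small_structure, p1)
        s1 = read_pdb(p1)
        write_pdb(s1, p2)
        s2 = read_pdb(p2)
        assert len(s1) == len(small_structure)
        for a, b in zip(s1.atoms, s2.atoms):
            assert a.name == b.name
            assert a.residue_name == b.residue_name
            assert a.residue_number == b.residue_number
            assert a.chain_id == b.chain_id
            assert np.allclose(a.position, b.position, atol=1e-9)

    def test_coordinates_preserved_to_pdb_precision(self, small_structure, tmp_path):
        p = tmp_path / "a.pdb"
        write_pdb(small_structure, p)
        s = read_pdb(p)
        assert np.allclose(s.coordinates, small_structure.coordinates, atol=5.01e-4)

    def test_gemmi_reads_our_output(self, small_structure, tmp_path):
        """Independent reader cross-check of the fixed-column writer."""
        gemmi = pytest.importorskip("gemmi")
        p = tmp_path / "a.pdb"
        write_pdb(small_structure, p)
        st = gemmi.read_structure(str(p))
        atoms = [(a.name, r.name, a.pos.x, a.pos.y, a.pos.z)
                 for model in st for ch in model for r in ch for a in r]
        assert len(atoms) == len(small_structure)
        for (name, resname, x, y, z), ours in zip(atoms, small_structure.atoms):
            assert name == ours.name
            assert resname == ours.residue_name
            assert np.allclose((x, y, z), ours.position, atol=1e-3)

    def test_ter_between_chains_and_end(self, small_structure, tmp_path):
        p = tmp_path / "a.pdb"
        write_pdb(small_structure, p)
        lines = p.read_text().splitlines()
        assert lines[-1] == "END"
        ter = [i for i, l in enumerate(lines) if l.startswith("TER")]
        assert len(ter) == 2  # chain A → W transition plus the final TER

    def test_single_atom_file(self, tmp_path):
        s = make_structure([("CA", "C", "GLY", 1, "A", (1.0, 2.0, 3.0))])
        p = tmp_path / "one.pdb"
        write_pdb(s, p)
        text = p.read_text()
        assert sum(1 for l in text.splitlines() if l.startswith("ATOM")) == 1


class TestPDBErrors:
    def test_malformed_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1      12.3A4   0.000   0.000  1.00  0.00           C\n")
        with pytest.raises(PDBParseError, match="line 1"):
            read_pdb(p)

    def test_no_atom_records(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(StructureError, match="no ATOM/HETATM"):
            read_pdb(p)

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(OSError):
            read_pdb(tmp_path / "does-not-exist.pdb")


class TestAltloc:
    def _write(self, tmp_path, occ_a, occ_b):
        p = tmp_path / "alt.pdb"
        p.write_text(
            f"ATOM      1  CA AGLY A   1       0.000   0.000   0.000{occ_a:6.2f}  0.00           C\n"
            f"ATOM      2  CA BGLY A   1       1.000   0.000   0.000{occ_b:6.2f}  0.00           C\n"
            "END\n")
        return p

    def test_highest_occupancy_wins(self, tmp_path):
        s = read_pdb(self._write(tmp_path, 0.3, 0.7))
        assert len(s) == 1
        assert s.atoms[0].position[0] == pytest.approx(1.0)

    def test_tie_broken_by_altloc_letter(self, tmp_path):
        s = read_pdb(self._write(tmp_path, 0.5, 0.5))
        assert len(s) == 1
        assert s.atoms[0].position[0] == pytest.approx(0.0)  # conformer A


class TestResidueDistance:
    def test_three_four_five_triangle(self, triangle_structure):
        assert min_residue_distance(triangle_structure, ("A", 1), ("A", 2)) == pytest.approx(5.0)

    def test_symmetric(self, triangle_structure):
        d1 = min_residue_distance(triangle_structure, ("A", 1), ("B", 3))
        d2 = min_residue_distance(triangle_structure, ("B", 3), ("A", 1))
        assert d1 == pytest.approx(d2)

    def test_self_distance_zero(self, triangle_structure):
        assert min_residue_distance(triangle_structure, ("A", 1), ("A", 1)) == 0.0

    def test_triangle_inequality(self, triangle_structure):
        d12 = min_residue_distance(triangle_structure, ("A", 1), ("A", 2))
        d23 = min_residue_distance(triangle_structure, ("A", 2), ("B", 3))
        d13 = min_residue_distance(triangle_structure, ("A", 1), ("B", 3))
        assert d13 <= d12 + d23 + 1e-12

    def test_missing_residue_named(self, triangle_structure):
        with pytest.raises(StructureError, match="A:99"):
            min_residue_distance(triangle_structure, ("A", 99), ("A", 1))

    def test_heavy_only_excludes_hydrogens(self):
        s = make_structure([
            ("CA", "C", "GLY", 1, "A", (0.0, 0.0, 0.0)),
            ("HA", "H", "GLY", 1, "A", (3.0, 0.0, 0.0)),
            ("CA", "C", "GLY", 2, "A", (5.0, 0.0, 0.0)),
        ])
        assert min_residue_distance(s, ("A", 1), ("A", 2), heavy_only=True) == pytest.approx(5.0)
        assert min_residue_distance(s, ("A", 1), ("A", 2), heavy_only=False) == pytest.approx(2.0)


class TestReactiveGeometry:
    @pytest.mark.parametrize("x,expected_ok", [(3.1, True), (4.5, True), (6.0, False)])
    def test_threshold_inclusive(self, x, expected_ok):
        s = make_structure([
            ("C11", "C", "THF", 1, "S", (0.0, 0.0, 0.0)),
            ("C4N", "C", "NAD", 2, "S", (x, 0.0, 0.0)),
        ])
        ok, d = assess_reactive_geometry(s, ("S", 1, "C11"), ("S", 2, "C4N"), 4.5)
        assert ok is expected_ok
        assert d == pytest.approx(x)

    def test_missing_atom(self, triangle_structure):
        with pytest.raises(StructureError, match="not found"):
            assess_reactive_geometry(triangle_structure, ("A", 1, "CB"), ("A", 2, "CA"), 4.5)


class TestSelection:
    def test_chain_filter(self, triangle_structure):
        sub = extract_subset(triangle_structure, SelectionSpec(chain="B"))
        assert [a.chain_id for a in sub.atoms] == ["B"]

    def test_empty_criteria_rejected(self):
        with pytest.raises(StructureError, match="criterion"):
            SelectionSpec()

    def test_sphere_nesting_monotone(self, two_mg_fixture):
        s = two_mg_fixture.structure
        center = tuple(two_mg_fixture.reactive_midpoint)
        radii = [3.0, 6.0, 9.0, 12.0]
        counts = [len(extract_subset(s, SelectionSpec(sphere_center=center, sphere_radius=r)))
                  for r in radii]
        assert counts == sorted(counts)
        small = {a.serial for a in extract_subset(
            s, SelectionSpec(sphere_center=center, sphere_radius=6.0)).atoms}
        big = {a.serial for a in extract_subset(
            s, SelectionSpec(sphere_center=center, sphere_radius=9.0)).atoms}
        assert small <= big

    def test_sphere_radius_positive(self):
        with pytest.raises(StructureError):
            SelectionSpec(sphere_center=(0, 0, 0), sphere_radius=-1.0)

    def test_conjunctive(self, triangle_structure):
        sub = extract_subset(triangle_structure,
                             SelectionSpec(chain="A", residue_numbers=frozenset({2})))
        assert len(sub) == 1
        assert sub.atoms[0].residue_number == 2
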