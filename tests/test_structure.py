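"""Structure model: PDB I/O, parameterization, side-chain construction,
interface selection and mutation primitives."""
import math

import numpy as np
import pytest

from surfcraft import (build_side_chain, make_ideal_helix, merge,
                       mutate_positions, parameterize, read_pdb,
                       remove_binder, select_interface, write_pdb)
from surfcraft.geometry import bond_angle, dihedral, virtual_cbeta
from surfcraft import params as P
from surfcraft.structure import AtomRecord, Structure

GLY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.40  0.00           C
ATOM      3  CA BALA A   1       1.400   0.100   0.000  0.60  0.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
"""

BLANK_ELEMENT_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00
"""


def _write(tmp_path, text, name="x.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPdb:
    def test_minimal_glycine(self, tmp_path):
        s = read_pdb(_write(tmp_path, GLY_PDB))
        assert len(s) == 3
        assert s.residue_ids() == [("A", 1)]
        assert [a.name for a in s.atoms] == ["N", "CA", "C"]

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        s = read_pdb(_write(tmp_path, ALTLOC_PDB))
        cas = [a for a in s.atoms if a.name == "CA"]
        assert len(cas) == 1
        assert np.isclose(cas[0].coord[0], 1.400)  # the 0.60-occupancy B

    def test_blank_element_inferred(self, tmp_path):
        s = read_pdb(_write(tmp_path, BLANK_ELEMENT_PDB))
        assert s.atom("A", 1, "CA").element == "C"
        assert s.atom("A", 1, "N").element == "N"

    def test_empty_file_raises(self, tmp_path):
        with pytest.raises(ValueError):
            read_pdb(_write(tmp_path, "REMARK nothing\n"))

    def test_roundtrip_preserves_names_numbering_coords(self, tmp_path):
        full = merge(*__import__("surfcraft").make_two_helix_complex(0))
        path = tmp_path / "c.pdb"
        write_pdb(full, path)
        back = read_pdb(path)
        assert len(back) == len(full)
        for a, b in zip(full.atoms, back.atoms):
            assert (a.name, a.residue_index, a.chain_id, a.residue_type) == \
                (b.name, b.residue_index, b.chain_id, b.residue_type)
        assert np.abs(back.coords() - full.coords()).max() < 1e-3


class TestParameterize:
    def test_ca_radius_is_table_carbon(self):
        ps = parameterize(make_ideal_helix("AKA"))
        assert ps.atom("A", 2, "CA").radius == P.element_radii()["C"]

    @pytest.mark.parametrize("seq,resi,expected", [
        ("AAA", 2, 0.0),    # internal alanine is neutral
        ("AKA", 2, 1.0),    # lysine carries +1
        ("ADA", 2, -1.0),   # aspartate carries -1
    ])
    def test_residue_charge_sums_match_formal(self, seq, resi, expected):
        ps = parameterize(make_ideal_helix(seq))
        total = sum(a.charge for a in ps.residue_atoms("A", resi))
        assert math.isclose(total, expected, abs_tol=1e-6)

    def test_every_standard_residue_sums_to_formal_charge(self):
        formal = P.formal_charges()
        seq = "".join(P.THREE_TO_ONE[r] for r in P.STANDARD_RESIDUES)
        ps = parameterize(make_ideal_helix(seq))
        for i, r in enumerate(P.STANDARD_RESIDUES, start=1):
            total = sum(a.charge for a in ps.residue_atoms("A", i))
            assert math.isclose(total, formal[r], abs_tol=1e-6), r

    def test_unknown_residue_raises(self, tmp_path):
        bad = GLY_PDB.replace("GLY", "LIG")
        p = tmp_path / "lig.pdb"
        p.write_text(bad)
        # non-standard residues are dropped at parse time -> empty file error
        with pytest.raises(ValueError):
            parameterize(read_pdb(p))

    def test_unknown_atom_raises(self):
        s = make_ideal_helix("AA")
        s.atoms[0].name = "XX"
        with pytest.raises(ValueError, match="unknown atom"):
            parameterize(Structure(s.atoms))


class TestBuildSideChain:
    N = np.array([-0.525, 1.363, 0.0])
    CA = np.zeros(3)
    C = np.array([1.526, 0.0, 0.0])

    def test_alanine_cb_at_ideal_bond_length(self):
        (name, elem, cb), = build_side_chain("ALA", self.N, self.CA, self.C)
        assert name == "CB" and elem == "C"
        assert abs(np.linalg.norm(cb - self.CA) - 1.521) < 1e-6

    def test_glycine_empty(self):
        assert build_side_chain("GLY", self.N, self.CA, self.C) == []

    @pytest.mark.parametrize("res,chi", [
        ("SER", (60.0,)), ("LEU", (-60.0, 180.0)),
        ("ARG", (-60.0, 180.0, 60.0, 180.0)), ("THR", (-175.0,)),
    ])
    def test_chi_round_trip(self, res, chi):
        coords = {"N": self.N, "CA": self.CA, "C": self.C}
        for name, _, pos in build_side_chain(res, self.N, self.CA, self.C,
                                             chi):
            coords[name] = pos
        topo = P.sidechain_topology()[res]
        measured = []
        for row in topo:
            if row.dihedral.startswith("chi") and row.dihedral[3:].isdigit():
                measured.append(dihedral(coords[row.dihedral_ref],
                                         coords[row.angle_ref],
                                         coords[row.parent],
                                         coords[row.atom]))
        wrapped = (np.array(measured) - np.array(chi) + 180.0) % 360.0 - 180.0
        assert np.allclose(wrapped, 0.0, atol=1e-6)

    def test_all_bond_lengths_match_table(self):
        for res in P.STANDARD_RESIDUES:
            chi = tuple([-60.0] * P.n_chi()[res])
            coords = {"N": self.N, "CA": self.CA, "C": self.C}
            for name, _, pos in build_side_chain(res, self.N, self.CA,
                                                 self.C, chi):
                coords[name] = pos
            for row in P.sidechain_topology()[res]:
                d = np.linalg.norm(coords[row.atom] - coords[row.parent])
                assert abs(d - row.bond) < 1e-6, (res, row.atom)

    def test_chi_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="chi"):
            build_side_chain("SER", self.N, self.CA, self.C, (60.0, 70.0))

    def test_virtual_cbeta_deterministic_ideal(self):
        cb1 = virtual_cbeta(self.N, self.CA, self.C)
        cb2 = virtual_cbeta(self.N, self.CA, self.C)
        assert np.array_equal(cb1, cb2)
        assert abs(np.linalg.norm(cb1 - self.CA) - 1.521) < 1e-9
        assert abs(bond_angle(self.N, self.CA, cb1) - 110.5) < 1e-9


class TestMutatePositions:
    def test_lysine_to_alanine(self):
        s = make_ideal_helix("AKA")
        out = mutate_positions(s, {("A", 2): ("ALA", ())})
        names = sorted(a.name for a in out.residue_atoms("A", 2))
        assert names == ["C", "CA", "CB", "N", "O"]
        for name in ("N", "CA", "C", "O"):
            assert np.array_equal(out.atom("A", 2, name).coord,
                                  s.atom("A", 2, name).coord)

    def test_untouched_residues_bit_identical(self):
        s = make_ideal_helix("AKA")
        out = mutate_positions(s, {("A", 2): ("ALA", ())})
        for resi in (1, 3):
            for a, b in zip(s.residue_atoms("A", resi),
                            out.residue_atoms("A", resi)):
                assert np.array_equal(a.coord, b.coord)

    def test_leucine_chi_round_trip(self):
        s = make_ideal_helix("AAA")
        out = mutate_positions(s, {("A", 2): ("LEU", (-60.0, 180.0))})
        from surfcraft.structure import measure_chi
        assert np.allclose(measure_chi(out, "A", 2), (-60.0, 180.0),
                           atol=1e-6)

    def test_missing_position_raises(self):
        s = make_ideal_helix("AAA")
        with pytest.raises(KeyError):
            mutate_positions(s, {("A", 9): ("ALA", ())})

    def test_parameterization_carried_through(self):
        ps = parameterize(make_ideal_helix("AAA"))
        out = mutate_positions(ps, {("A", 2): ("LYS",
                                               (-60.0, 180.0, 180.0, 180.0))})
        total = sum(a.charge for a in out.residue_atoms("A", 2))
        assert math.isclose(total, 1.0, abs_tol=1e-6)


class TestRemoveBinder:
    def test_remove_one_chain(self, toy_complex):
        target, binder = toy_complex
        full = merge(target, binder)
        only_a = remove_binder(full, ["B"])
        assert set(c for c, _ in only_a.residue_ids()) == {"A"}
        assert len(only_a) == len(target)

    def test_remove_nothing_is_identity(self, toy_complex):
        target, _ = toy_complex
        out = remove_binder(target, [])
        assert len(out) == len(target)
        assert np.array_equal(out.coords(), target.coords())

    def test_remove_all_raises(self, toy_complex):
        target, _ = toy_complex
        with pytest.raises(ValueError, match="empty"):
            remove_binder(target, ["A"])

    def test_unknown_chain_raises(self, toy_complex):
        target, _ = toy_complex
        with pytest.raises(KeyError):
            remove_binder(target, ["Z"])


def _residue_pair(distance, face_angle=0.0):
    """Two alanine-like residues with CB-CB along x at the given distance;
    the second residue's CA-CB direction is rotated by face_angle degrees
    away from pointing back at the first."""
    def res(chain, idx, origin, flip):
        ca = origin
        direction = np.array([1.0, 0.0, 0.0]) * (1 if not flip else -1)
        a = np.deg2rad(face_angle if flip else 0.0)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        cb = ca + 1.521 * (rot @ direction)
        n = ca + np.array([0.0, 1.458, 0.0])
        c = ca + np.array([0.0, -1.0, 1.1])
        o = c + np.array([0.0, -1.0, 0.3])
        mk = lambda name, el, xyz: AtomRecord(name, el, xyz, idx, "ALA",
                                              chain, radius=1.7, charge=0.0)
        return [mk("N", "N", n), mk("CA", "C", ca), mk("C", "C", c),
                mk("O", "O", o), mk("CB", "C", cb)]
    from surfcraft.structure import ParameterizedStructure
    first = ParameterizedStructure(res("A", 1, np.zeros(3), False))
    second = ParameterizedStructure(
        res("B", 1, np.array([distance + 2 * 1.521, 0.0, 0.0]), True))
    return first, second


class TestSelectInterface:
    def test_facing_pair_within_cutoff_selected(self):
        a, b = _residue_pair(5.0)  # CB-CB = 5 Å
        sel = select_interface(a, b, cutoff=7.0)
        assert sel.positions == [("A", 1)]

    def test_outside_cutoff_not_selected(self):
        a, b = _residue_pair(8.0)
        # CB-CB distance is 8 Å here by construction
        cb_a = a.atom("A", 1, "CB").coord
        cb_b = b.atom("B", 1, "CB").coord
        assert abs(np.linalg.norm(cb_a - cb_b) - 8.0) < 1e-9
        assert select_interface(a, b, cutoff=7.0).positions == []

    def test_pointing_away_not_selected(self):
        a, b = _residue_pair(6.0, face_angle=180.0)
        sel = select_interface(b, a, cutoff=20.0)
        assert sel.positions == []

    def test_rigid_transform_leaves_selection_unchanged(self, toy_complex):
        from scipy.spatial.transform import Rotation
        target, binder = toy_complex
        sel = select_interface(target, binder)
        rot = Rotation.from_euler("zyx", [17, -39, 121],
                                  degrees=True).as_matrix()
        t = np.array([3.0, -7.0, 11.0])
        sel2 = select_interface(target.transformed(rot, t),
                                binder.transformed(rot, t))
        assert sel.positions == sel2.positions

    def test_cysteines_flagged(self):
        from surfcraft import make_two_helix_complex
        target, binder = make_two_helix_complex(
            seed=0, interface_aas=("LEU", "CYS", "ASP"))
        sel = select_interface(target, binder)
        assert ("A", 7) in sel.cysteine_positions
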