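"""Protein structure representation, PDB I/O, parameterization and the
fixed-backbone mutation primitives.

A :class:`Structure` is an ordered list of heavy-atom records grouped into
residues keyed by ``(chain_id, residue_index)``.  Only the 20 standard amino
acids are modelled; hydrogens, waters and heteroatoms are excluded.
"""
from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from . import params
from .geometry import bond_angle, dihedral, place_atom, virtual_cbeta

__all__ = [
    "AtomRecord", "Structure", "ParameterizedStructure", "InterfaceSelection",
    "read_pdb", "write_pdb", "parameterize", "select_interface",
    "mutate_positions", "build_side_chain", "remove_binder", "measure_chi",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class AtomRecord:
    """One heavy atom: PDB name, element, position and physical parameters.

    ``radius`` (Å) and ``charge`` (e) are NaN until :func:`parameterize`
    assigns them from the packaged table.
    """
    name: str
    element: str
    coord: np.ndarray
    residue_index: int
    residue_type: str
    chain_id: str
    radius: float = math.nan
    charge: float = math.nan

    def copy(self) -> "AtomRecord":
        return replace(self, coord=self.coord.copy())


class Structure:
    """Ordered heavy-atom collection with residue/chain topology."""

    def __init__(self, atoms: list[AtomRecord]):
        self.atoms = list(atoms)
        self._index: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self._index.setdefault((a.chain_id, a.residue_index), []).append(i)

    # ------------------------------------------------------------ access
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for c, i in self._index:
            out.setdefault(c, []).append(i)
        for c in out:
            out[c] = sorted(out[c])
        return out

    def residue_ids(self) -> list[tuple[str, int]]:
        return list(self._index)

    def residue_atoms(self, chain_id: str, residue_index: int) -> list[AtomRecord]:
        try:
            idx = self._index[(chain_id, residue_index)]
        except KeyError:
            raise KeyError(f"no residue {chain_id}:{residue_index}") from None
        return [self.atoms[i] for i in idx]

    def residue_type(self, chain_id: str, residue_index: int) -> str:
        return self.residue_atoms(chain_id, residue_index)[0].residue_type

    def atom(self, chain_id: str, residue_index: int, name: str) -> AtomRecord:
        for a in self.residue_atoms(chain_id, residue_index):
            if a.name == name:
                return a
        raise KeyError(f"no atom {name} in {chain_id}:{residue_index}")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def copy(self) -> "Structure":
        return type(self)([a.copy() for a in self.atoms])

    def backbone_complete(self, chain_id: str, residue_index: int) -> bool:
        names = {a.name for a in self.residue_atoms(chain_id, residue_index)}
        return all(n in names for n in BACKBONE_ATOMS)

    def cbeta(self, chain_id: str, residue_index: int) -> np.ndarray:
        """Real C-beta coordinate, or the ideal virtual one for glycine."""
        res = self.residue_atoms(chain_id, residue_index)
        for a in res:
            if a.name == "CB":
                return a.coord
        frame = {a.name: a.coord for a in res}
        try:
            return virtual_cbeta(frame["N"], frame["CA"], frame["C"])
        except KeyError:
            raise ValueError(
                f"missing backbone atoms at {chain_id}:{residue_index}"
            ) from None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.copy()
        for a in out.atoms:
            a.coord = rotation @ a.coord + translation
        return out


class ParameterizedStructure(Structure):
    """A Structure in which every atom carries a radius and partial charge."""

    def __init__(self, atoms: list[AtomRecord]):
        super().__init__(atoms)
        for a in self.atoms:
            if math.isnan(a.radius) or math.isnan(a.charge):
                raise ValueError(f"atom {a.name} lacks radius/charge")


@dataclass
class InterfaceSelection:
    """Residues at a protein-protein interface by the C-beta rule."""
    positions: list[tuple[str, int]]
    cb_cutoff: float = 7.0
    orientation_rule: bool = True
    cysteine_positions: list[tuple[str, int]] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "positions": [list(p) for p in self.positions],
            "cb_cutoff": self.cb_cutoff,
            "orientation_rule": self.orientation_rule,
            "cysteine_positions": [list(p) for p in self.cysteine_positions],
        }


# ---------------------------------------------------------------- PDB I/O

def read_pdb(path) -> Structure:
    """Read a PDB file into a Structure.

    Keeps only standard amino-acid ATOM records; waters and heteroatoms are
    dropped.  For alternate locations the highest-occupancy conformer is
    kept (ties resolved to the alphabetically first altloc).
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            if res.name not in params.STANDARD_RESIDUES:
                continue
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                if at.is_hydrogen():
                    continue
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                elif at.altloc == prev.altloc:
                    raise ValueError(
                        f"duplicate atom {at.name} in {chain.name}:"
                        f"{res.seqid.num}")
                elif (at.occ, -ord(at.altloc or "A")) > (
                        prev.occ, -ord(prev.altloc or "A")):
                    by_name[at.name] = at
            for at in by_name.values():
                elem = at.element.name.upper()
                if elem in ("", "X"):
                    elem = _infer_element(at.name)
                atoms.append(AtomRecord(
                    name=at.name, element=elem,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_index=res.seqid.num, residue_type=res.name,
                    chain_id=chain.name))
    if not atoms:
        raise ValueError(f"no standard-residue ATOM records in {path}")
    return Structure(atoms)


def _infer_element(name: str) -> str:
    name = name.strip()
    if name.startswith(("SD", "SG")):
        return "S"
    return {"O": "O", "N": "N"}.get(name[0], "C" if name[0] == "C" else name[0])


def write_pdb(s: Structure, path) -> None:
    st = gemmi.Structure()
    st.name = "surfcraft"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for (chain_id, idx) in s.residue_ids():
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        res_atoms = s.residue_atoms(chain_id, idx)
        res = gemmi.Residue()
        res.name = res_atoms[0].residue_type
        res.seqid = gemmi.SeqId(idx, " ")
        for a in res_atoms:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coord)
            at.occ = 1.0
            res.add_atom(at)
        chains[chain_id].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# --------------------------------------------------------- parameterization

def parameterize(s: Structure, table: str = "default") -> ParameterizedStructure:
    """Assign van der Waals radii and partial charges from the packaged table.

    Raises on any residue or atom name absent from the table (e.g. ligands,
    terminal OXT).
    """
    if table != "default":
        raise ValueError(f"unknown parameter table {table!r}")
    charges = params.atom_charges()
    radii = params.element_radii()
    atoms = []
    for a in s.atoms:
        if a.residue_type not in params.STANDARD_RESIDUES:
            raise ValueError(f"unknown residue {a.residue_type}")
        try:
            elem, q = charges[(a.residue_type, a.name)]
        except KeyError:
            raise ValueError(
                f"unknown atom {a.name} in residue {a.residue_type}") from None
        b = a.copy()
        b.element = elem
        b.charge = q
        b.radius = radii[elem]
        atoms.append(b)
    return ParameterizedStructure(atoms)


# ------------------------------------------------------ interface selection

def select_interface(target: Structure, binder: Structure,
                     cutoff: float = 7.0) -> InterfaceSelection:
    """Interface residues of ``target``: C-beta within ``cutoff`` Å of any
    binder C-beta and the CA->CB vector pointing toward the binder (angle
    with CA->nearest-binder-atom below 90 degrees).

    Glycines use an ideal-geometry virtual C-beta.  Cysteines are selected
    but flagged for downstream exclusion.
    """
    if len(target) == 0 or len(binder) == 0:
        raise ValueError("empty structure")
    from scipy.spatial import cKDTree

    binder_cb = np.array([binder.cbeta(c, i) for c, i in binder.residue_ids()])
    binder_xyz = binder.coords()
    tree_cb = cKDTree(binder_cb)
    tree_all = cKDTree(binder_xyz)
    positions: list[tuple[str, int]] = []
    cys: list[tuple[str, int]] = []
    for (chain_id, idx) in target.residue_ids():
        if not target.backbone_complete(chain_id, idx):
            raise ValueError(f"missing backbone atoms at {chain_id}:{idx}")
        cb = target.cbeta(chain_id, idx)
        d, _ = tree_cb.query(cb)
        if d > cutoff:
            continue
        ca = target.atom(chain_id, idx, "CA").coord
        _, j = tree_all.query(ca)
        to_binder = binder_xyz[j] - ca
        if np.dot(cb - ca, to_binder) <= 0:
            continue
        positions.append((chain_id, idx))
        if target.residue_type(chain_id, idx) == "CYS":
            cys.append((chain_id, idx))
    return InterfaceSelection(positions=positions, cb_cutoff=cutoff,
                              cysteine_positions=cys)


# ------------------------------------------------- side-chain construction

def build_side_chain(residue_type: str, n: np.ndarray, ca: np.ndarray,
                     c: np.ndarray, chi: tuple[float, ...] = ()
                     ) -> list[tuple[str, str, np.ndarray]]:
    """Ideal-geometry side-chain atoms (name, element, coord) for a backbone
    frame, built by internal-coordinate placement at the given chi angles.

    Glycine returns an empty list.  Chi count must match the residue's
    rotatable-bond count.
    """
    if residue_type not in params.STANDARD_RESIDUES:
        raise ValueError(f"unknown residue {residue_type}")
    expected = params.n_chi()[residue_type]
    if len(chi) != expected:
        raise ValueError(
            f"{residue_type} takes {expected} chi angles, got {len(chi)}")
    topo = params.sidechain_topology()[residue_type]
    coords: dict[str, np.ndarray] = {"N": np.asarray(n, float),
                                     "CA": np.asarray(ca, float),
                                     "C": np.asarray(c, float)}
    out: list[tuple[str, str, np.ndarray]] = []
    for row in topo:
        pos = place_atom(coords[row.dihedral_ref], coords[row.angle_ref],
                         coords[row.parent], row.bond, row.angle,
                         row.resolve_dihedral(chi))
        coords[row.atom] = pos
        out.append((row.atom, row.element, pos))
    return out


def measure_chi(s: Structure, chain_id: str, residue_index: int
                ) -> tuple[float, ...]:
    """Chi dihedrals of a residue as built/read, following the packaged
    topology definitions."""
    res = {a.name: a.coord for a in s.residue_atoms(chain_id, residue_index)}
    rtype = s.residue_type(chain_id, residue_index)
    topo = params.sidechain_topology()[rtype]
    chis: list[float] = []
    coords = dict(res)
    for row in topo:
        if row.dihedral.startswith("chi") and "+" not in row.dihedral \
                and not row.dihedral[3:].lstrip("0123456789"):
            chis.append(dihedral(coords[row.dihedral_ref],
                                 coords[row.angle_ref], coords[row.parent],
                                 coords[row.atom]))
    return tuple(chis)


def mutate_positions(s: Structure,
                     assignments: dict[tuple[str, int],
                                       tuple[str, tuple[float, ...]]]
                     ) -> Structure:
    """Replace side chains at the given positions with ideal-geometry side
    chains of the assigned residue type at the assigned chi angles.

    Backbone atoms (N, CA, C, O) are untouched; atoms outside the assigned
    residues are bit-identical to the input.  If ``s`` is parameterized the
    result is too (new atoms get table radii/charges).
    """
    parameterized = isinstance(s, ParameterizedStructure)
    charges = params.atom_charges()
    radii = params.element_radii()
    new_atoms: list[AtomRecord] = []
    for (chain_id, idx) in s.residue_ids():
        res = s.residue_atoms(chain_id, idx)
        if (chain_id, idx) not in assignments:
            new_atoms.extend(a.copy() for a in res)
            continue
        rtype, chi = assignments[(chain_id, idx)]
        frame = {a.name: a.coord for a in res if a.name in BACKBONE_ATOMS}
        if not all(k in frame for k in ("N", "CA", "C")):
            raise ValueError(f"missing backbone atoms at {chain_id}:{idx}")
        for a in res:
            if a.name in BACKBONE_ATOMS:
                b = a.copy()
                b.residue_type = rtype
                if parameterized:
                    elem, q = charges[(rtype, a.name)]
                    b.charge = q
                    b.radius = radii[elem]
                new_atoms.append(b)
        for (name, elem, pos) in build_side_chain(
                rtype, frame["N"], frame["CA"], frame["C"], tuple(chi)):
            rec = AtomRecord(name=name, element=elem, coord=pos,
                             residue_index=idx, residue_type=rtype,
                             chain_id=chain_id)
            if parameterized:
                elem2, q = charges[(rtype, name)]
                rec.charge = q
                rec.radius = radii[elem2]
            new_atoms.append(rec)
    for pos in assignments:
        if pos not in s._index:
            raise KeyError(f"position {pos} absent from structure")
    return type(s)(new_atoms)


def remove_binder(complex_structure: Structure,
                  binder_chains: list[str] | tuple[str, ...] | set[str]
                  ) -> Structure:
    """Drop the named chains without touching remaining coordinates."""
    binder_chains = set(binder_chains)
    present = set(c for c, _ in complex_structure.residue_ids())
    unknown = binder_chains - present
    if unknown:
        raise KeyError(f"unknown chain id(s) {sorted(unknown)}")
    kept = [a.copy() for a in complex_structure.atoms
            if a.chain_id not in binder_chains]
    if not kept:
        raise ValueError("empty structure after binder removal")
    return type(complex_structure)(kept)


def merge(*structures: Structure) -> Structure:
    """Concatenate structures (chains must not collide)."""
    seen: set[tuple[str, int]] = set()
    atoms: list[AtomRecord] = []
    for s in structures:
        for rid in s.residue_ids():
            if rid in seen:
                raise ValueError(f"duplicate residue {rid} while merging")
            seen.add(rid)
        atoms.extend(a.copy() for a in s.atoms)
    cls = Structure
    if all(isinstance(s, ParameterizedStructure) for s in structures):
        cls = ParameterizedStructure
    return cls(atoms)
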