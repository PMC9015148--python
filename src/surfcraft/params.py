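"""Packaged physical parameter tables.

One self-contained, internally consistent parameter set ships with the
package as TSV files: per-element van der Waals radii, heavy-atom partial
charges that sum to each residue's formal charge, ideal side-chain
internal-coordinate topology, and a coarse backbone-independent rotamer
library (canonical chi bins at -60/60/180 degrees, at most 9 rotamers per
residue, uniform priors).
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "STANDARD_RESIDUES",
    "DESIGN_RESIDUES",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "element_radii",
    "atom_charges",
    "formal_charges",
    "n_chi",
    "sidechain_topology",
    "rotamer_library",
    "TopologyRow",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("surfcraft.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


@functools.lru_cache(maxsize=None)
def _residues() -> pd.DataFrame:
    return _read("residues.tsv")


@functools.lru_cache(maxsize=None)
def element_radii() -> dict[str, float]:
    df = _read("element_radii.tsv")
    return dict(zip(df["element"], df["radius"].astype(float)))


@functools.lru_cache(maxsize=None)
def atom_charges() -> dict[tuple[str, str], tuple[str, float]]:
    """(residue, atom name) -> (element, partial charge / e)."""
    df = _read("atom_charges.tsv")
    return {(r, a): (e, float(q)) for r, a, e, q in
            zip(df["residue"], df["atom"], df["element"], df["charge"])}


@functools.lru_cache(maxsize=None)
def formal_charges() -> dict[str, int]:
    df = _residues()
    return dict(zip(df["residue"], df["formal_charge"].astype(int)))


@functools.lru_cache(maxsize=None)
def n_chi() -> dict[str, int]:
    df = _residues()
    return dict(zip(df["residue"], df["n_chi"].astype(int)))


@dataclass(frozen=True)
class TopologyRow:
    atom: str
    element: str
    parent: str
    angle_ref: str
    dihedral_ref: str
    bond: float
    angle: float
    dihedral: str  # fixed angle in degrees, or "chiN[+/-offset]"

    def resolve_dihedral(self, chi: tuple[float, ...]) -> float:
        spec = self.dihedral
        if spec.startswith("chi"):
            rest = spec[3:]
            offset = 0.0
            for sign in ("+", "-"):
                if sign in rest[1:]:
                    idx = rest.index(sign, 1)
                    offset = float(rest[idx:])
                    rest = rest[:idx]
                    break
            return chi[int(rest) - 1] + offset
        return float(spec)


@functools.lru_cache(maxsize=None)
def sidechain_topology() -> dict[str, tuple[TopologyRow, ...]]:
    df = _read("sidechain_topology.tsv")
    topo: dict[str, list[TopologyRow]] = {r: [] for r in STANDARD_RESIDUES}
    for row in df.itertuples(index=False):
        topo[row.residue].append(TopologyRow(
            row.atom, row.element, row.parent, row.angle_ref,
            row.dihedral_ref, float(row.bond), float(row.angle),
            str(row.dihedral)))
    return {r: tuple(v) for r, v in topo.items()}


@functools.lru_cache(maxsize=None)
def rotamer_library() -> dict[str, tuple[tuple[tuple[float, ...], float], ...]]:
    """residue -> ((chi tuple, prior probability), ...)."""
    df = _read("rotamers.tsv")
    lib: dict[str, list[tuple[tuple[float, ...], float]]] = {}
    for row in df.itertuples(index=False):
        chis = tuple(float(c) for c in (row.chi1, row.chi2, row.chi3,
                                        row.chi4) if pd.notna(c))
        lib.setdefault(row.residue, []).append((chis, float(row.prob)))
    return {r: tuple(v) for r, v in lib.items()}


STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
# the 19 design alphabet residues (cysteine excluded throughout the
# benchmarks because disulfide formation makes its surface non-local)
DESIGN_RESIDUES = tuple(r for r in STANDARD_RESIDUES if r != "CYS")

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}
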