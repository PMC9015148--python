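"""Dev script: generate the packaged parameter TSVs under src/surfcraft/data.

Run from repo root:  python scripts/generate_parameter_tables.py
"""
import os

OUT = os.path.join(os.path.dirname(__file__), "..", "src", "surfcraft", "data")

# ---------------------------------------------------------------- radii
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# ------------------------------------------------------------ charges
# Heavy-atom effective partial charges (no hydrogens modelled); per-residue
# sums equal the formal charge exactly.
BACKBONE = [("N", -0.47), ("CA", 0.47), ("C", 0.51), ("O", -0.51)]

SIDE_CHARGES = {
    "ALA": [("CB", 0.0)],
    "GLY": [],
    "SER": [("CB", 0.25), ("OG", -0.25)],
    "THR": [("CB", 0.25), ("OG1", -0.25), ("CG2", 0.0)],
    "CYS": [("CB", 0.10), ("SG", -0.10)],
    "VAL": [("CB", 0.0), ("CG1", 0.0), ("CG2", 0.0)],
    "LEU": [("CB", 0.0), ("CG", 0.0), ("CD1", 0.0), ("CD2", 0.0)],
    "ILE": [("CB", 0.0), ("CG1", 0.0), ("CG2", 0.0), ("CD1", 0.0)],
    "MET": [("CB", 0.0), ("CG", 0.06), ("SD", -0.12), ("CE", 0.06)],
    "PRO": [("CB", 0.0), ("CG", 0.0), ("CD", 0.0)],
    "PHE": [("CB", 0.0), ("CG", 0.0), ("CD1", 0.0), ("CD2", 0.0),
            ("CE1", 0.0), ("CE2", 0.0), ("CZ", 0.0)],
    "TYR": [("CB", 0.0), ("CG", 0.0), ("CD1", 0.0), ("CD2", 0.0),
            ("CE1", 0.0), ("CE2", 0.0), ("CZ", 0.25), ("OH", -0.25)],
    "TRP": [("CB", 0.0), ("CG", 0.0), ("CD1", 0.15), ("CD2", 0.0),
            ("NE1", -0.30), ("CE2", 0.15), ("CE3", 0.0), ("CZ2", 0.0),
            ("CZ3", 0.0), ("CH2", 0.0)],
    "ASP": [("CB", 0.0), ("CG", 0.36), ("OD1", -0.68), ("OD2", -0.68)],
    "GLU": [("CB", 0.0), ("CG", 0.0), ("CD", 0.36), ("OE1", -0.68),
            ("OE2", -0.68)],
    "ASN": [("CB", 0.0), ("CG", 0.55), ("OD1", -0.55), ("ND2", 0.0)],
    "GLN": [("CB", 0.0), ("CG", 0.0), ("CD", 0.55), ("OE1", -0.55),
            ("NE2", 0.0)],
    "LYS": [("CB", 0.0), ("CG", 0.0), ("CD", 0.0), ("CE", 0.25),
            ("NZ", 0.75)],
    "ARG": [("CB", 0.0), ("CG", 0.0), ("CD", 0.20), ("NE", -0.40),
            ("CZ", 0.60), ("NH1", 0.30), ("NH2", 0.30)],
    "HIS": [("CB", 0.0), ("CG", 0.10), ("ND1", -0.30), ("CD2", 0.20),
            ("CE1", 0.30), ("NE2", -0.30)],
}

FORMAL = {r: 0 for r in SIDE_CHARGES}
FORMAL.update({"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1})

# ------------------------------------------------ side-chain topology
# Z-matrix rows: atom, parent, angle_ref, dihedral_ref, bond, angle, dihedral
# dihedral is a number (degrees) or "chiN[+/-offset]".
# CB is implicit (placed from the backbone frame) and listed first with
# parent CA / refs N, C and fixed improper dihedral -122.6.
CB = ("CB", "CA", "N", "C", 1.521, 110.5, "-122.6")

TOPOLOGY = {
    "ALA": [CB],
    "GLY": [],
    "SER": [CB, ("OG", "CB", "CA", "N", 1.417, 110.8, "chi1")],
    "CYS": [CB, ("SG", "CB", "CA", "N", 1.808, 113.8, "chi1")],
    "THR": [CB, ("OG1", "CB", "CA", "N", 1.433, 109.6, "chi1"),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, "chi1-120")],
    "VAL": [CB, ("CG1", "CB", "CA", "N", 1.527, 110.5, "chi1"),
            ("CG2", "CB", "CA", "N", 1.527, 110.5, "chi1+120")],
    "LEU": [CB, ("CG", "CB", "CA", "N", 1.530, 116.3, "chi1"),
            ("CD1", "CG", "CB", "CA", 1.521, 110.7, "chi2"),
            ("CD2", "CG", "CB", "CA", 1.521, 110.7, "chi2+120")],
    "ILE": [CB, ("CG1", "CB", "CA", "N", 1.530, 110.4, "chi1"),
            ("CG2", "CB", "CA", "N", 1.521, 110.5, "chi1-120"),
            ("CD1", "CG1", "CB", "CA", 1.513, 113.8, "chi2")],
    "MET": [CB, ("CG", "CB", "CA", "N", 1.520, 114.1, "chi1"),
            ("SD", "CG", "CB", "CA", 1.803, 112.7, "chi2"),
            ("CE", "SD", "CG", "CB", 1.791, 100.9, "chi3")],
    "PRO": [CB, ("CG", "CB", "CA", "N", 1.492, 104.5, "30"),
            ("CD", "CG", "CB", "CA", 1.503, 106.1, "-35")],
    "PHE": [CB, ("CG", "CB", "CA", "N", 1.502, 113.8, "chi1"),
            ("CD1", "CG", "CB", "CA", 1.384, 120.8, "chi2"),
            ("CD2", "CG", "CB", "CA", 1.384, 120.8, "chi2+180"),
            ("CE1", "CD1", "CG", "CB", 1.382, 120.8, "180"),
            ("CE2", "CD2", "CG", "CB", 1.382, 120.8, "180"),
            ("CZ", "CE1", "CD1", "CG", 1.372, 120.1, "0")],
    "TYR": [CB, ("CG", "CB", "CA", "N", 1.502, 113.8, "chi1"),
            ("CD1", "CG", "CB", "CA", 1.384, 120.8, "chi2"),
            ("CD2", "CG", "CB", "CA", 1.384, 120.8, "chi2+180"),
            ("CE1", "CD1", "CG", "CB", 1.382, 120.8, "180"),
            ("CE2", "CD2", "CG", "CB", 1.382, 120.8, "180"),
            ("CZ", "CE1", "CD1", "CG", 1.372, 120.1, "0"),
            ("OH", "CZ", "CE1", "CD1", 1.376, 119.9, "180")],
    "TRP": [CB, ("CG", "CB", "CA", "N", 1.498, 113.6, "chi1"),
            ("CD1", "CG", "CB", "CA", 1.365, 126.9, "chi2"),
            ("CD2", "CG", "CB", "CA", 1.433, 126.6, "chi2+180"),
            ("NE1", "CD1", "CG", "CB", 1.374, 110.2, "180"),
            ("CE2", "CD2", "CG", "CB", 1.409, 107.2, "180"),
            ("CE3", "CD2", "CG", "CB", 1.398, 133.9, "0"),
            ("CZ2", "CE2", "CD2", "CG", 1.394, 122.4, "180"),
            ("CZ3", "CE3", "CD2", "CG", 1.382, 118.6, "180"),
            ("CH2", "CZ2", "CE2", "CD2", 1.368, 117.5, "180")],
    "ASP": [CB, ("CG", "CB", "CA", "N", 1.516, 112.6, "chi1"),
            ("OD1", "CG", "CB", "CA", 1.249, 118.4, "chi2"),
            ("OD2", "CG", "CB", "CA", 1.249, 118.4, "chi2+180")],
    "ASN": [CB, ("CG", "CB", "CA", "N", 1.516, 112.6, "chi1"),
            ("OD1", "CG", "CB", "CA", 1.231, 120.8, "chi2"),
            ("ND2", "CG", "CB", "CA", 1.328, 116.4, "chi2+180")],
    "GLU": [CB, ("CG", "CB", "CA", "N", 1.520, 114.1, "chi1"),
            ("CD", "CG", "CB", "CA", 1.516, 112.6, "chi2"),
            ("OE1", "CD", "CG", "CB", 1.249, 118.4, "chi3"),
            ("OE2", "CD", "CG", "CB", 1.249, 118.4, "chi3+180")],
    "GLN": [CB, ("CG", "CB", "CA", "N", 1.520, 114.1, "chi1"),
            ("CD", "CG", "CB", "CA", 1.516, 112.6, "chi2"),
            ("OE1", "CD", "CG", "CB", 1.231, 120.8, "chi3"),
            ("NE2", "CD", "CG", "CB", 1.328, 116.4, "chi3+180")],
    "LYS": [CB, ("CG", "CB", "CA", "N", 1.520, 114.1, "chi1"),
            ("CD", "CG", "CB", "CA", 1.520, 111.3, "chi2"),
            ("CE", "CD", "CG", "CB", 1.520, 111.3, "chi3"),
            ("NZ", "CE", "CD", "CG", 1.489, 111.9, "chi4")],
    "ARG": [CB, ("CG", "CB", "CA", "N", 1.520, 114.1, "chi1"),
            ("CD", "CG", "CB", "CA", 1.520, 111.3, "chi2"),
            ("NE", "CD", "CG", "CB", 1.461, 112.0, "chi3"),
            ("CZ", "NE", "CD", "CG", 1.329, 124.2, "chi4"),
            ("NH1", "CZ", "NE", "CD", 1.326, 120.0, "0"),
            ("NH2", "CZ", "NE", "CD", 1.326, 120.0, "180")],
    "HIS": [CB, ("CG", "CB", "CA", "N", 1.504, 113.8, "chi1"),
            ("ND1", "CG", "CB", "CA", 1.378, 122.7, "chi2"),
            ("CD2", "CG", "CB", "CA", 1.354, 131.0, "chi2+180"),
            ("CE1", "ND1", "CG", "CB", 1.321, 109.0, "180"),
            ("NE2", "CD2", "CG", "CB", 1.374, 107.2, "180")],
}

N_CHI = {"ALA": 0, "GLY": 0, "PRO": 0, "SER": 1, "CYS": 1, "THR": 1,
         "VAL": 1, "ILE": 2, "LEU": 2, "ASP": 2, "ASN": 2, "HIS": 2,
         "PHE": 2, "TYR": 2, "TRP": 2, "MET": 3, "GLU": 3, "GLN": 3,
         "LYS": 4, "ARG": 4}

ONE = {"ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
       "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
       "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
       "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}

ELEMENT_OF = lambda name: ("S" if name.startswith("S") and name != "SER" else
                           name[0])


def atom_element(name):
    if name.startswith(("SD", "SG")):
        return "S"
    if name.startswith("O"):
        return "O"
    if name.startswith("N"):
        return "N"
    return "C"


def main():
    os.makedirs(OUT, exist_ok=True)

    with open(os.path.join(OUT, "element_radii.tsv"), "w") as f:
        f.write("element\tradius\n")
        for e, r in ELEMENT_RADII.items():
            f.write(f"{e}\t{r}\n")

    with open(os.path.join(OUT, "residues.tsv"), "w") as f:
        f.write("residue\tone_letter\tformal_charge\tn_chi\n")
        for r in sorted(SIDE_CHARGES):
            f.write(f"{r}\t{ONE[r]}\t{FORMAL[r]}\t{N_CHI[r]}\n")

    with open(os.path.join(OUT, "atom_charges.tsv"), "w") as f:
        f.write("residue\tatom\telement\tcharge\n")
        for r in sorted(SIDE_CHARGES):
            rows = BACKBONE + SIDE_CHARGES[r]
            total = sum(q for _, q in rows)
            assert abs(total - FORMAL[r]) < 1e-9, (r, total)
            for name, q in rows:
                elem = "N" if name == "N" else "O" if name == "O" else \
                    atom_element(name) if name not in ("CA", "C") else "C"
                f.write(f"{r}\t{name}\t{elem}\t{q:.2f}\n")

    with open(os.path.join(OUT, "sidechain_topology.tsv"), "w") as f:
        f.write("residue\tatom\telement\tparent\tangle_ref\tdihedral_ref"
                "\tbond\tangle\tdihedral\n")
        for r in sorted(TOPOLOGY):
            for (name, p, a, d, bond, ang, dih) in TOPOLOGY[r]:
                f.write(f"{r}\t{name}\t{atom_element(name)}\t{p}\t{a}\t{d}"
                        f"\t{bond}\t{ang}\t{dih}\n")

    # rotamer library: canonical chi bins -60/60/180 per rotatable bond,
    # capped at 9 rotamers (chi1 x chi2 grid; chi3+ fixed at 180), uniform
    # priors.
    bins = (-60.0, 60.0, 180.0)
    with open(os.path.join(OUT, "rotamers.tsv"), "w") as f:
        f.write("residue\tchi1\tchi2\tchi3\tchi4\tprob\n")
        for r in sorted(N_CHI):
            k = N_CHI[r]
            if k == 0:
                rots = [()]
            elif k == 1:
                rots = [(b,) for b in bins]
            else:
                rots = [(b1, b2) + (180.0,) * (k - 2)
                        for b1 in bins for b2 in bins]
            p = 1.0 / len(rots)
            for rot in rots:
                cells = [f"{c:.1f}" for c in rot] + [""] * (4 - len(rot))
                f.write(f"{r}\t" + "\t".join(cells) + f"\t{p:.10f}\n")

    print("tables written to", OUT)


if __name__ == "__main__":
    main()
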