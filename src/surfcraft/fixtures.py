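"""Deterministic generators for every synthetic input the package needs:
ideal-geometry helices, toy two-chain complexes with designed interfaces,
perturbed structures and clouds, analytic sphere clouds, and labeled
(S_S, E_S) score datasets with the benchmark dataset's 1:18 native to
non-native structure.

Every generator is a pure function of its arguments and seed.
"""
from __future__ import annotations

import numpy as np

from . import params
from .geometry import place_atom
from .structure import (AtomRecord, ParameterizedStructure, Structure,
                        build_side_chain, parameterize, select_interface)
from .surface import SurfaceCloud
from .weights import DEFAULT_WEIGHTS, LabeledScoreRecord, WeightSet

__all__ = ["make_ideal_helix", "make_two_helix_complex", "jitter",
           "jitter_cloud", "sphere_cloud", "make_score_dataset"]

# ideal backbone geometry (lengths Å, angles degrees)
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_A = {"N-CA-C": 110.0, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5}


def make_ideal_helix(sequence: str, phi: float = -57.0, psi: float = -47.0,
                     chain_id: str = "A", start_index: int = 1) -> Structure:
    """Ideal-geometry peptide backbone at fixed (phi, psi) with side chains
    at the first library rotamer.  Defaults give a standard alpha helix.
    """
    if not sequence:
        raise ValueError("empty sequence")
    try:
        three = [params.ONE_TO_THREE[c] for c in sequence]
    except KeyError as exc:
        raise ValueError(f"invalid residue code {exc.args[0]!r}") from None
    lib = params.rotamer_library()
    n_res = len(three)
    bb: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        if i == 0:
            n = np.zeros(3)
            ca = np.array([_B["N-CA"], 0.0, 0.0])
            c = place_atom(np.array([-1.0, 1.0, 0.0]), n, ca,
                           _B["CA-C"], _A["N-CA-C"], 150.0)
        else:
            prev = bb[i - 1]
            n = place_atom(prev["N"], prev["CA"], prev["C"],
                           _B["C-N"], _A["CA-C-N"], psi)
            ca = place_atom(prev["CA"], prev["C"], n,
                            _B["N-CA"], _A["C-N-CA"], 180.0)  # omega trans
            c = place_atom(prev["C"], n, ca,
                           _B["CA-C"], _A["N-CA-C"], phi)
        bb.append({"N": n, "CA": ca, "C": c})
    atoms: list[AtomRecord] = []
    for i, rtype in enumerate(three):
        idx = start_index + i
        frame = bb[i]
        # carbonyl O anti to the next amide N (psi + 180 about CA-C)
        o = place_atom(frame["N"], frame["CA"], frame["C"],
                       _B["C-O"], _A["CA-C-O"], psi + 180.0)
        for name, elem, pos in (("N", "N", frame["N"]),
                                ("CA", "C", frame["CA"]),
                                ("C", "C", frame["C"]), ("O", "O", o)):
            atoms.append(AtomRecord(name, elem, pos.copy(), idx, rtype,
                                    chain_id))
        chi = lib[rtype][0][0]
        for name, elem, pos in build_side_chain(
                rtype, frame["N"], frame["CA"], frame["C"], chi):
            atoms.append(AtomRecord(name, elem, pos, idx, rtype, chain_id))
    return Structure(atoms)


def _helix_axis_frame(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit axis) of a helix from its CA trace."""
    cas = np.array([s.atom(c, i, "CA").coord for c, i in s.residue_ids()])
    center = cas.mean(axis=0)
    u, _, vt = np.linalg.svd(cas - center)
    axis = vt[0]
    if np.dot(cas[-1] - cas[0], axis) < 0:
        axis = -axis
    return center, axis


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def make_two_helix_complex(seed: int = 0,
                           interface_aas: tuple[str, str, str] =
                           ("LEU", "LYS", "ASP"),
                           target_length: int = 11,
                           ) -> tuple[ParameterizedStructure,
                                      ParameterizedStructure]:
    """Toy two-chain complex: an 11-residue target helix facing an
    anti-parallel poly-alanine binder helix, placed so that at least three
    target residues (carrying ``interface_aas``) satisfy the 7 Å C-beta
    interface rule.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    iface_pos = (4, 7, 8)  # same helical face (i, i+3, i+4)
    seq = ["ALA"] * target_length
    for p, aa in zip(iface_pos, interface_aas):
        seq[p - 1] = aa
    one = "".join(params.THREE_TO_ONE[r] for r in seq)
    target = make_ideal_helix(one, chain_id="A")
    binder0 = make_ideal_helix("A" * target_length, chain_id="B",
                               start_index=101)

    t_center, t_axis = _helix_axis_frame(target)
    # direction from the helix axis toward the mean interface C-beta
    cbs = np.array([target.cbeta("A", p) for p in iface_pos])
    v = cbs.mean(axis=0) - t_center
    v -= np.dot(v, t_axis) * t_axis
    v /= np.linalg.norm(v)

    b_center, b_axis = _helix_axis_frame(binder0)
    jitter_d = rng.uniform(-0.3, 0.3)
    jitter_roll = rng.uniform(-10.0, 10.0)
    tp = parameterize(target)
    r_flip = _rotation(v, 180.0)  # anti-parallel about the contact normal
    from scipy.spatial import cKDTree
    t_tree = cKDTree(tp.coords())
    for d in (9.5 + jitter_d, 10.0 + jitter_d, 10.5 + jitter_d,
              9.0 + jitter_d, 11.0 + jitter_d):
        for k in range(12):
            roll = jitter_roll + 30.0 * k
            rot = _rotation(-t_axis, roll) @ r_flip
            moved = binder0.transformed(
                np.eye(3), -b_center).transformed(rot, np.zeros(3))
            moved = moved.transformed(np.eye(3), t_center + d * v)
            bp = parameterize(moved)
            sel = select_interface(tp, bp)
            if len(sel.positions) >= 3 and all(
                    ("A", p) in sel.positions for p in iface_pos):
                # reject clashing placements
                dmin = t_tree.query(bp.coords())[0].min()
                if dmin > 3.0:
                    return tp, bp
    raise RuntimeError("no feasible two-helix placement found")


def jitter(structure: Structure, sigma: float, seed: int) -> Structure:
    """I.i.d. Gaussian displacement of every atom; deterministic per seed."""
    rng = np.random.default_rng(seed)
    out = structure.copy()
    noise = rng.normal(0.0, sigma, size=(len(out.atoms), 3))
    for a, dx in zip(out.atoms, noise):
        a.coord = a.coord + dx
    return out


def sphere_cloud(n: int = 500, radius: float = 5.0,
                 center: np.ndarray | None = None,
                 density: float | None = None) -> SurfaceCloud:
    """Deterministic Fibonacci-lattice sphere cloud with radial normals."""
    if n < 1:
        raise ValueError("n must be positive")
    center = np.zeros(3) if center is None else np.asarray(center, float)
    i = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r_xy = np.sqrt(np.maximum(1 - z ** 2, 0.0))
    normals = np.stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z],
                       axis=1)
    pts = center + radius * normals
    dens = density if density is not None else n / (4 * np.pi * radius ** 2)
    return SurfaceCloud(points=pts, normals=normals, probe_radius=0.0,
                        density=dens)


def jitter_cloud(cloud: SurfaceCloud, sigma: float, seed: int
                 ) -> SurfaceCloud:
    """Displace cloud points by i.i.d. Gaussian noise (normals kept)."""
    rng = np.random.default_rng(seed)
    from dataclasses import replace
    return replace(cloud,
                   points=cloud.points + rng.normal(0, sigma,
                                                    cloud.points.shape))


# ---------------------------------------------------------- score dataset

def _sigmoid(s: np.ndarray, e: np.ndarray, w: WeightSet) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(w.b0 + w.b_ss * s + w.b_es * e))


def _draw_base(n: int, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray]:
    """Base (S_S, E_S) feature distribution of candidate substitutions.

    A small native-like component (high S_S, strongly negative E_S) plus a
    broad non-native background; the mixture weight is set so the marginal
    native probability under the default logistic model equals 1/19, the
    benchmark's native to non-native ratio.
    """
    p_native_like = 0.0346
    comp = rng.random(n) < p_native_like
    s = np.where(comp,
                 np.clip(1 - 0.08 * np.abs(rng.standard_normal(n)), 0, 1),
                 rng.beta(2, 2, n))
    e = np.where(comp,
                 np.clip(-1 + 0.25 * np.abs(rng.standard_normal(n)), -1, 1),
                 rng.uniform(-0.2, 1, n))
    return s, e


def _rejection(n_needed: int, want_native: bool, w: WeightSet,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    out_s: list[np.ndarray] = []
    out_e: list[np.ndarray] = []
    need = n_needed
    while need > 0:
        m = max(need * 25, 2000)
        s, e = _draw_base(m, rng)
        accept = rng.random(m) < _sigmoid(s, e, w)
        if not want_native:
            accept = ~accept
        out_s.append(s[accept][:need])
        out_e.append(e[accept][:need])
        need -= len(out_s[-1])
    return np.concatenate(out_s), np.concatenate(out_e)


def make_score_dataset(n_complexes_per_aa: int,
                       weights: WeightSet = DEFAULT_WEIGHTS,
                       noise: float = 0.0, seed: int = 0
                       ) -> list[LabeledScoreRecord]:
    """Labeled (S_S, E_S) records mirroring the benchmark dataset's shape:
    for each of the 19 design residue types and each of ``n`` pseudo
    complexes, one native and 18 non-native records, with features drawn so
    that class membership follows the given logistic weights.

    ``n = 140`` reproduces the 2,660 native / 47,880 non-native cardinality
    of the weight-fitting dataset; ``n = 100`` the 1,900 native cases of the
    single-amino-acid recovery benchmark.
    """
    if n_complexes_per_aa < 1:
        raise ValueError("need at least one complex per residue type")
    rng = np.random.default_rng(seed)
    n = n_complexes_per_aa
    aas = params.DESIGN_RESIDUES
    nat_s, nat_e = _rejection(19 * n, True, weights, rng)
    non_s, non_e = _rejection(18 * 19 * n, False, weights, rng)
    if noise > 0:
        nat_s = np.clip(nat_s + rng.normal(0, noise, nat_s.shape), 0, 1)
        nat_e = np.clip(nat_e + rng.normal(0, noise, nat_e.shape), -1, 1)
        non_s = np.clip(non_s + rng.normal(0, noise, non_s.shape), 0, 1)
        non_e = np.clip(non_e + rng.normal(0, noise, non_e.shape), -1, 1)
    records: list[LabeledScoreRecord] = []
    for ai, aa in enumerate(aas):
        for ci in range(n):
            cid = f"{aa}_{ci:04d}"
            k = ai * n + ci
            records.append(LabeledScoreRecord(
                s_s=float(nat_s[k]), e_s=float(nat_e[k]), is_native=True,
                complex_id=cid, residue_type=aa))
            base = (ai * n + ci) * 18
            for j, sub in enumerate(r for r in aas if r != aa):
                records.append(LabeledScoreRecord(
                    s_s=float(non_s[base + j]), e_s=float(non_e[base + j]),
                    is_native=False, complex_id=cid, residue_type=sub))
    return records
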