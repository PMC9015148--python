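"""Internal-coordinate geometry: atom placement, dihedrals, rigid frames.

All coordinates are in Ångström, all angles in degrees unless noted.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "place_atom",
    "dihedral",
    "bond_angle",
    "virtual_cbeta",
    "canonical_frame",
]

# Ideal backbone-frame parameters for the (virtual) C-beta atom.  Used both
# for real side-chain construction and for the glycine virtual C-beta of the
# interface rule.
CB_BOND = 1.521
CB_ANGLE = 110.5
CB_DIHEDRAL = -122.6  # improper dihedral C-N-CA-CB, L-amino-acid chirality


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dih: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = dih (NeRF construction).

    Parameters are the three reference positions (most distal last), the
    bond length in Å and the two angles in degrees.
    """
    angle_r = np.deg2rad(angle)
    dih_r = np.deg2rad(dih)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms for placement")
    n /= nn
    m = np.cross(n, bc)
    # local displacement in the (bc, m, n) frame
    d_local = np.array([
        -bond * np.cos(angle_r),
        bond * np.sin(angle_r) * np.cos(dih_r),
        bond * np.sin(angle_r) * np.sin(dih_r),
    ])
    rot = np.stack([bc, m, n], axis=1)
    return c + rot @ d_local


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.rad2deg(np.arctan2(y, x)))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = p0 - p1
    v = p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral C-beta position from the backbone N/CA/C frame.

    Deterministic; used for glycine in the C-beta interface rule and as the
    first atom of every constructed side chain.
    """
    return place_atom(c, n, ca, CB_BOND, CB_ANGLE, CB_DIHEDRAL)


def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-equivariant canonical frame of a point set.

    Returns (center, R) with R a right-handed 3x3 matrix whose rows are the
    canonical axes; canonical coordinates are (coords - center) @ R.T.
    Axes are covariance eigenvectors ordered by decreasing eigenvalue, each
    sign-fixed so the third moment of the projected coordinates is
    non-negative.  Rigidly transforming the input transforms the frame the
    same way, so downstream grid computations become rigid-equivariant.
    """
    coords = np.asarray(coords, dtype=float)
    center = coords.mean(axis=0)
    x = coords - center
    cov = x.T @ x / max(len(coords), 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    axes = v[:, order].T  # rows
    skews = np.empty(3)
    for i in range(3):
        proj = x @ axes[i]
        s = float(np.sum(proj ** 3))
        if s < 0:
            axes[i] = -axes[i]
            s = -s
        skews[i] = s
    if np.linalg.det(axes) < 0:
        # flip the axis whose sign is least constrained by the data
        i = int(np.argmin(skews))
        axes[i] = -axes[i]
    return center, axes
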