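"""Electrostatic potentials on surface points.

A screened-Coulomb (Debye–Hückel) model in a uniform dielectric: every
surface point receives

    phi_i = sum_j k_e * q_j * exp(-kappa * d_ij) / (eps_r * d_ij)

converted to kT/e at the model temperature.  The downstream electrostatic
similarity score consumes only linear and rank correlations of potentials
across matched points, which depend on the spatial pattern of the field
rather than its absolute magnitude, so a uniform-dielectric model is
adequate; no dielectric boundary or finite-difference solver is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .structure import ParameterizedStructure
from .surface import SurfaceCloud

__all__ = ["PotentialModel", "assign_potential", "COULOMB_CONSTANT",
           "BOLTZMANN_KCAL"]

COULOMB_CONSTANT = 332.06    # kcal Å mol^-1 e^-2
BOLTZMANN_KCAL = 0.0019872041  # kcal mol^-1 K^-1


@dataclass(frozen=True)
class PotentialModel:
    """Screened-Coulomb potential parameters.

    kappa = 0.113 Å^-1 corresponds to ~150 mM monovalent salt at 298 K;
    eps_r = 78.54 is bulk water.
    """
    model: str = "screened_coulomb"
    epsilon_r: float = 78.54
    kappa: float = 0.113
    temperature: float = 298.15

    def __post_init__(self):
        if self.model != "screened_coulomb":
            raise ValueError(f"unknown model {self.model!r}")
        if self.epsilon_r <= 0:
            raise ValueError("epsilon_r must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")

    @property
    def kt_kcal(self) -> float:
        return BOLTZMANN_KCAL * self.temperature


def assign_potential(cloud: SurfaceCloud, ps: ParameterizedStructure,
                     model: PotentialModel = PotentialModel()
                     ) -> SurfaceCloud:
    """Return a copy of ``cloud`` with per-point potentials in kT/e.

    Raises if any surface point coincides with an atom center — surface
    points are at least one van der Waals radius from their own atoms by
    construction, so a zero distance signals a geometry bug.
    """
    charges = np.array([a.charge for a in ps.atoms])
    centers = ps.coords()
    pts = cloud.points
    prefac = COULOMB_CONSTANT / (model.epsilon_r * model.kt_kcal)
    pot = np.zeros(len(pts))
    # chunked pairwise evaluation to bound memory
    chunk = max(1, int(4e6 / max(len(centers), 1)))
    for s in range(0, len(pts), chunk):
        d = np.linalg.norm(pts[s:s + chunk, None, :] - centers[None, :, :],
                           axis=2)
        if np.any(d < 1e-9):
            raise ValueError("surface point coincides with an atom center")
        pot[s:s + chunk] = prefac * (
            charges[None, :] * np.exp(-model.kappa * d) / d).sum(axis=1)
    return replace(cloud, potentials=pot)
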