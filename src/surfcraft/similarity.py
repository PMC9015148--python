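"""The surface scores: shape similarity S_S, electrostatic similarity E_S,
their logistic combination Surf_S, and shape complementarity S_C.

S_S compares outward normals of nearest point pairs between two clouds with
a Gaussian distance penalty, averaged over both matching directions and
clamped to [0, 1].  E_S is the sign-flipped mean of Pearson and Spearman
correlations of potentials over the matched pairs (so -1 means identical
fields, +1 perfectly anti-correlated, i.e. complementary).  Surf_S squashes
the two through a fitted logistic model.  S_C is S_S against the reference
cloud with inverted normals, so snugly complementary surfaces score high.

Both clouds are assumed to live in a common coordinate frame; no alignment
search is performed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .electrostatics import PotentialModel, assign_potential
from .structure import ParameterizedStructure
from .surface import (PatchSpec, SurfaceCloud, compute_ses_cloud,
                      extract_patch, nearest_pairs)
from .weights import DEFAULT_WEIGHTS, WeightSet, surf_score

__all__ = ["ShapeParams", "SimilarityResult", "shape_similarity",
           "shape_similarity_pointwise", "electrostatic_similarity",
           "shape_complementarity", "compare_surfaces", "surf_score"]


@dataclass(frozen=True)
class ShapeParams:
    """Distance weighting of the normal-vector comparison.

    ``w`` is the Gaussian falloff weight in Å^-2 applied to pair distances,
    after the Lawrence–Colman complementarity formulation; ``clamp`` clips
    the aggregate score into [0, 1].
    """
    w: float = 0.5
    clamp: bool = True

    def __post_init__(self):
        if self.w < 0:
            raise ValueError("w must be non-negative")


@dataclass
class SimilarityResult:
    s_s: float
    e_s: float
    e_s_pearson: float
    e_s_spearman: float
    surf_s: float
    n_pairs_ab: int
    n_pairs_ba: int
    median_pair_distance: float

    def to_json(self) -> dict:
        return {k: getattr(self, k) for k in
                ("s_s", "e_s", "e_s_pearson", "e_s_spearman", "surf_s",
                 "n_pairs_ab", "n_pairs_ba", "median_pair_distance")}


def _directional(a: SurfaceCloud, b: SurfaceCloud, w: float
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point similarity of a's points against nearest b points.

    Returns (per-point values, matched b indices, pair distances).
    """
    idx, d = nearest_pairs(a, b)
    dots = np.einsum("ij,ij->i", a.normals, b.normals[idx])
    return dots * np.exp(-w * d ** 2), idx, d


def shape_similarity_pointwise(target: SurfaceCloud, reference: SurfaceCloud,
                               p: ShapeParams = ShapeParams()
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Unclamped per-point similarity values for both matching directions."""
    va, _, _ = _directional(target, reference, p.w)
    vb, _, _ = _directional(reference, target, p.w)
    return va, vb


def shape_similarity(target: SurfaceCloud, reference: SurfaceCloud,
                     p: ShapeParams = ShapeParams()) -> float:
    """Symmetrized shape similarity S_S in [0, 1] (1 = identical shape)."""
    va, vb = shape_similarity_pointwise(target, reference, p)
    s = 0.5 * (float(va.mean()) + float(vb.mean()))
    if p.clamp:
        s = min(max(s, 0.0), 1.0)
    return s


def electrostatic_similarity(target: SurfaceCloud, reference: SurfaceCloud
                             ) -> tuple[float, float, float]:
    """E_S with its Pearson and Spearman components.

    Correlations are computed over the concatenation of both matching
    directions' potential pairs; E_S = -(pearson + spearman)/2, so -1 means
    identical fields.  Zero-variance potential vectors yield E_S = 0 with a
    warning (keeps the combined score defined on uncharged toys).
    """
    if target.potentials is None or reference.potentials is None:
        raise ValueError("both clouds need potentials")
    ia, _ = nearest_pairs(target, reference)
    ib, _ = nearest_pairs(reference, target)
    x = np.concatenate([target.potentials, target.potentials[ib]])
    y = np.concatenate([reference.potentials[ia], reference.potentials])
    if len(x) < 3:
        raise ValueError("fewer than 3 matched pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance potentials; E_S set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0, float("nan"), float("nan")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return -(pearson + spearman) / 2.0, pearson, spearman


def shape_complementarity(a: SurfaceCloud, b: SurfaceCloud,
                          p: ShapeParams = ShapeParams()) -> float:
    """S_C: shape similarity of ``a`` against ``b`` with inverted normals."""
    return shape_similarity(a, b.flipped_normals(), p)


def compare_surfaces(target_ps: ParameterizedStructure,
                     reference_ps: ParameterizedStructure,
                     target_patch: PatchSpec | None = None,
                     reference_patch: PatchSpec | None = None,
                     probe_radius: float = 1.4,
                     density: float = 3.0,
                     shape_params: ShapeParams = ShapeParams(),
                     potential_model: PotentialModel = PotentialModel(),
                     weights: WeightSet = DEFAULT_WEIGHTS
                     ) -> SimilarityResult:
    """End-to-end comparison: surfaces -> patches -> potentials -> scores."""
    tc = compute_ses_cloud(target_ps, probe_radius, density)
    rc = compute_ses_cloud(reference_ps, probe_radius, density)
    if target_patch is not None:
        tc = extract_patch(tc, target_patch)
    if reference_patch is not None:
        rc = extract_patch(rc, reference_patch)
    tc = assign_potential(tc, target_ps, potential_model)
    rc = assign_potential(rc, reference_ps, potential_model)

    va, _, da = _directional(tc, rc, shape_params.w)
    vb, _, db = _directional(rc, tc, shape_params.w)
    s_s = 0.5 * (float(va.mean()) + float(vb.mean()))
    if shape_params.clamp:
        s_s = min(max(s_s, 0.0), 1.0)
    e_s, pearson, spearman = electrostatic_similarity(tc, rc)
    return SimilarityResult(
        s_s=s_s, e_s=e_s, e_s_pearson=pearson, e_s_spearman=spearman,
        surf_s=surf_score(s_s, e_s, weights),
        n_pairs_ab=len(va), n_pairs_ba=len(vb),
        median_pair_distance=float(np.median(np.concatenate([da, db]))))
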