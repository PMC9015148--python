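"""Evaluation protocols: single-amino-acid recovery, all-vs-all mean-score
confusion matrix, interface sequence recovery, and complex grouping helpers.

The single-residue protocol captures the native residue's patch surface as
the comparison reference, substitutes each of the 19 design residue types
(cysteine excluded), scores the best clash-free rotamer of each against the
native surface, and counts success when the native type is the strict
unique maximum.  Interface recovery first converts the interface to alanine
(removing side-chain memory), then lets a design protocol rebuild it
against the native interface surface.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import params
from .design import (AnnealSchedule, DesignTask, PatchScorer, RotamerLibrary,
                     _candidate_clashes, design_mc, design_site_scan,
                     load_rotamer_library)
from .electrostatics import PotentialModel
from .similarity import ShapeParams
from .structure import ParameterizedStructure, mutate_positions, \
    select_interface
from .weights import DEFAULT_WEIGHTS, WeightSet, rank_candidates

__all__ = ["RecoveryCase", "RecoverySummary", "single_aa_recovery",
           "recovery_summary", "interface_recovery", "classify_complexity",
           "flexibility_fraction", "FLEXIBLE_RESIDUES"]

# residue types with access to diverse rotamer conformations (one-letter
# R, N, Q, E, H, K, M, W); the rest count as static
FLEXIBLE_RESIDUES = frozenset(
    {"ARG", "ASN", "GLN", "GLU", "HIS", "LYS", "MET", "TRP"})


@dataclass
class RecoveryCase:
    complex_id: str
    position: tuple[str, int]
    native: str
    mode: str                      # bound | unbound
    scores: dict[str, float]       # 19 residues -> best-rotamer score
    success: bool
    native_self_score: float       # native patch scored against itself


@dataclass
class RecoverySummary:
    rates: pd.Series               # per-residue-type recovery rate
    matrix: pd.DataFrame           # mean score, native x substituted
    n_cases: int
    diagonal_argmax: pd.Series     # row-wise argmax flags


def _scoring_kwargs(probe_radius, density, shape_params, potential_model,
                    weights):
    return dict(probe_radius=probe_radius, density=density,
                shape_params=shape_params, potential_model=potential_model,
                weights=weights)


def single_aa_recovery(target: ParameterizedStructure,
                       binder: ParameterizedStructure,
                       position: tuple[str, int],
                       mode: str = "bound",
                       library: RotamerLibrary | None = None,
                       complex_id: str = "",
                       probe_radius: float = 1.4, density: float = 3.0,
                       shape_params: ShapeParams = ShapeParams(),
                       potential_model: PotentialModel = PotentialModel(),
                       weights: WeightSet = DEFAULT_WEIGHTS
                       ) -> RecoveryCase:
    """Recovery of one interface residue from its surface alone.

    The native surface serves only as the scoring reference; each of the 19
    candidate residue types is rebuilt from ideal geometry and its best
    clash-free rotamer scored against that reference.  In unbound mode the
    binder is removed before any surface computation (it still never
    contributes its own patch points, but in bound mode it shapes the
    solvent-excluded surface and restricts rotamer space).
    """
    if mode not in ("bound", "unbound"):
        raise ValueError(f"unknown mode {mode!r}")
    position = tuple(position)
    native_aa = target.residue_type(*position)
    if native_aa == "CYS":
        raise ValueError("cysteine positions are skipped")
    library = library or load_rotamer_library()
    context = binder if mode == "bound" else None
    scorer = PatchScorer(
        reference=None, patch_residues={position}, objective="similarity",
        context=context, **_scoring_kwargs(probe_radius, density,
                                           shape_params, potential_model,
                                           weights))
    reference = scorer.patch_cloud(target)
    scorer.reference = reference
    native_self = scorer.score(target)

    scores: dict[str, float] = {}
    for aa in params.DESIGN_RESIDUES:
        best = -np.inf
        for chis, _ in library[aa]:
            if _candidate_clashes(target, context, position, aa, chis):
                continue
            trial = mutate_positions(target, {position: (aa, chis)})
            best = max(best, scorer.score(trial))
        scores[aa] = best if np.isfinite(best) else np.nan
    ranked, unique_best = rank_candidates(
        {aa: (-np.inf if np.isnan(s) else s) for aa, s in scores.items()})
    success = unique_best and ranked[0][0] == native_aa
    return RecoveryCase(complex_id=complex_id, position=position,
                        native=native_aa, mode=mode, scores=scores,
                        success=success, native_self_score=native_self)


def recovery_summary(cases: list[RecoveryCase]) -> RecoverySummary:
    """Per-residue recovery rates and the 19x19 mean-score matrix.

    Matrix rows are native residue types, columns substituted types; the
    row-wise argmax marks which substitution looks most native-like on
    average.
    """
    if not cases:
        raise ValueError("no cases")
    aas = list(params.DESIGN_RESIDUES)
    succ: dict[str, list[bool]] = {}
    sums = pd.DataFrame(0.0, index=aas, columns=aas)
    counts = pd.DataFrame(0, index=aas, columns=aas)
    for c in cases:
        succ.setdefault(c.native, []).append(c.success)
        for aa, s in c.scores.items():
            if not np.isnan(s):
                sums.loc[c.native, aa] += s
                counts.loc[c.native, aa] += 1
    rates = pd.Series({aa: float(np.mean(v)) for aa, v in succ.items()})
    with np.errstate(invalid="ignore"):
        matrix = sums / counts.replace(0, np.nan)
    diag = pd.Series({aa: (matrix.loc[aa].idxmax() == aa)
                      for aa in matrix.index if matrix.loc[aa].notna().any()})
    return RecoverySummary(rates=rates, matrix=matrix, n_cases=len(cases),
                           diagonal_argmax=diag)


def interface_recovery(target: ParameterizedStructure,
                       binder: ParameterizedStructure,
                       protocol: str = "mc", mode: str = "bound",
                       seed: int = 0, cutoff: float = 7.0,
                       schedule: AnnealSchedule = AnnealSchedule(),
                       library: RotamerLibrary | None = None,
                       top_k: int = 3,
                       probe_radius: float = 1.4, density: float = 3.0,
                       shape_params: ShapeParams = ShapeParams(),
                       potential_model: PotentialModel = PotentialModel(),
                       weights: WeightSet = DEFAULT_WEIGHTS
                       ) -> tuple[float, pd.DataFrame]:
    """Interface sequence recovery after alanization.

    Selects the target interface by the C-beta rule (cysteines excluded),
    records the native surface of the interface patch, converts the
    interface to alanine and runs the chosen design protocol ("mc" or
    "site") with the native surface as reference.  Returns the fraction of
    positions whose final residue type matches the native, plus a
    per-position table.
    """
    if protocol not in ("mc", "site"):
        raise ValueError(f"unknown protocol {protocol!r}")
    sel = select_interface(target, binder, cutoff)
    positions = [p for p in sel.positions
                 if p not in set(sel.cysteine_positions)]
    if not positions:
        raise ValueError("empty interface")
    natives = {p: target.residue_type(*p) for p in positions}
    context = binder if mode == "bound" else None
    kwargs = _scoring_kwargs(probe_radius, density, shape_params,
                             potential_model, weights)
    ref_scorer = PatchScorer(reference=None, patch_residues=set(positions),
                             objective="similarity", context=context,
                             **kwargs)
    reference = ref_scorer.patch_cloud(target)

    alanized = mutate_positions(target, {p: ("ALA", ()) for p in positions})
    task = DesignTask(scaffold=alanized, designable=positions,
                      reference_surface=reference,
                      patch_residues=set(positions), schedule=schedule,
                      seed=seed, objective="similarity", context=context,
                      library=library, **kwargs)
    result = design_mc(task) if protocol == "mc" \
        else design_site_scan(task, top_k=top_k)
    rows = []
    hits = 0
    for p in positions:
        final_aa = result.final_structure.residue_type(*p)
        ok = final_aa == natives[p]
        hits += ok
        rows.append({"position": f"{p[0]}:{p[1]}", "native": natives[p],
                     "designed": final_aa, "recovered": ok})
    return hits / len(positions), pd.DataFrame(rows)


def classify_complexity(s_c: float) -> str:
    """Interface complexity class: 'low' below the 0.65 shape
    complementarity threshold, else 'high' (the boundary counts as high)."""
    if not 0.0 <= s_c <= 1.0:
        raise ValueError("s_c must be in [0, 1]")
    return "low" if s_c < 0.65 else "high"


def flexibility_fraction(residue_types: list[str]) -> tuple[float, str]:
    """Fraction of interface residues with flexible side chains and the
    resulting group label (Flexible at >= 40%, else Static)."""
    if not residue_types:
        raise ValueError("empty interface")
    for r in residue_types:
        if r not in params.STANDARD_RESIDUES:
            raise ValueError(f"non-standard residue {r}")
    frac = float(np.mean([r in FLEXIBLE_RESIDUES for r in residue_types]))
    return frac, ("Flexible" if frac >= 0.40 else "Static")
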