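"""Surface-guided sequence design.

Three sampling protocols share one scoring pathway:

* :func:`design_mc` — Monte-Carlo simulated annealing over (position,
  residue, rotamer) moves, accepted by the Metropolis criterion on the
  surface score (Surf_S against a reference surface, or shape
  complementarity S_C against a binder patch).
* :func:`design_site_scan` — every allowed (residue, rotamer) is scored
  independently at each position first; the top-k rotamers per position are
  then sampled combinatorially with the same annealer.
* :func:`ssm_scan` — computational site-saturation mutagenesis: per
  position and residue type, the best clash-free rotamer's interface shape
  complementarity.

Scoring is localized: only the surface over a bounding region around the
scored patch residues is regenerated after each move, which is equivalent
to full recomputation for the patch points because every surface point lies
within probe + max-radius of its owning atom.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import params
from .electrostatics import PotentialModel, assign_potential
from .similarity import ShapeParams, shape_complementarity, shape_similarity, \
    electrostatic_similarity
from .structure import (ParameterizedStructure, build_side_chain, merge,
                        mutate_positions, select_interface)
from .surface import PatchSpec, SurfaceCloud, compute_ses_cloud, extract_patch
from .weights import DEFAULT_WEIGHTS, WeightSet, surf_score

__all__ = ["RotamerLibrary", "AnnealSchedule", "DesignTask", "DesignResult",
           "ScanTable", "PatchScorer", "design_mc", "design_site_scan",
           "ssm_scan", "select_top", "load_rotamer_library"]

CLASH_FACTOR = 0.6  # hard clash: pair distance < 0.6 x sum of vdW radii


@dataclass
class RotamerLibrary:
    """Discrete side-chain conformations per residue type with priors."""
    rotamers: dict[str, tuple[tuple[tuple[float, ...], float], ...]]

    def __post_init__(self):
        nchi = params.n_chi()
        for res, rots in self.rotamers.items():
            total = sum(p for _, p in rots)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{res} rotamer priors sum to {total}")
            for chis, _ in rots:
                if len(chis) != nchi[res]:
                    raise ValueError(f"{res} chi count mismatch")

    def __getitem__(self, res: str):
        return self.rotamers[res]

    def __contains__(self, res: str) -> bool:
        return res in self.rotamers


def load_rotamer_library() -> RotamerLibrary:
    return RotamerLibrary(dict(params.rotamer_library()))


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule in score units.

    Surface scores saturate near 1, so score differences between rotamers
    are often 1e-5 or smaller; the default schedule therefore cools from an
    exploratory temperature down to one far below typical deltas, making
    the final third of the trajectory effectively greedy.
    """
    t_start: float = 0.01
    t_end: float = 1e-9
    n_steps: int | None = None  # default: 200 per designable position

    def __post_init__(self):
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")
        if self.n_steps is not None and self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def temperature(self, step: int, n_steps: int) -> float:
        if n_steps <= 1:
            return self.t_start
        frac = step / (n_steps - 1)
        return self.t_start * (self.t_end / self.t_start) ** frac


@dataclass
class DesignTask:
    scaffold: ParameterizedStructure
    designable: list[tuple[str, int]]
    reference_surface: SurfaceCloud
    patch_residues: set[tuple[str, int]] | None = None
    allowed_aas: tuple[str, ...] = params.DESIGN_RESIDUES
    schedule: AnnealSchedule = AnnealSchedule()
    seed: int = 0
    objective: str = "similarity"  # or "complementarity"
    context: ParameterizedStructure | None = None  # e.g. bound binder
    library: RotamerLibrary | None = None
    probe_radius: float = 1.4
    density: float = 3.0
    shape_params: ShapeParams = ShapeParams()
    potential_model: PotentialModel = PotentialModel()
    weights: WeightSet = DEFAULT_WEIGHTS

    def __post_init__(self):
        present = set(self.scaffold.residue_ids())
        for pos in self.designable:
            if tuple(pos) not in present:
                raise ValueError(f"designable position {pos} not in scaffold")
        if self.objective not in ("similarity", "complementarity"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.patch_residues is None:
            self.patch_residues = set(tuple(p) for p in self.designable)


@dataclass
class DesignResult:
    final_structure: ParameterizedStructure
    best_structure: ParameterizedStructure
    trajectory: pd.DataFrame
    final_score: float
    best_score: float
    assignments: dict[tuple[str, int], tuple[str, tuple[float, ...]]]
    scan_table: "ScanTable | None" = None


@dataclass
class ScanTable:
    """Per-(position, residue) best surface score and rotamer."""
    scores: pd.DataFrame          # index: "chain:resi", columns: residues
    best_chi: dict[tuple[tuple[str, int], str], tuple[float, ...]]
    native: dict[tuple[str, int], str]

    def position_key(self, pos: tuple[str, int]) -> str:
        return f"{pos[0]}:{pos[1]}"


class PatchScorer:
    """Scores a structure's surface patch against a fixed reference cloud.

    The patch is the set of surface points owned by ``patch_residues``.
    Only the surface over the patch atoms' bounding region is regenerated;
    every patch-owned point lies within probe + r_max of a patch atom, so
    the localized cloud equals the corresponding subset of a full
    recomputation on the same lattice.
    """

    def __init__(self, reference: SurfaceCloud,
                 patch_residues: set[tuple[str, int]],
                 objective: str = "similarity",
                 context: ParameterizedStructure | None = None,
                 probe_radius: float = 1.4, density: float = 3.0,
                 shape_params: ShapeParams = ShapeParams(),
                 potential_model: PotentialModel = PotentialModel(),
                 weights: WeightSet = DEFAULT_WEIGHTS):
        self.reference = reference
        self.patch_residues = set(patch_residues)
        self.objective = objective
        self.context = context
        self.probe_radius = probe_radius
        self.density = density
        self.shape_params = shape_params
        self.potential_model = potential_model
        self.weights = weights

    def patch_cloud(self, ps: ParameterizedStructure) -> SurfaceCloud:
        full = ps if self.context is None else merge(ps, self.context)
        patch_atoms = np.array(
            [a.coord for a in full.atoms
             if (a.chain_id, a.residue_index) in self.patch_residues])
        r_max = max(a.radius for a in full.atoms)
        margin = r_max + self.probe_radius + 1.0
        region = (patch_atoms.min(axis=0) - margin,
                  patch_atoms.max(axis=0) + margin)
        cloud = compute_ses_cloud(full, self.probe_radius, self.density,
                                  region=region)
        cloud = extract_patch(cloud, PatchSpec(residues=self.patch_residues))
        if self.objective == "similarity":
            cloud = assign_potential(cloud, full, self.potential_model)
        return cloud

    def score_cloud(self, cloud: SurfaceCloud) -> float:
        if self.objective == "complementarity":
            return shape_complementarity(cloud, self.reference,
                                         self.shape_params)
        s_s = shape_similarity(cloud, self.reference, self.shape_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            e_s, _, _ = electrostatic_similarity(cloud, self.reference)
        return surf_score(s_s, e_s, self.weights)

    def score(self, ps: ParameterizedStructure) -> float:
        return self.score_cloud(self.patch_cloud(ps))


def make_reference_cloud(task: DesignTask,
                         native: ParameterizedStructure) -> SurfaceCloud:
    """Patch cloud of a native structure under a task's scoring settings."""
    scorer = _scorer_for(task)
    return scorer.patch_cloud(native)


def _scorer_for(task: DesignTask) -> PatchScorer:
    return PatchScorer(task.reference_surface, task.patch_residues,
                       task.objective, task.context, task.probe_radius,
                       task.density, task.shape_params, task.potential_model,
                       task.weights)


def _clashes(side_atoms: list[tuple[str, str, np.ndarray]],
             other_coords: np.ndarray, other_radii: np.ndarray,
             radii_table: dict[str, float]) -> bool:
    if len(side_atoms) == 0 or len(other_coords) == 0:
        return False
    tree = cKDTree(other_coords)
    for name, elem, pos in side_atoms:
        r = radii_table[elem]
        hits = tree.query_ball_point(pos, r=CLASH_FACTOR * (r + other_radii.max()))
        for j in hits:
            if np.linalg.norm(pos - other_coords[j]) < \
                    CLASH_FACTOR * (r + other_radii[j]):
                return True
    return False


def _candidate_clashes(ps: ParameterizedStructure,
                       context: ParameterizedStructure | None,
                       pos: tuple[str, int], rtype: str,
                       chi: tuple[float, ...]) -> bool:
    """Hard-clash test of a rebuilt side chain against all other residues."""
    res = ps.residue_atoms(*pos)
    frame = {a.name: a.coord for a in res if a.name in ("N", "CA", "C")}
    side = build_side_chain(rtype, frame["N"], frame["CA"], frame["C"], chi)
    others = [a for a in ps.atoms
              if (a.chain_id, a.residue_index) != pos]
    if context is not None:
        others.extend(context.atoms)
    coords = np.array([a.coord for a in others])
    radii = np.array([a.radius for a in others])
    return _clashes(side, coords, radii, params.element_radii())


def _default_candidates(task: DesignTask, library: RotamerLibrary
                        ) -> dict[tuple[str, int],
                                  list[tuple[str, tuple[float, ...], float]]]:
    cands: dict = {}
    for pos in task.designable:
        lst = []
        for aa in task.allowed_aas:
            if aa not in library:
                raise ValueError(f"rotamer library lacks {aa}")
            for chis, prob in library[aa]:
                lst.append((aa, chis, prob))
        total = sum(p for _, _, p in lst)
        cands[tuple(pos)] = [(a, c, p / total) for a, c, p in lst]
    return cands


def _run_mc(task: DesignTask,
            candidates: dict[tuple[str, int],
                             list[tuple[str, tuple[float, ...], float]]],
            scan_table: ScanTable | None = None) -> DesignResult:
    rng = np.random.default_rng(task.seed)
    scorer = _scorer_for(task)
    positions = [tuple(p) for p in task.designable]
    current = task.scaffold.copy()
    assignments: dict[tuple[str, int], tuple[str, tuple[float, ...]]] = {}
    # the score is a pure function of the joint assignment over designable
    # positions (scaffold and context fixed), so revisited states are free
    cache: dict[tuple, float] = {}

    def state_key(asgn: dict) -> tuple:
        return tuple(sorted((p, asgn.get(p)) for p in positions))

    score = cache.setdefault(state_key(assignments), scorer.score(current))
    best_score = score
    best = current.copy()
    rows = []
    if not positions:
        traj = pd.DataFrame(columns=["step", "position", "residue", "chi",
                                     "score", "accepted", "clash"])
        return DesignResult(current, best, traj, score, best_score, {},
                            scan_table)
    n_steps = task.schedule.n_steps or 200 * len(positions)
    for step in range(n_steps):
        t = task.schedule.temperature(step, n_steps)
        pos = positions[rng.integers(len(positions))]
        cand = candidates[pos]
        probs = np.array([p for _, _, p in cand])
        k = rng.choice(len(cand), p=probs / probs.sum())
        aa, chis, _ = cand[k]
        clash = _candidate_clashes(current, task.context, pos, aa, chis)
        accepted = False
        new_score = np.nan
        if not clash:
            trial = mutate_positions(current, {pos: (aa, chis)})
            trial_asgn = dict(assignments)
            trial_asgn[pos] = (aa, tuple(chis))
            key = state_key(trial_asgn)
            if key in cache:
                new_score = cache[key]
            else:
                new_score = scorer.score(trial)
                cache[key] = new_score
            delta = new_score - score
            if delta >= 0 or rng.random() < np.exp(delta / t):
                accepted = True
                current = trial
                score = new_score
                assignments[pos] = (aa, tuple(chis))
                if score > best_score:
                    best_score = score
                    best = current.copy()
        rows.append({"step": step, "position": f"{pos[0]}:{pos[1]}",
                     "residue": aa, "chi": ",".join(f"{c:.1f}" for c in chis),
                     "score": new_score, "accepted": accepted,
                     "clash": clash})
    traj = pd.DataFrame(rows)
    return DesignResult(current, best, traj, score, best_score, assignments,
                        scan_table)


def design_mc(task: DesignTask) -> DesignResult:
    """Monte-Carlo simulated-annealing design over all allowed rotamers.

    Moves are (uniform position, uniform residue type, prior-weighted
    rotamer); hard-clashing rotamers are rejected outright; otherwise the
    patch surface is regenerated and the move accepted with Metropolis
    probability min(1, exp((score_new - score_old)/T)).  Deterministic
    given the task seed.
    """
    library = task.library or load_rotamer_library()
    return _run_mc(task, _default_candidates(task, library))


def scan_position(task: DesignTask, pos: tuple[str, int],
                  library: RotamerLibrary,
                  base: ParameterizedStructure | None = None
                  ) -> list[tuple[float, str, tuple[float, ...]]]:
    """Score every allowed (residue, rotamer) at one position, other
    positions held at their current identity.  Clashing rotamers are
    skipped.  Returns (score, residue, chi) sorted best-first."""
    scorer = _scorer_for(task)
    current = base if base is not None else task.scaffold
    out = []
    for aa in task.allowed_aas:
        for chis, _ in library[aa]:
            if _candidate_clashes(current, task.context, pos, aa, chis):
                continue
            trial = mutate_positions(current, {pos: (aa, chis)})
            out.append((scorer.score(trial), aa, chis))
    out.sort(key=lambda t: (-t[0], t[1], t[2]))
    return out


def design_site_scan(task: DesignTask, top_k: int = 3) -> DesignResult:
    """Two-phase design: independent per-position scans shortlist the
    ``top_k`` rotamers by surface score, then the annealer samples the
    shortlists combinatorially.  With ``top_k`` at least the total rotamer
    count this reduces to :func:`design_mc`'s search space."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    library = task.library or load_rotamer_library()
    shortlists: dict = {}
    score_rows: dict = {}
    best_chi: dict = {}
    native: dict = {}
    for pos in task.designable:
        pos = tuple(pos)
        native[pos] = task.scaffold.residue_type(*pos)
        scored = scan_position(task, pos, library)
        if not scored:
            raise ValueError(f"all rotamers clash at {pos}")
        shortlist = scored[:top_k]
        p = 1.0 / len(shortlist)
        shortlists[pos] = [(aa, chis, p) for _, aa, chis in shortlist]
        row = {}
        for sc, aa, chis in scored:
            if aa not in row:   # scored is sorted best-first
                row[aa] = sc
                best_chi[(pos, aa)] = chis
        score_rows[f"{pos[0]}:{pos[1]}"] = row
    table = ScanTable(scores=pd.DataFrame(score_rows).T, best_chi=best_chi,
                      native=native)
    return _run_mc(task, shortlists, scan_table=table)


def ssm_scan(target: ParameterizedStructure, binder: ParameterizedStructure,
             positions: list[tuple[str, int]] | None = None,
             allowed_aas: tuple[str, ...] = params.DESIGN_RESIDUES,
             library: RotamerLibrary | None = None,
             probe_radius: float = 1.4, density: float = 3.0,
             shape_params: ShapeParams = ShapeParams(),
             cutoff: float = 7.0) -> ScanTable:
    """Computational site-saturation mutagenesis ranked by interface shape
    complementarity.

    For each position and allowed residue the best clash-free rotamer is
    substituted and S_C between the target's interface patch and the
    binder's interface patch is recorded; all-clashing substitutions yield
    NaN.  Positions outside the C-beta interface produce a warning but are
    still scanned.
    """
    library = library or load_rotamer_library()
    iface = select_interface(target, binder, cutoff)
    if positions is None:
        positions = list(iface.positions)
    if not positions:
        raise ValueError("no positions to scan")
    for pos in positions:
        if tuple(pos) not in set(iface.positions):
            warnings.warn(f"position {pos} is not at the interface",
                          RuntimeWarning, stacklevel=2)
    binder_iface = select_interface(binder, target, cutoff)
    if not binder_iface.positions:
        raise ValueError("binder has no interface residues")
    binder_scorer = PatchScorer(
        reference=None, patch_residues=set(binder_iface.positions),
        objective="complementarity", probe_radius=probe_radius,
        density=density, shape_params=shape_params)
    binder_cloud = binder_scorer.patch_cloud(binder)

    patch = set(tuple(p) for p in iface.positions) | \
        set(tuple(p) for p in positions)
    scorer = PatchScorer(
        reference=binder_cloud, patch_residues=patch,
        objective="complementarity", probe_radius=probe_radius,
        density=density, shape_params=shape_params)

    score_rows: dict = {}
    best_chi: dict = {}
    native: dict = {}
    for pos in positions:
        pos = tuple(pos)
        native[pos] = target.residue_type(*pos)
        row = {}
        for aa in allowed_aas:
            entries = []
            for chis, _ in library[aa]:
                if _candidate_clashes(target, binder, pos, aa, chis):
                    continue
                trial = mutate_positions(target, {pos: (aa, chis)})
                entries.append((scorer.score(trial), chis))
            if entries:
                entries.sort(key=lambda t: (-t[0], t[1]))
                row[aa] = entries[0][0]
                best_chi[(pos, aa)] = entries[0][1]
            else:
                row[aa] = np.nan
        score_rows[f"{pos[0]}:{pos[1]}"] = row
    return ScanTable(scores=pd.DataFrame(score_rows).T, best_chi=best_chi,
                     native=native)


def select_top(table: ScanTable, k: int = 4) -> dict[str, list[str]]:
    """Per position, the k highest-scoring residue types; ties break
    alphabetically by three-letter code.  NaN (all-clash) entries never
    rank."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, list[str]] = {}
    for pos_key, row in table.scores.iterrows():
        scored = [(aa, sc) for aa, sc in row.items() if pd.notna(sc)]
        scored.sort(key=lambda t: (-t[1], t[0]))
        out[pos_key] = [aa for aa, _ in scored[:k]]
    return out
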