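# Methods

This note documents the models, numerical choices and limitations behind
`surfcraft`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Surface representation

The solvent-excluded surface (SES) is the boundary swept by the inward face
of a probe sphere (default radius 1.4 Å, water) rolling over the van der
Waals spheres of the heavy atoms. We approximate it on a grid:

1. The solvent-accessible surface (SAS) field `A(x) = min_j(|x−c_j| − r_j)
   − r_p` is evaluated on a cubic lattice. A two-stage nearest-neighbour
   scheme computes the exact multi-atom minimum only in a thin band around
   the SAS (the nearest atom centre alone bounds the value to within the
   vdW-radius spread, ≤ 0.28 Å for the packaged radii).
2. The interior mask `A < 0` is eroded by the probe with a Euclidean
   distance transform. A sub-voxel correction subtracts the SAS-field value
   at the nearest exterior voxel, removing the ~h/2 outward bias the
   discrete transform would otherwise introduce.
3. Marching cubes triangulates the zero level set; vertices are then
   **projected exactly**: each point is moved to distance r_p from an
   approximate nearest probe-centre position on the SAS (found by iterated
   radial projection onto the probe-inflated spheres). Projection makes
   containment exact — no emitted point lies inside any vdW sphere — and
   yields exactly unit, exactly outward normals (the direction from surface
   point to probe centre). For r_p = 0 the construction degenerates to the
   vdW surface with radial normals.
4. Points are sampled on the triangles at the requested density (default
   3.0 points/Å²) by a deterministic, locality-preserving scheme: triangles
   are grouped into fixed spatial supercells (side 2h) and each cell is
   swept systematically over its cumulative area, with sub-triangle
   positions drawn from a spatial hash. Cells whose triangles are unchanged
   between two runs emit bit-identical points, which is what makes
   localized recomputation during design exact away from the perturbation.

Grid spacing is tied to the density, `h = 0.7/√density` (≈ 0.40 Å at the
default), so triangulation and sampling refine together; the sphere-area
error decreases as density increases. Each point is tagged with the residue
of the atom whose sphere surface is nearest; interior cavities are retained
(patch extraction makes them irrelevant for interface work).

**Frames.** By default the grid lives in a canonical frame derived from the
atom covariance (eigenvectors ordered by eigenvalue, signs fixed by the
third moment) and results are mapped back to world coordinates; cloud
generation therefore commutes exactly with rigid motions of the input. The
canonical frame is undefined for point sets with vanishing third moments or
degenerate covariance (a single atom falls back to the identity frame); the
synthetic helices used in tests are generic. A `frame="world"` mode uses a
lattice-snapped world-aligned grid instead; design scoring uses it because
there a *stable* lattice under small coordinate changes matters more than
rotational equivariance.

## Electrostatics

Surface potentials use a screened-Coulomb (Debye–Hückel) model in a uniform
dielectric: φ_i = Σ_j k_e q_j e^(−κ d_ij)/(ε_r d_ij), reported in kT/e
(k_e = 332.06 kcal·Å·mol⁻¹·e⁻², k_B T at 298.15 K). Defaults: ε_r = 78.54,
κ = 0.113 Å⁻¹ (≈ 150 mM monovalent salt). The downstream electrostatic
score consumes only linear and rank correlations of potentials across
matched points, which track the spatial *pattern* of the field rather than
its magnitude, so no dielectric boundary or finite-difference solver is
modelled; absolute potentials from this model should not be compared with
Poisson–Boltzmann output. A surface point coinciding with an atom centre
raises rather than clamps — by construction points are at least one vdW
radius from their owning atom, so d = 0 signals a geometry bug.

Partial charges are a packaged heavy-atom effective set (no hydrogens);
each residue's charges sum exactly to its formal charge (Asp/Glu −1,
Lys/Arg +1, others 0). The values are internally consistent rather than
taken from any force field; only their spatial pattern matters to E_S.

## Scores

* **S_S** — for each point of cloud A, the nearest point of B (ties to the
  lowest index); the per-pair value is the normal dot product scaled by
  exp(−w d²) with w = 0.5 Å⁻² following the Lawrence–Colman
  complementarity tradition. Per-point values are averaged (mean, not
  median), the two matching directions are averaged, and the *aggregate*
  is clamped to [0, 1]; per-point values are never clamped.
* **E_S** — Pearson and Spearman correlations are computed over the
  concatenation of both directions' matched potential pairs and combined
  as E_S = −(r + ρ)/2, so identical fields give −1. Zero-variance
  potential vectors (an uncharged toy) return E_S = 0 with a warning
  rather than NaN.
* **Surf_S** — the logistic 1/(1 + exp(b₀ + b_SS·S_S + b_ES·E_S)) with the
  fitted default weights (13.79986756, −14.64347448, +13.78594078).
  A self-comparison gives S_S = 1, E_S = −1 and Surf_S = 0.9999996.
* **S_C** — S_S against the reference cloud with negated normals; a
  surface and its normal-flipped copy are perfect complements (S_C = 1),
  and S_C(A, A) clamps to 0.

Clouds are assumed pre-aligned; no superposition search is performed.

## Weight fitting and the synthetic score dataset

`fit_weights` is plain maximum-likelihood logistic regression (no
regularization — the large fitted coefficients imply none was used) with a
stratified 80/20 train/test split and accuracy at threshold 0.5.

The synthetic dataset generator mirrors the benchmark dataset's structure:
19 residue types × n pseudo-complexes × (1 native + 18 non-native) records,
so n = 140 gives 2,660 natives and 47,880 non-natives and n = 100 gives the
1,900 recovery cases. Features are drawn from a base distribution (a small
native-like component near S_S ≈ 0.9, E_S ≈ −0.9 plus a broad background)
and assigned to classes by rejection against the default logistic model, so
class membership follows the generating weights exactly. The native-like
mixture weight (0.0346) is set so that the base distribution's marginal
native probability equals 1/19 — the dataset's own class ratio — which
makes the refitted intercept unbiased. Refitting on n = 140 recovers all
three weights within 10 % with ≈ 98.6 % held-out accuracy. The generator
emulates the *shape* of the real dataset, not its marginals: passing tests
show estimator consistency and pipeline correctness, not transferability of
the weights to crystal structures.

## Design

Moves are (uniform random position, uniform residue type from the 19-letter
design alphabet, prior-weighted rotamer). The packaged rotamer library is a
coarse backbone-independent grid — chi bins at −60/60/180° per rotatable
bond, capped at 9 rotamers per residue (chi₁ × chi₂ grid, further chis at
180°), uniform priors; proline's ring is built at a fixed pucker with no
sampled chi. Rebuilt side chains use ideal internal coordinates from the
packaged topology table.

A hard-clash prefilter rejects rotamers with any heavy-atom pair below
0.6 × the radii sum against other residues before any surface work. Scoring
then regenerates only the surface over the patch atoms' bounding region
(margin r_max + r_probe + 1 Å): every surface point lies within
r_probe + r_max of its owning atom, so the localized cloud restricted to
the patch equals the corresponding subset of a full recomputation on the
same lattice (a test asserts this). Acceptance is Metropolis on the surface
score with geometric cooling. Because Surf_S saturates near 1, score
differences between competing rotamers are often 1e-5 or smaller; the
default schedule (0.01 → 1e-9 over 200 steps per position) therefore ends
far below typical deltas so the final third of a trajectory is effectively
greedy and the chain freezes at its best-visited basin. Scores are cached
by joint assignment state — the objective is a pure function of (scaffold,
assignments) — which makes long trajectories cheap.

The site-scan protocol scores every allowed (residue, rotamer) per position
independently (other positions held at their *current* identity, i.e.
alanine right after alanization), shortlists the top-k, and anneals over
the shortlists. With all neighbours wrong the single-position ranking is
noisier than with native neighbours; on the toy complex one position's
native drops to rank 4, so the interface-recovery benchmark uses k = 5.

The SSM scan substitutes each residue type at each position (best clash-free
rotamer by the objective) and reports S_C between the target's interface
patch and the binder's interface patch; electrostatics are deliberately
excluded from this objective. All-clash substitutions yield NaN and never
rank in the top-k selection (ties break alphabetically).

## Benchmarks

Single-residue recovery captures the native patch surface as reference,
substitutes each of the 19 candidates (best clash-free rotamer by Surf_S
against that reference) and declares success when the native is the strict
maximum (margin > 1e-9 — the operational meaning of "uniquely
identifiable"). Cysteine positions raise (disulfide chemistry makes the
surface non-local to one residue). Unbound mode removes the binder before
any computation; bound mode keeps it as surface and clash context.
Interface recovery alanizes the C-beta-rule interface (7 Å cutoff; CA→CB
orientation test against the nearest binder atom, < 90°; glycine uses an
ideal virtual C-beta) and reports the fraction of positions redesigned to
the native type. The S_C complexity boundary assigns 0.65 itself to "high"
(only "less than 0.65" is defined as low). Flexible side chains are
{R, N, Q, E, H, K, M, W}; an interface with ≥ 40 % of them is "Flexible".

## Synthetic fixtures

The toy two-helix complex places an 11-residue target helix (designed
interface residues at positions 4, 7, 8 — one helical face) against an
anti-parallel poly-alanine binder, searching axis separations ~9.5–11 Å and
roll angles for a placement satisfying the interface rule without clashes;
the seed jitters the separation and roll. Ideal helices are built by
internal-coordinate chaining at (φ, ψ) = (−57°, −47°), ω = 180°, with
τ(N–CA–C) = 110° — chosen so the 10-residue helical rise lands at the
canonical ~1.5 Å — and side chains at the first library rotamer (which is
what makes "the native rotamer is in the library" hold exactly for design
tests). These fixtures have none of the messiness of crystal structures
(alternate conformations, missing atoms, non-ideal geometry), so passing
benchmarks demonstrate correctness of the scoring and sampling machinery,
not expected recovery rates on real complexes.

## Problem sizes and tolerances

Tests and the acceptance script run at density 2–3 points/Å² on structures
of ~150–300 atoms; design tasks use 400–1,200 annealing steps. Identities
that hold by construction (self-comparison, double normal flip) are
asserted at 1e-6–1e-12; oracle equivalences (exhaustive matching,
enumeration parity) at 1e-9; stochastic trends (jitter degradation,
weight recovery) at the tolerances a 20-seed or 50,000-record experiment
supports. The single-sphere SES area estimate is accurate to ~2 % at the
default density.

## Known limitations

* No mmCIF, nucleic acids, ligands, hydrogens, protonation logic or
  structure minimization; terminal OXT atoms are rejected at
  parameterization.
* The SES is grid-derived; exact analytic (Connolly) patches and
  triangle-mesh topology guarantees are out of scope. Deep multi-atom
  seams are projected approximately (alternating projections), though
  containment remains exact.
* Scores depend on probe radius, density and w; comparisons are meaningful
  only under fixed settings.
* The design objective contains no packing/energy term beyond the hard
  clash filter, and the backbone is rigid throughout.
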