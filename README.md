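# surfcraft

Surface-centric protein scoring and fixed-backbone sequence design.

Protein function is often carried by the *shape* and *electrostatics* of a
molecular surface rather than by any particular sequence. `surfcraft`
represents solvent-excluded surfaces (SES) as oriented point clouds and
provides:

* **Surface scores.** Shape similarity **S_S** compares outward normals of
  nearest point pairs with a Gaussian distance penalty,

      S_S = ½ [ mean_a ( n̂_a · n̂_nn(a) ) e^(−w d²)  +  (B→A direction) ],

  clamped to [0, 1]. Electrostatic similarity **E_S** is the sign-flipped
  mean of Pearson and Spearman correlations of surface potentials over the
  matched pairs (−1 = identical fields, +1 = complementary fields). The
  combined score is the fitted logistic

      Surf_S = 1 / (1 + exp(13.79986756 − 14.64347448·S_S + 13.78594078·E_S)),

  and shape complementarity **S_C** is S_S evaluated against the reference
  cloud with inverted normals, so snugly fitting interfaces score high.
* **Design protocols.** Monte-Carlo simulated annealing over residue/rotamer
  substitutions accepted by the Metropolis criterion on the surface score;
  a two-phase variant that shortlists the top-k rotamers per position
  before combinatorial sampling; and a computational site-saturation scan
  of an interface ranked by S_C.
* **Benchmarks.** Single-residue recovery (does the native amino acid score
  best among the 19 candidates, cysteine excluded?), interface sequence
  recovery after alanization, and interface grouping helpers (the S_C 0.65
  complexity threshold; flexible vs. static side-chain content).
* **Synthetic structures.** Ideal-geometry helices, toy two-chain
  complexes with designed interfaces, perturbed clouds and labeled score
  datasets — every stage of the pipeline is testable without downloading a
  single structure.

The intended audience is structural-bioinformatics and protein-design
researchers who want a transparent, dependency-light implementation of
surface-similarity scoring to experiment with, not a drop-in replacement
for a full design suite.

## Worked example

```python
from surfcraft import (PatchScorer, make_two_helix_complex,
                       select_interface, single_aa_recovery)

target, binder = make_two_helix_complex(seed=0)   # toy complex, LEU/LYS/ASP interface
iface = select_interface(target, binder)          # 7 Å C-beta rule
print(iface.positions)
# [('A', 4), ('A', 7), ('A', 8), ('A', 11)]

case = single_aa_recovery(target, binder, ("A", 7), mode="bound")
print(case.native, case.success)
print(sorted(case.scores.items(), key=lambda kv: -kv[1])[:3])
# LYS True
# [('LYS', 0.9999995569344649), ('ARG', 0.9999931822996503),
#  ('MET', 0.9999235203851957)]
```

The native lysine's best rotamer reproduces the native surface exactly, so
its Surf_S equals the self-comparison value 0.9999996 (= the logistic at
S_S = 1, E_S = −1); arginine — the most lysine-like surface — is a close
runner-up, and the recovery flag is true because the native is the strict
maximum.

The same machinery runs from the shell:

```bash
surf synth --kind complex --seed 0 --out complex.pdb
surf score --target complex.pdb --reference complex.pdb \
     --target-patch A:7 --reference-patch A:7
surf bench --suite interface --complex complex.pdb \
     --target-chain A --binder-chain B --protocol site
```

## Layout

| Path | Contents |
| --- | --- |
| `src/surfcraft/structure.py` | PDB I/O (gemmi), parameterization, side-chain building, mutations, interface selection |
| `src/surfcraft/surface.py` | SES point clouds, patches, nearest-pair matching |
| `src/surfcraft/electrostatics.py` | screened-Coulomb surface potentials |
| `src/surfcraft/similarity.py` | S_S, E_S, Surf_S, S_C |
| `src/surfcraft/weights.py` | logistic weights, refitting, candidate ranking |
| `src/surfcraft/design.py` | annealer, site scan, SSM scan |
| `src/surfcraft/benchmarks.py` | recovery protocols and grouping helpers |
| `src/surfcraft/fixtures.py` | synthetic structures, clouds and datasets |
| `src/surfcraft/data/` | packaged radii/charges/topology/rotamer tables (TSV) |
| `docs/methods.md` | model assumptions, numerical choices, limitations |
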