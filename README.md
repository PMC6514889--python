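# fullerbind

Analysis toolkit for the binding of fullerene (C60) and fullerenol
(C60(OH)6, C60(OH)12) nanoparticles to amyloid-beta protofibrils.

Aggregation of the amyloid-beta (Abeta) peptide into cross-beta fibrils
is central to Alzheimer's disease, and carbon nanoparticles are studied
as aggregation inhibitors: they bind the protofibril surface, block
hydrophobic side-chain packing and backbone amide sites, and their
behaviour changes systematically with surface hydroxylation.  This
package implements the quantitative layer of such a study for people who
have (or want to simulate having) receptor-ligand trajectories:

* **geometric detectors** -- receptor-ligand minimum distance,
  per-residue heavy-atom contacts (0.54 nm), geometric hydrogen bonds
  (D-A < 0.35 nm, D-H-A > 150 deg), pi-stacking of aromatic rings
  against the spherical carbon cage surface (< 0.45 nm) with
  parallel/herringbone/T-shaped orientation classes, Calpha-RMSD
  (Kabsch), salt-bridge persistence;
* **binding kinetics** -- persistent-contact onset on the d_min series,
  fast (<= 3 ns) vs slow regimes, binding-site occupancy from the
  dominant-contact residue;
* **MM/PBSA energetics** -- single-trajectory end-point binding free
  energy

  dG_bind = dE_vdW + dE_elec + dG_polar + dG_nonpolar - T*dS

  with pairwise Lennard-Jones/Coulomb terms, Shrake-Rupley SASA
  (dG_nonpolar = gamma*SASA + b, gamma = 0.542 kcal/mol/nm^2,
  b = 0.92 kcal/mol, 0.14 nm probe), a from-scratch finite-difference
  linearised Poisson-Boltzmann solver for dG_polar (eps 2/80, 0.1 M,
  310 K), per-residue decomposition and binding-site energies, reported
  as mean +- SEM over independent runs (T*dS ignored, flagged);
* **synthetic systems** -- an idealised in-register cross-beta trimer
  builder, truncated-icosahedron C60(OH)n cages with maximally separated
  hydroxyls, a toy force field, and seeded toy binding trajectories that
  inject known binding sites and kinetic regimes, so the whole pipeline
  is testable end to end without an MD engine.

See `docs/methods.md` for the models and numerical choices and
`docs/formats.md` for the file formats.

## Worked example

```python
import numpy as np
from fullerbind import (AnalysisConfig, PBParameters, SasaParameters,
                        TrajectorySpec, binding_time, build_complex,
                        generate_trajectory, mmpbsa_binding_energy)
from fullerbind.geometry import detect_pi_stacking, minimum_distance_series

# Abeta42 trimer + C60 placed 2 nm from the N-terminal 2-4 site
system = build_complex(n_hydroxyl=0, seed=1, target_site=(2, 4))

# one fast-regime toy run: 200 frames x 100 ps = 20 ns
traj = generate_trajectory(system, TrajectorySpec(
    regime="fast", target_site=(2, 4), n_frames=200, seed=3))

dmin = minimum_distance_series(system, traj)
onset = binding_time(traj.times, dmin)
print(f"binding onset: {onset.time_ps:.0f} ps ({onset.regime})")

stacks = detect_pi_stacking(system, traj.coordinates[150])
print(f"pi-stacks in frame 150: {len(stacks)} "
      f"({[e.orientation for e in stacks]})")

cfg = AnalysisConfig(pb=PBParameters(grid_spacing=0.15, tolerance=1e-5),
                     sasa=SasaParameters(n_sphere_points=384))
bd, _ = mmpbsa_binding_energy(system, traj, window_ps=5000.0, stride=10,
                              config=cfg)
print(f"dG_bind = {bd.dG_bind:+.2f} kcal/mol "
      f"(vdW {bd.dE_vdw:+.2f}, elec {bd.dE_elec:+.2f}, "
      f"polar {bd.dG_polar:+.2f}, nonpolar {bd.dG_nonpolar:+.2f})")
```

Output:

```
binding onset: 800 ps (fast)
pi-stacks in frame 150: 2 (['herringbone', 'parallel'])
dG_bind = -8.87 kcal/mol (vdW -7.08, elec +0.00, polar +0.03, nonpolar -1.82)
```

The C60 reaches persistent contact (d_min <= 0.30 nm) after 0.8 ns -- a
fast-regime run -- and, docked at the 2-4 site, stacks with the F4
phenyl rings of neighbouring chains (up to all three at once in other
frames).  The binding energy is
dominated by the van der Waals term; the electrostatic term is exactly
zero because the unhydroxylated cage carries no charges, and the small
polar and negative nonpolar (buried-surface) terms complete the
breakdown, which satisfies dG_bind = dE_MM + dG_solv identically.

The same study at campaign scale (3 nanoparticles x 6 seeded runs, fast
and slow regimes, last-20-ns analysis window) runs from the command
line:

```bash
fullerbind study run --seed 2019 --out-dir results/study
fullerbind build --cage-oh 12 --seed 1 --out-dir systems/oh12
fullerbind analyze geometry --traj run1.traj --topology topology.tsv \
    --ref complex.pdb --out results/geometry
```

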