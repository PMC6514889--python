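# Methods

## Scope and model

`fullerbind` implements the analysis layer of a nanoparticle-binding
study of amyloid-beta protofibrils: given trajectories of a peptide
oligomer (receptor) and a C60/C60(OH)6/C60(OH)12 cage (ligand), it
measures binding kinetics, binding sites, specific interactions and an
end-point MM/PBSA binding free energy.  Because no trajectory data are
deposited for such studies, the package also contains a synthetic-system
module that builds idealised receptor/ligand models and generates seeded
toy trajectories with the statistical structure the analysis assumes;
the whole pipeline can therefore be exercised, and its parameter
recovery validated, without any molecular-dynamics engine.

## Synthetic systems

**Cage.**  C60 is a truncated icosahedron (60 vertices, 90 edges) scaled
to a cage radius of 0.355 nm; the equal-edge polyhedral geometry keeps
bond-length dispersion below 2%, close enough to the real two-bond-length
cage for every detector in scope.  Hydroxyls attach to cage carbons
chosen to maximise the minimum pairwise geodesic (bond-graph) distance --
a concrete reading of "uniformly distributed".  The optimum is found
exactly by branch-and-bound over vertex subsets (the optimum separation
is 5 bonds for six hydroxyls and 3 bonds for twelve); the seed picks
among symmetry-equivalent optimal placements.  Hydroxyl O sits radially
outward at C-O = 0.14 nm, H at O-H = 0.10 nm.

**Protofibril.**  The receptor is an in-register parallel stack of
identical extended strands: Calpha rise 0.35 nm along the strand,
chains translated 0.48 nm along the fibril axis (z).  The backbone
zig-zags slightly in y, with the amplitude solved numerically so that
N-CA/CA-C/C-N bond lengths take ideal values while preserving the rise.
Carbonyl oxygens point up (+z) and amide hydrogens down, aimed at the
in-register carbonyl of the chain below, so every peptide-unit donor of
an upper chain forms a geometric hydrogen bond (D-A about 0.30 nm, angle
180 deg) across the interface: 41 bonds per interface for a 42-residue
chain, 82 for the trimer.  This is the ladder a cross-beta sheet provides
one donor per peptide unit, so roughly `(n_chains-1) x (L-1)` inter-chain
H-bonds is the physical ceiling for translationally identical chains.
Side chains are reduced to one interaction centre per functional group
(full six-atom rings for F/Y/H -- histidine deliberately gets a
six-membered toy ring so one template serves all aromatics; carboxylate,
amine and guanidinium centres for D/E, K, R; a CB pseudo-atom
otherwise), alternating sides of the sheet.  Termini are charged
(NH3+/COO-), giving the Abeta42 chain its physiological net charge of -3.

**Toy force field.**  Element-based LJ types under Lorentz-Berthelot
combination; +-0.4 e partial charges on N-H/C=O, +-1 e on ionised side
chains, +0.2/-0.6/+0.4 e on hydroxyl C-O-H; polar hydrogens carry no LJ
well (they keep a 0.11 nm PB/SASA radius so the dielectric cavity stays
closed).  Total system charge is integral by construction.  Real
force-field parameters can be supplied through the topology table
instead; nothing downstream depends on the toy set.

**Trajectories.**  The ligand performs a biased random walk (drift
toward the target site, isotropic diffusion, random rigid-body
rotation); the receptor gets independent 0.02 nm Gaussian jitter per
frame.  Arrival is controlled by the drift magnitude, derived from the
regime: fast runs reach d_min <= 0.30 nm at a nominal 2 ns (never later
than 4% of the run), safely inside the 3 ns fast/slow classification
boundary; slow runs arrive at a species-dependent fraction of the run
(0.26 for C60, 0.40 for C60(OH)6, 0.42 of the doubled-length C60(OH)12
runs), so slow onsets move from ~13 ns to ~20 ns to ~40 ns along the
hydroxyl series.  Once in contact, apolar cages hold their carbon
surface at 0.295 +- 0.01 nm from the nearest receptor atom; hydroxylated
cages dock one hydroxyl at a site acceptor (backbone carbonyl for
C60(OH)6, a carboxylate for C60(OH)12) at a donor-acceptor distance of
0.32-0.33 nm with ~8 deg orientational wobble, which produces geometric
hydrogen bonds in most bound frames.  The hydrophilicity "knob" the
study design calls for is exactly this docked geometry: larger
donor-acceptor distance, anchor wandering across the site and slower
drift with increasing hydroxyl count.  One frame represents 100 ps; runs
are 500 frames (1000 for the slowest binder) and six runs use seeds
`master_seed + 0..5`, three fast and three slow.

What the generator does **not** emulate: conformational change of the
peptide (jitter is memory-less, so Calpha-RMSD stays near the jitter
amplitude rather than the 0.3 nm of real fibrils), unbinding/rebinding
kinetics, solvent degrees of freedom, and force-field realism.  Passing
end-to-end tests therefore demonstrates that the *analysis* recovers
injected ground truth -- binding sites, kinetic regimes, interaction
fingerprints -- not that the toy systems reproduce any published
trajectory-derived number.

## Detectors

All thresholds live in `GeometryThresholds` with the field's standard
values: atomic contact = two non-hydrogen atoms within 0.54 nm (counted
per atom pair); hydrogen bond = donor-acceptor distance strictly below
0.35 nm and D-H-A angle at the hydrogen strictly above 150 deg;
pi-stacking = aromatic-ring centroid within 0.45 nm of the spherical
carbon surface.  The surface distance is radial by default
(`|centroid - cage centre| - cage radius`, hydroxyl O/H excluded from
the cage), because the criterion refers to a spherical surface; a
nearest-carbon variant sits behind `pistack_mode`.  Ring orientation is
the tilt between ring plane and local tangent plane: parallel < 30 deg,
herringbone 30-70 deg (placing the ~50 deg arrangement centrally),
T-shaped > 70 deg; the bin edges are a package choice since only the
class names and the ~50 deg anchor are standard.  Boundary ties at
floating-point equality are excluded everywhere.

Binding onset is the first time d_min <= 0.30 nm while staying below
0.45 nm for a 1 ns persistence window (the window suppresses grazing
contacts); onsets at <= 3 ns classify fast, later ones slow.  Bound
frames are those at/after onset with d_min <= 0.45 nm; site occupancy is
the fraction of bound frames whose dominant-contact residue (argmax of
chain-summed per-residue contacts, ties to the lowest residue number)
falls in each site.  Salt bridges use charged-group centres within
0.46 nm, a standard convention.  Minimum-image periodicity is applied
for orthorhombic boxes only; triclinic cells are rejected.

Calpha-RMSD uses closed-form Kabsch superposition (SVD with reflection
guard).

## MM/PBSA

Single-trajectory end-point scheme: complex, receptor and ligand
conformations all come from the complex trajectory, so bonded terms
cancel and

dG_bind = dE_vdW + dE_elec + dG_polar + dG_nonpolar - T*dS,

with -T*dS fixed at zero and flagged ignored (the usual convention for
relative binding energies).  dE terms are full pairwise sums (no cutoff;
the systems are finite), Coulomb screened by the solute dielectric.
dG_nonpolar = gamma*SASA + b with gamma = 0.542 kcal/mol/nm^2,
b = 0.92 kcal/mol and a 0.14 nm probe; note the three-state difference
equals gamma*dSASA - b.  SASA is Shrake-Rupley with a deterministic
golden-spiral point set (960 points by default); per-atom areas sum to
the total exactly.

dG_polar comes from a from-scratch finite-difference linearised
Poisson-Boltzmann solver: 7-point stencil, dielectric 2 inside atom
spheres and 80 outside, face coefficients from a three-point harmonic
average along each grid edge (locating the boundary to sub-spacing
accuracy), Debye-Hueckel screening at 0.1 M and 310 K in the solvent
region, screened-monopole Dirichlet boundaries, charges spread
trilinearly and potentials read back trilinearly.  The grid self-energy
is removed by the standard two-solve scheme (solvated minus uniform-
dielectric reference on the identical grid), and all three states of a
frame share one grid so per-charge discretisation errors cancel in the
complex-minus-parts difference.  The symmetric positive-definite system
is solved by Jacobi-preconditioned conjugate gradients to a 1e-6
relative residual (default).  At the default 0.05 nm spacing the solver
reproduces the Born closed form within ~1%, degrading to ~5-7% at the
0.15 nm spacing the desk-scale pipeline uses; accuracy improves
monotonically under refinement.

Per-residue decomposition attributes pairwise MM terms to the receptor
residue of each pair (summing exactly to the totals), the nonpolar term
through each residue's buried SASA, and the polar term through the
per-charge reaction-field energies (complex minus isolated receptor) --
one defensible allocation among several, chosen because it needs no
extra solves.  Chain-equivalent residues are averaged over the three
chains.  Site energies are conditional means of the per-frame dG_bind
over frames whose dominant contact lies in the site; unvisited sites
report no-data rather than zero.

Components are averaged over the trailing 20 ns window of each run
(energy evaluated every 5 ns of toy time -- four frames per run -- a
desk-scale stride chosen because the docked-pose fluctuations decorrelate
within one frame) and reported as mean +- SEM across the six runs.

## Numerical and design choices

* Internal units nm/ps/kJ/mol/e; kcal/mol only at reporting (factor
  4.184).
* The pipeline's PB grid (0.15 nm, tolerance 1e-5, 384 SASA points) is a
  deliberate desk-scale setting; the defaults in `PBParameters`
  (0.05 nm, 1e-6, 960 points) are the accuracy-grade settings used by
  the validation suite.
* Coincident identical atoms in SASA count their surface once (kept on
  the larger-radius or lowest-index atom) -- a degenerate-input rule.
* PB non-convergence raises with the residual; a grid coarser than the
  smallest atomic radius warns.
* The published component table bundled under `data/` is used only for
  additivity audits (`compare_breakdowns`), never as a fitting target.

## Known limitations

* The extended-strand receptor is ~14 nm long, unlike the folded
  S-shaped chains of real fibrils; absolute energies and SASA values are
  therefore not comparable to experiment, only the relative/qualitative
  structure is meaningful.
* The linear PB solver has no Stern layer and uses a monopole boundary;
  both are adequate for the neutral-to-moderately-charged systems here.
* Histidine's aromatic ring is six-membered in the reduced
  representation.
* Toy trajectories cannot produce unbinding statistics; occupancy
  probabilities are conditional on the single injected site per run.
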