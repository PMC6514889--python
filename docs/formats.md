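# File formats

All coordinates are nanometres internally; times are picoseconds.

## PDB (fixed-width)

Standard wwPDB fixed-width records via biotite.  Receptor chains are ATOM
records with chain identifiers A, B, C, ...; the nanoparticle is written
as HETATM records with residue name `FUL` on chain `L`.  On reading, any
residue named `FUL` is assigned the ligand role.  Coordinates convert
Angstrom <-> nm on the way in/out.  Only MODEL 1 of multi-model files is
used.

## GRO-style coordinates

```
<title line>
<natoms, %5d>
%5d%-5s%5s%5d%8.3f%8.3f%8.3f     (resnum resname atomname atomnum x y z)
...
%10.5f%10.5f%10.5f                (box diagonal, nm)
```

GRO carries no chain identifiers.  The writer keeps chain-scoped residue
numbering (1..L per chain); the reader starts a new chain (A, B, ...)
whenever the residue number decreases, which recovers the chains of any
file this package writes.

## Trajectory (plain text, optional gzip)

```
# fullerbind trajectory v1
natoms <N>
frame t= <time ps> box <bx> <by> <bz>
<x> <y> <z>          (N lines, %.6f nm)
...repeat per frame...
```

A `.gz` suffix selects transparent gzip compression.  A box of `0 0 0`
means "no periodic cell".  Readers must reject frames whose atom count
differs from the header and report the number of complete frames
recovered when the file is truncated.

## Topology table (TSV)

One row per atom, tab-separated, matching the coordinate file by the
`index` column:

```
index  name  element  residue_number  residue_name  chain_id  role
charge  lj_epsilon  lj_sigma  radius
```

Units: charge in elementary charges, LJ well depth kJ/mol, LJ diameter
nm, PB/SASA radius nm.  The donor/acceptor/aromatic-ring tables are
derived after loading: donors are N/O atoms with a hydrogen within
0.125 nm, acceptors are all N/O atoms, rings come from the F/Y/H residue
templates (atom names CG, CD1, CE1, CZ, CE2, CD2).

## Analysis configuration (YAML)

`AnalysisConfig.save/load` round-trips three blocks -- `thresholds`
(contact/H-bond/pi-stacking/binding cutoffs), `sasa` (probe radius,
gamma, b, sphere points) and `pb` (dielectrics, ionic strength,
temperature, grid spacing, margin, solver tolerance).  Every analysis
header records the configuration it used.
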