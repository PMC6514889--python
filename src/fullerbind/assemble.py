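"""Assembly of complete receptor-ligand systems from the synthetic models."""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .cage import CageModel, build_cage
from .forcefield import ToyForceField
from .geometry import minimum_distance
from .protofibril import AB42_SEQUENCE, ProtofibrilModel, build_protofibril
from .system import MolecularSystem, make_atom_table


def approach_direction(fibril: ProtofibrilModel,
                       target_site: Optional[tuple[int, int]],
                       face_residue: Optional[int] = None) -> np.ndarray:
    """Unit vector pointing away from the sheet toward the ligand start.

    The ligand approaches the side-chain face of the site: the face of the
    site's first aromatic residue when it has one (aromatic stacking is the
    interesting contact geometry), otherwise of its middle residue.  Side
    chains alternate sides of the sheet, so the sign of y follows that
    residue's parity.
    """
    if target_site is None:
        target_site = (1, len(fibril.sequence))
    lo, hi = target_site
    pick = face_residue
    if pick is None:
        pick = (lo + hi) // 2
        for resnum in range(lo, hi + 1):
            if fibril.sequence[resnum - 1] in "FYH":
                pick = resnum
                break
    s = 1.0 if (pick - 1) % 2 == 0 else -1.0
    return np.array([0.0, -s, 0.0])


def site_anchor(fibril: ProtofibrilModel,
                target_site: Optional[tuple[int, int]]) -> np.ndarray:
    """Geometric anchor of a residue-range site: centroid of its Calphas."""
    if target_site is None:
        target_site = (1, len(fibril.sequence))
    lo, hi = target_site
    if not (1 <= lo <= hi <= len(fibril.sequence)):
        raise ValueError(f"site {target_site} outside sequence "
                         f"1..{len(fibril.sequence)}")
    pts = [xyz for rec, xyz in zip(fibril.atom_records, fibril.coordinates)
           if rec["name"] == "CA" and lo <= rec["residue_number"] <= hi]
    return np.mean(pts, axis=0)


def build_complex(sequence: str = AB42_SEQUENCE, n_chains: int = 3,
                  n_hydroxyl: int = 0, seed: int = 0,
                  separation: float = 2.0,
                  target_site: Optional[tuple[int, int]] = None,
                  face_residue: Optional[int] = None,
                  forcefield: Optional[ToyForceField] = None) -> MolecularSystem:
    """Build protofibril + cage, place the cage ``separation`` nm away.

    The separation is a minimum interatomic distance, achieved by moving the
    cage along the approach direction until d_min matches.  The cage gets a
    seeded random initial orientation.  The reference coordinates carry no
    box; trajectory generation attaches one.
    """
    fibril = build_protofibril(sequence, n_chains)
    cage = build_cage(n_hydroxyl, seed=seed)
    forcefield = forcefield or ToyForceField()

    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2 ** 31))))
    cage_xyz = cage.all_positions() @ rot.as_matrix().T

    u = approach_direction(fibril, target_site, face_residue)
    anchor = site_anchor(fibril, target_site)
    centre = anchor + u * (separation + 1.5)
    rec_xyz = fibril.coordinates
    for _ in range(50):
        d = minimum_distance(rec_xyz, cage_xyz + centre)
        if abs(d - separation) < 1e-9:
            break
        centre = centre + u * (separation - d)

    records = []
    for rec in fibril.atom_records:
        records.append(dict(rec, index=len(records) + 1, charge=0.0,
                            lj_epsilon=0.0, lj_sigma=0.0, radius=0.0))
    for rec in cage.to_atom_records():
        records.append(dict(rec, index=len(records) + 1, charge=0.0,
                            lj_epsilon=0.0, lj_sigma=0.0, radius=0.0))
    atoms = forcefield.assign(make_atom_table(records))
    coords = np.vstack([rec_xyz, cage_xyz + centre])
    return MolecularSystem(atoms=atoms, coordinates=coords)
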