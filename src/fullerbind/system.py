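"""In-memory containers: atoms, molecular systems and trajectories.

A :class:`MolecularSystem` couples a per-atom parameter table (a pandas
DataFrame) with reference coordinates and the derived lookup tables the
geometric detectors need (hydrogen-bond donors/acceptors and aromatic rings).
Receptor atoms are the peptide chains; the single nanoparticle is the ligand.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import TopologyError

#: Column order of the atom table.
ATOM_COLUMNS = [
    "index", "name", "element", "residue_number", "residue_name",
    "chain_id", "role", "charge", "lj_epsilon", "lj_sigma", "radius",
]

#: Backbone atom names; used to classify hydrogen-bond partners as
#: main-chain vs side-chain.
BACKBONE_NAMES = frozenset({"N", "H", "CA", "C", "O"})

#: Ligand residue name convention for fullerene/fullerenol HETATM records.
LIGAND_RESNAME = "FUL"

#: Maximum distance (nm) for a covalent X-H bond when inferring donors.
_XH_BOND_CUTOFF = 0.125


@dataclass
class AromaticRing:
    """Six-membered aromatic ring of one residue (F/Y/H templates)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_indices: np.ndarray  # positional indices of the 6 ring atoms


@dataclass
class MolecularSystem:
    """Atoms plus reference coordinates of a receptor-ligand complex.

    ``atoms`` holds one row per atom with identity, role and force-field
    parameters (charge e, LJ epsilon kJ/mol, LJ sigma nm, PB/SASA radius nm).
    ``coordinates`` are the reference coordinates in nm, in atom-table order.
    """

    atoms: pd.DataFrame
    coordinates: np.ndarray
    donors: np.ndarray = field(default=None)      # (k, 2) heavy, hydrogen
    acceptors: np.ndarray = field(default=None)   # (m,) positional indices
    rings: list = field(default_factory=list)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise TopologyError(
                f"coordinate array shape {self.coordinates.shape} does not "
                f"match {len(self.atoms)} atoms")
        if self.atoms["index"].duplicated().any():
            raise TopologyError("duplicate atom indices in atom table")
        if self.donors is None or self.acceptors is None:
            self.rebuild_interaction_tables()

    # -- derived selections ------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.atoms["role"].to_numpy() == "receptor")

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.flatnonzero(self.atoms["role"].to_numpy() == "ligand")

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.atoms["element"].to_numpy() != "H"

    def ligand_carbon_indices(self) -> np.ndarray:
        """Cage carbons of the ligand (hydroxyl O/H excluded)."""
        el = self.atoms["element"].to_numpy()
        role = self.atoms["role"].to_numpy()
        return np.flatnonzero((role == "ligand") & (el == "C"))

    def receptor_residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_number) pairs of the receptor."""
        rec = self.atoms.iloc[self.receptor_indices]
        seen, out = set(), []
        for c, r in zip(rec["chain_id"], rec["residue_number"]):
            if (c, r) not in seen:
                seen.add((c, r))
                out.append((c, r))
        return out

    def residue_atom_indices(self, chain_id: str,
                             residue_number: int) -> np.ndarray:
        a = self.atoms
        mask = ((a["chain_id"].to_numpy() == chain_id)
                & (a["residue_number"].to_numpy() == residue_number))
        return np.flatnonzero(mask)

    def find_atom(self, chain_id: str, residue_number: int,
                  name: str) -> int:
        idx = self.residue_atom_indices(chain_id, residue_number)
        names = self.atoms["name"].to_numpy()[idx]
        hit = idx[names == name]
        if len(hit) == 0:
            raise KeyError(
                f"no atom {name!r} in {chain_id}:{residue_number}")
        return int(hit[0])

    # -- interaction tables ------------------------------------------------
    def rebuild_interaction_tables(self) -> None:
        """Derive donor/acceptor/ring tables from names and coordinates.

        Donors are N/O atoms with a covalently bonded hydrogen (inferred by
        an X-H distance below 0.125 nm in the reference coordinates);
        acceptors are all N/O atoms; rings come from the F/Y/H residue
        templates (atom names CG, CD1, CD2, CE1, CE2, CZ).
        """
        el = self.atoms["element"].to_numpy()
        heavy_no = np.flatnonzero((el == "N") | (el == "O"))
        hydrogens = np.flatnonzero(el == "H")
        donors = []
        if len(heavy_no) and len(hydrogens):
            from scipy.spatial import cKDTree

            tree = cKDTree(self.coordinates[hydrogens])
            for i in heavy_no:
                for jh in tree.query_ball_point(self.coordinates[i],
                                                _XH_BOND_CUTOFF):
                    donors.append((i, hydrogens[jh]))
        self.donors = (np.asarray(donors, dtype=int)
                       if donors else np.empty((0, 2), dtype=int))
        self.acceptors = heavy_no
        self.rings = self._find_rings()

    def _find_rings(self) -> list[AromaticRing]:
        ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        rings = []
        a = self.atoms
        aromatic = a[(a["role"] == "receptor")
                     & a["residue_name"].isin(["PHE", "TYR", "HIS"])]
        for (chain, resnum, resname), grp in aromatic.groupby(
                ["chain_id", "residue_number", "residue_name"], sort=False):
            names = grp["name"].tolist()
            if all(n in names for n in ring_names):
                pos = {n: i for n, i in zip(grp["name"], grp.index)}
                idx = np.array([a.index.get_loc(pos[n]) for n in ring_names])
                rings.append(AromaticRing(chain, int(resnum), resname, idx))
        return rings


@dataclass
class Frame:
    """One trajectory frame: time (ps), coordinates (nm), box diagonal (nm)."""

    time: float
    coordinates: np.ndarray
    box: Optional[np.ndarray] = None


@dataclass
class Trajectory:
    """Ordered frames with strictly increasing time stamps.

    Coordinates are a dense (n_frames, n_atoms, 3) array in nm; boxes are
    the diagonals of orthorhombic cells, (n_frames, 3), or None for
    non-periodic systems.
    """

    times: np.ndarray
    coordinates: np.ndarray
    boxes: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3:
            raise ValueError("coordinates must be (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coordinates):
            raise ValueError("times and coordinates length mismatch")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> Frame:
        box = None if self.boxes is None else self.boxes[i]
        return Frame(float(self.times[i]), self.coordinates[i], box)

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def window(self, t_start: float, t_end: float = np.inf) -> "Trajectory":
        """Sub-trajectory with t_start <= time <= t_end."""
        mask = (self.times >= t_start) & (self.times <= t_end)
        boxes = None if self.boxes is None else self.boxes[mask]
        return Trajectory(self.times[mask], self.coordinates[mask], boxes)


def make_atom_table(records: list[dict]) -> pd.DataFrame:
    """Build a validated atom table from per-atom dictionaries."""
    df = pd.DataFrame(records, columns=ATOM_COLUMNS)
    if df["element"].eq("").any():
        raise TopologyError("empty element field in atom table")
    return df
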