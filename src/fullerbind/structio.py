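"""File formats: PDB, GRO-style coordinates, topology tables, trajectories.

Internal units are nm everywhere; the PDB reader/writer converts from/to
Angstrom.  Receptor chains are written as ATOM records (chains A, B, C...),
the nanoparticle as HETATM records with residue name FUL -- and conversely
any FUL residue read from file is assigned the ligand role.

The GRO-style and trajectory formats are plain text and documented in
docs/formats.md.  GRO files carry no chain identifiers; the reader starts a
new chain whenever the residue number decreases, which round-trips the
chain-scoped 1..L numbering this package writes.
"""
from __future__ import annotations

import gzip
import warnings
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import ParseError, TopologyError
from .system import (LIGAND_RESNAME, Frame, MolecularSystem, Trajectory,
                     make_atom_table)

_IDENTITY_COLUMNS = ["index", "name", "element", "residue_number",
                     "residue_name", "chain_id", "role"]


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def write_pdb(system: MolecularSystem, path) -> None:
    """Write the system as a fixed-width PDB file (coordinates nm -> A)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(system.coordinates) * 10.0
    a = system.atoms
    arr.chain_id = a["chain_id"].to_numpy().astype(str)
    arr.res_id = a["residue_number"].to_numpy()
    arr.res_name = a["residue_name"].to_numpy().astype(str)
    arr.atom_name = a["name"].to_numpy().astype(str)
    arr.element = a["element"].to_numpy().astype(str)
    arr.hetero = (a["role"].to_numpy() == "ligand")
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_pdb(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a PDB file; returns (identity table, coordinates in nm).

    Only MODEL 1 of multi-model files is used.  Missing elements are
    inferred from the first letter of the atom name, with a warning.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises various parse errors
        raise ParseError(f"malformed PDB file {path}: {exc}") from exc
    elements = np.asarray(arr.element, dtype=str)
    missing = elements == ""
    if missing.any():
        warnings.warn(f"{missing.sum()} atoms lack an element; inferring "
                      "from atom names")
        names = np.asarray(arr.atom_name, dtype=str)
        elements = np.where(missing,
                            [n.lstrip("0123456789")[:1] for n in names],
                            elements)
    records = []
    for i in range(arr.array_length()):
        resname = str(arr.res_name[i])
        records.append(dict(
            index=i + 1, name=str(arr.atom_name[i]),
            element=str(elements[i]),
            residue_number=int(arr.res_id[i]), residue_name=resname,
            chain_id=str(arr.chain_id[i]),
            role="ligand" if resname == LIGAND_RESNAME else "receptor"))
    return pd.DataFrame(records, columns=_IDENTITY_COLUMNS), arr.coord / 10.0


# ---------------------------------------------------------------------------
# GRO-style
# ---------------------------------------------------------------------------

def write_gro(system: MolecularSystem, path, box=None,
              title: str = "fullerbind system") -> None:
    """GRO-style fixed-width coordinates, nm, 3 decimals."""
    a = system.atoms
    lines = [title, f"{system.n_atoms:5d}"]
    for i, ((_, row), xyz) in enumerate(
            zip(a.iterrows(), system.coordinates), start=1):
        lines.append(
            f"{row['residue_number']:5d}{row['residue_name']:<5s}"
            f"{row['name']:>5s}{i % 100000:5d}"
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}")
    if box is None:
        span = (system.coordinates.max(axis=0)
                - system.coordinates.min(axis=0) + 2.0)
    else:
        span = np.asarray(box, dtype=float)
    lines.append(f"{span[0]:10.5f}{span[1]:10.5f}{span[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gro(path) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Read GRO-style coordinates; returns (identity table, xyz nm, box).

    Chains restart (A, B, ...) whenever the residue number decreases.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"GRO file {path} too short", line=len(lines))
    try:
        n = int(lines[1])
    except ValueError as exc:
        raise ParseError("invalid atom count", line=2) from exc
    if len(lines) < n + 3:
        raise ParseError(f"expected {n} atom lines", line=len(lines))
    records, coords = [], []
    chain_ord, prev_resnum = 0, -1
    for k in range(n):
        ln = lines[2 + k]
        try:
            resnum = int(ln[0:5])
            resname = ln[5:10].strip()
            name = ln[10:15].strip()
            xyz = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except ValueError as exc:
            raise ParseError(f"malformed GRO atom record: {ln!r}",
                             line=3 + k) from exc
        if resnum < prev_resnum:
            chain_ord += 1
        prev_resnum = resnum
        records.append(dict(
            index=k + 1, name=name,
            element=name.lstrip("0123456789")[:1],
            residue_number=resnum, residue_name=resname,
            chain_id=chr(ord("A") + chain_ord),
            role="ligand" if resname == LIGAND_RESNAME else "receptor"))
        coords.append(xyz)
    box = np.array([float(x) for x in lines[2 + n].split()[:3]])
    return (pd.DataFrame(records, columns=_IDENTITY_COLUMNS),
            np.array(coords), box)


def read_structure(path, fmt: Optional[str] = None):
    """Dispatch to the PDB or GRO reader; format inferred from the suffix.

    Returns (identity table, coordinates nm); the GRO box is dropped here.
    """
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = {"pdb": "pdb", ".pdb": "pdb", ".gro": "gro"}.get(suffix, None)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path}")
    if fmt == "pdb":
        return read_pdb(path)
    if fmt in ("gro", "gro-style"):
        table, coords, _ = read_gro(path)
        return table, coords
    raise ValueError(f"unknown structure format {fmt!r}")


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

_TOPOLOGY_COLUMNS = ["index", "name", "element", "residue_number",
                     "residue_name", "chain_id", "role", "charge",
                     "lj_epsilon", "lj_sigma", "radius"]


def write_topology(system: MolecularSystem, path) -> None:
    """Tabular topology: one row per atom with charge/LJ/radius."""
    system.atoms[_TOPOLOGY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_topology(path) -> pd.DataFrame:
    """Read a topology table; warns when the total charge is non-integral."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise TopologyError(f"topology {path} lacks columns {missing}")
    total = df["charge"].sum()
    if abs(total - round(total)) > 1e-6:
        warnings.warn(f"total charge {total:.4f} is not integral")
    return df


def build_system(structure_table: pd.DataFrame, coordinates: np.ndarray,
                 topology: pd.DataFrame) -> MolecularSystem:
    """Join coordinates with a topology table into a validated system.

    Atom indices of the topology must match the coordinate table exactly;
    missing or surplus rows are reported by index.
    """
    struct_idx = structure_table["index"].to_numpy()
    topo_idx = topology["index"].to_numpy()
    missing = sorted(set(struct_idx) - set(topo_idx))
    surplus = sorted(set(topo_idx) - set(struct_idx))
    if missing or surplus:
        raise TopologyError(
            f"topology mismatch: missing atom rows {missing[:10]}, "
            f"surplus rows {surplus[:10]}")
    topo = topology.set_index("index").loc[struct_idx].reset_index()
    atoms = make_atom_table([
        dict(row, index=int(row["index"]))
        for row in topo[_TOPOLOGY_COLUMNS].to_dict("records")])
    return MolecularSystem(atoms=atoms, coordinates=coordinates)


def load_system(structure_path, topology_path) -> MolecularSystem:
    table, coords = read_structure(structure_path)
    return build_system(table, coords, read_topology(topology_path))


# ---------------------------------------------------------------------------
# trajectory text format
# ---------------------------------------------------------------------------

_TRAJ_MAGIC = "# fullerbind trajectory v1"


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Plain-text multi-frame format (optionally gzip via a .gz suffix)."""
    with _open_text(path, "wt") as fh:
        fh.write(_TRAJ_MAGIC + "\n")
        fh.write(f"natoms {trajectory.n_atoms}\n")
        for frame in trajectory:
            box = frame.box if frame.box is not None else np.zeros(3)
            fh.write(f"frame t= {frame.time:.6f} box "
                     f"{box[0]:.6f} {box[1]:.6f} {box[2]:.6f}\n")
            np.savetxt(fh, frame.coordinates, fmt="%.6f")


def iter_trajectory_frames(path) -> Iterator[Frame]:
    """Stream frames from a trajectory file without loading it whole."""
    with _open_text(path) as fh:
        header = fh.readline().strip()
        if header != _TRAJ_MAGIC:
            raise ParseError(f"not a fullerbind trajectory: {header!r}",
                             line=1)
        natoms_line = fh.readline().split()
        if len(natoms_line) != 2 or natoms_line[0] != "natoms":
            raise ParseError("missing natoms header", line=2)
        n = int(natoms_line[1])
        frame_index = 0
        while True:
            head = fh.readline()
            if not head:
                return
            parts = head.split()
            if len(parts) != 7 or parts[0] != "frame":
                raise ParseError(f"bad frame header {head!r}",
                                 frame=frame_index)
            time = float(parts[2])
            box = np.array([float(x) for x in parts[4:7]])
            coords = np.empty((n, 3))
            for k in range(n):
                ln = fh.readline()
                if not ln or ln.startswith("frame"):
                    raise ParseError(
                        f"truncated frame (got {k} of {n} atoms); "
                        f"{frame_index} complete frames recovered",
                        frame=frame_index)
                vals = ln.split()
                if len(vals) != 3:
                    raise ParseError(f"bad coordinate line {ln!r}",
                                     frame=frame_index)
                coords[k] = [float(v) for v in vals]
            yield Frame(time, coords,
                        box if np.any(box > 0) else None)
            frame_index += 1


def read_trajectory(path, expected_atoms: Optional[int] = None) -> Trajectory:
    """Read a whole trajectory file into memory.

    ``expected_atoms`` cross-checks the file header against a known system.
    """
    frames = []
    for frame in iter_trajectory_frames(path):
        if expected_atoms is not None and len(frame.coordinates) != \
                expected_atoms:
            raise ParseError(
                f"trajectory atom count {len(frame.coordinates)} does not "
                f"match system ({expected_atoms})", frame=len(frames))
        frames.append(frame)
    if not frames:
        raise ParseError("trajectory contains no frames")
    boxes = None
    if all(f.box is not None for f in frames):
        boxes = np.array([f.box for f in frames])
    return Trajectory(
        times=np.array([f.time for f in frames]),
        coordinates=np.array([f.coordinates for f in frames]),
        boxes=boxes)
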