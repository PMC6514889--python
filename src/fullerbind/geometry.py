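"""Geometric interaction detectors and time-series analyses.

Implements the trajectory observables used to characterise nanoparticle
binding: minimum receptor-ligand distance, per-residue heavy-atom contacts,
geometric hydrogen bonds, pi-stacking against the spherical carbon surface,
Calpha-RMSD after optimal superposition, binding-onset classification,
binding-site occupancy and salt-bridge persistence.

Periodic boundary conditions are supported for orthorhombic boxes through
the minimum-image convention; triclinic boxes are rejected.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import GeometryThresholds
from .system import BACKBONE_NAMES, MolecularSystem, Trajectory


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _as_box_diagonal(box) -> Optional[np.ndarray]:
    if box is None:
        return None
    box = np.asarray(box, dtype=float)
    if box.ndim == 2:
        if np.any(np.abs(box - np.diag(np.diag(box))) > 1e-12):
            raise ValueError("triclinic boxes are not supported; "
                             "only orthorhombic (diagonal) cells")
        box = np.diag(box)
    return box


def _pair_deltas(a: np.ndarray, b: np.ndarray, box) -> np.ndarray:
    """All cross-group displacement vectors, minimum image if box given."""
    delta = a[:, None, :] - b[None, :, :]
    box = _as_box_diagonal(box)
    if box is not None:
        delta -= box * np.round(delta / box)
    return delta


def pair_distances(a: np.ndarray, b: np.ndarray, box=None) -> np.ndarray:
    """(len_a, len_b) matrix of minimum-image distances in nm."""
    return np.linalg.norm(_pair_deltas(np.asarray(a), np.asarray(b), box),
                          axis=-1)


def minimum_distance(coords_a: np.ndarray, coords_b: np.ndarray,
                     box=None) -> float:
    """Smallest distance between any atom of group a and any of group b."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("minimum_distance requires two non-empty groups")
    return float(pair_distances(a, b, box).min())


def minimum_distance_series(system: MolecularSystem,
                            trajectory: Trajectory) -> np.ndarray:
    """d_min(t) between receptor and ligand over a trajectory."""
    ri, li = system.receptor_indices, system.ligand_indices
    out = np.empty(trajectory.n_frames)
    for i, frame in enumerate(trajectory):
        out[i] = minimum_distance(frame.coordinates[ri],
                                  frame.coordinates[li], frame.box)
    return out


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

@dataclass
class ContactSeries:
    """Per-residue, per-frame counts of receptor-ligand heavy-atom pairs."""

    counts: np.ndarray          # (n_residues, n_frames) integer
    chain_ids: list             # per row
    residue_numbers: np.ndarray  # per row
    times: np.ndarray            # ps

    def by_sequence_position(self) -> tuple[np.ndarray, np.ndarray]:
        """Sum counts over chains; returns (residue_numbers, matrix)."""
        resnums = np.unique(self.residue_numbers)
        out = np.zeros((len(resnums), self.counts.shape[1]), dtype=int)
        for k, rn in enumerate(resnums):
            out[k] = self.counts[self.residue_numbers == rn].sum(axis=0)
        return resnums, out


def _contact_groups(system: MolecularSystem):
    """Heavy receptor atoms with their residue-row mapping, heavy ligand."""
    heavy = system.heavy_mask
    residues = system.receptor_residues()
    row_of = {key: k for k, key in enumerate(residues)}
    rec = system.receptor_indices
    rec = rec[heavy[rec]]
    a = system.atoms
    rows = np.array([row_of[(c, r)] for c, r in zip(
        a["chain_id"].to_numpy()[rec], a["residue_number"].to_numpy()[rec])])
    lig = system.ligand_indices
    lig = lig[heavy[lig]]
    return residues, rec, rows, lig


def contact_counts(system: MolecularSystem, coordinates: np.ndarray,
                   box=None,
                   thresholds: GeometryThresholds | None = None
                   ) -> np.ndarray:
    """Heavy-atom contact count per receptor residue for one frame.

    A contact is a (receptor heavy atom, ligand heavy atom) pair within the
    contact cutoff; counting is per atom pair.
    """
    thresholds = thresholds or GeometryThresholds()
    residues, rec, rows, lig = _contact_groups(system)
    out = np.zeros(len(residues), dtype=int)
    if len(rec) and len(lig):
        d = pair_distances(coordinates[rec], coordinates[lig], box)
        np.add.at(out, rows,
                  (d < thresholds.contact_cutoff).sum(axis=1))
    return out


def contact_series(system: MolecularSystem, trajectory: Trajectory,
                   thresholds: GeometryThresholds | None = None
                   ) -> ContactSeries:
    thresholds = thresholds or GeometryThresholds()
    residues, rec, rows, lig = _contact_groups(system)
    counts = np.zeros((len(residues), trajectory.n_frames), dtype=int)
    for i, frame in enumerate(trajectory):
        if len(rec) and len(lig):
            d = pair_distances(frame.coordinates[rec],
                               frame.coordinates[lig], frame.box)
            np.add.at(counts[:, i], rows,
                      (d < thresholds.contact_cutoff).sum(axis=1))
    return ContactSeries(
        counts=counts,
        chain_ids=[c for c, _ in residues],
        residue_numbers=np.array([r for _, r in residues]),
        times=trajectory.times.copy(),
    )


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HBondEvent:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float       # D-A, nm
    angle: float          # D-H-A, deg
    partner_class: str    # main_chain / side_chain (receptor-side atom)
    frame_index: int


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbonds(system: MolecularSystem, coordinates: np.ndarray,
                  box=None,
                  thresholds: GeometryThresholds | None = None,
                  partner_scope: str = "intermolecular",
                  frame_index: int = 0) -> list[HBondEvent]:
    """All (donor, hydrogen, acceptor) triples passing both criteria.

    ``partner_scope``: "intermolecular" keeps donor and acceptor on opposite
    sides of the receptor/ligand partition; "interchain" keeps receptor
    pairs on different chains; "all" applies no partition filter.
    Both criteria are strict inequalities; the D-H-A angle is measured at
    the hydrogen.
    """
    thresholds = thresholds or GeometryThresholds()
    if len(system.donors) == 0 or len(system.acceptors) == 0:
        return []
    roles = system.atoms["role"].to_numpy()
    chains = system.atoms["chain_id"].to_numpy()
    names = system.atoms["name"].to_numpy()
    donors = system.donors
    acceptors = system.acceptors

    d_xyz = coordinates[donors[:, 0]]
    a_xyz = coordinates[acceptors]
    dist = pair_distances(d_xyz, a_xyz, box)
    box_diag = _as_box_diagonal(box)

    events = []
    for di, ai in zip(*np.where(dist < thresholds.hbond_da_cutoff)):
        d_idx, h_idx = int(donors[di, 0]), int(donors[di, 1])
        a_idx = int(acceptors[ai])
        if a_idx == d_idx:
            continue
        if partner_scope == "intermolecular":
            if roles[d_idx] == roles[a_idx]:
                continue
        elif partner_scope == "interchain":
            if roles[d_idx] != roles[a_idx] or chains[d_idx] == chains[a_idx]:
                continue
        h = coordinates[h_idx]
        v_d = coordinates[d_idx] - h
        v_a = coordinates[a_idx] - h
        if box_diag is not None:
            v_d -= box_diag * np.round(v_d / box_diag)
            v_a -= box_diag * np.round(v_a / box_diag)
        angle = _angle_deg(v_d, v_a)
        if angle <= thresholds.hbond_angle_min:
            continue
        # classify by the receptor-side atom of the pair
        rec_atom = d_idx if roles[d_idx] == "receptor" else a_idx
        partner = ("main_chain" if names[rec_atom] in BACKBONE_NAMES
                   else "side_chain")
        events.append(HBondEvent(d_idx, h_idx, a_idx,
                                 float(dist[di, ai]), angle, partner,
                                 frame_index))
    return events


# ---------------------------------------------------------------------------
# pi-stacking
# ---------------------------------------------------------------------------

@dataclass
class PiStackEvent:
    chain_id: str
    residue_number: int
    residue_name: str
    surface_distance: float   # ring centroid to cage surface, nm
    angle: float              # ring tilt vs local tangent plane, deg
    orientation: str          # parallel / herringbone / t_shaped
    frame_index: int


def classify_ring_orientation(angle: float) -> str:
    """Orientation class from the ring tilt angle (0..90 deg).

    Tilt is the angle between the ring plane and the local tangent plane of
    the cage: below 30 deg is parallel, 30-70 deg herringbone (the ~50 deg
    arrangement falls centrally in this bin), above 70 deg T-shaped.
    """
    if not (0.0 <= angle <= 90.0):
        raise ValueError("tilt angle must be folded into [0, 90] deg")
    if angle < 30.0:
        return "parallel"
    if angle <= 70.0:
        return "herringbone"
    return "t_shaped"


def _ring_normal(ring_xyz: np.ndarray) -> np.ndarray:
    centred = ring_xyz - ring_xyz.mean(axis=0)
    _, s, vt = np.linalg.svd(centred)
    if s[1] < 1e-8:
        raise ValueError("degenerate ring: atoms are collinear")
    return vt[2]


def detect_pi_stacking(system: MolecularSystem, coordinates: np.ndarray,
                       box=None,
                       thresholds: GeometryThresholds | None = None,
                       frame_index: int = 0) -> list[PiStackEvent]:
    """Aromatic rings stacked against the carbon cage surface.

    In the default "radial" mode the distance to the spherical carbon
    surface is |ring centroid - cage centroid| - cage_radius, with the cage
    centroid and radius computed from cage carbons only (hydroxyl O/H
    excluded).  The alternative "nearest-carbon" mode uses the smallest
    centroid-to-carbon distance instead.  The reported angle is the ring
    tilt relative to the local tangent plane of the cage, i.e. the angle
    between the ring normal and the radial direction, folded into [0, 90].
    """
    thresholds = thresholds or GeometryThresholds()
    carbons = system.ligand_carbon_indices()
    if len(carbons) == 0:
        return []
    cage_xyz = coordinates[carbons]
    centroid = cage_xyz.mean(axis=0)
    cage_radius = np.linalg.norm(cage_xyz - centroid, axis=1).mean()

    events = []
    for ring in system.rings:
        ring_xyz = coordinates[ring.atom_indices]
        ring_centroid = ring_xyz.mean(axis=0)
        radial = ring_centroid - centroid
        if thresholds.pistack_mode == "radial":
            surface_d = float(np.linalg.norm(radial) - cage_radius)
        else:
            surface_d = float(np.linalg.norm(
                cage_xyz - ring_centroid, axis=1).min())
        if surface_d >= thresholds.pistack_cutoff:
            continue
        normal = _ring_normal(ring_xyz)
        # tilt between ring plane and tangent plane = angle between their
        # normals (ring normal vs radial direction), folded into [0, 90]
        tilt = _angle_deg(normal, radial)
        tilt = min(tilt, 180.0 - tilt)
        events.append(PiStackEvent(
            ring.chain_id, ring.residue_number, ring.residue_name,
            surface_d, tilt, classify_ring_orientation(tilt), frame_index))
    return events


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal least-squares superposition (Kabsch)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("coordinate sets must have identical (n, 3) shapes")
    if len(mobile) == 0:
        raise ValueError("empty selection")
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (rot @ p.T).T - q
    return float(np.sqrt((diff ** 2).sum() / len(mobile)))


def calpha_rmsd(system: MolecularSystem, coordinates: np.ndarray,
                reference: np.ndarray,
                selection: Optional[np.ndarray] = None) -> float:
    """Calpha RMSD of the receptor after optimal superposition, nm."""
    if selection is None:
        names = system.atoms["name"].to_numpy()
        roles = system.atoms["role"].to_numpy()
        selection = np.flatnonzero((names == "CA") & (roles == "receptor"))
    selection = np.asarray(selection)
    if selection.size == 0:
        raise ValueError("empty selection")
    return kabsch_rmsd(coordinates[selection], reference[selection])


# ---------------------------------------------------------------------------
# binding kinetics and occupancy
# ---------------------------------------------------------------------------

@dataclass
class BindingTime:
    time_ps: Optional[float]   # None when unbound
    regime: str                # fast / slow / unbound


def binding_time(times: np.ndarray, dmin_series: np.ndarray,
                 thresholds: GeometryThresholds | None = None) -> BindingTime:
    """First persistent binding onset and its kinetic regime.

    Binding onset is the first time d_min <= bound threshold while staying
    below the loss-of-contact level for the persistence window; onsets at
    or below the fast/slow boundary are classified fast.
    """
    thresholds = thresholds or GeometryThresholds()
    times = np.asarray(times, dtype=float)
    d = np.asarray(dmin_series, dtype=float)
    if len(times) == 0 or len(times) != len(d):
        raise ValueError("times and dmin series must be equal, non-empty")
    candidates = np.flatnonzero(d <= thresholds.bound_dmin)
    for i in candidates:
        in_window = (times >= times[i]) & (times <= times[i]
                                           + thresholds.persistence_ps)
        if np.all(d[in_window] <= thresholds.unbind_dmin):
            regime = ("fast" if times[i] <= thresholds.fast_regime_ns * 1000.0
                      else "slow")
            return BindingTime(float(times[i]), regime)
    return BindingTime(None, "unbound")


def bound_frame_mask(times: np.ndarray, dmin_series: np.ndarray,
                     thresholds: GeometryThresholds | None = None
                     ) -> np.ndarray:
    """Frames counted as bound: at/after onset with d_min below the
    loss-of-contact level."""
    thresholds = thresholds or GeometryThresholds()
    onset = binding_time(times, dmin_series, thresholds)
    mask = np.zeros(len(times), dtype=bool)
    if onset.time_ps is None:
        return mask
    d = np.asarray(dmin_series, dtype=float)
    mask = (np.asarray(times) >= onset.time_ps) & (d <= thresholds.unbind_dmin)
    return mask


def dominant_residue(contact_by_seq: np.ndarray,
                     residue_numbers: np.ndarray) -> np.ndarray:
    """Per-frame residue number with the largest contact count.

    Ties resolve to the lowest residue number; frames with no contacts get 0.
    """
    counts = np.asarray(contact_by_seq)
    arg = counts.argmax(axis=0)     # argmax returns the first (lowest) max
    out = residue_numbers[arg]
    out = np.where(counts.sum(axis=0) == 0, 0, out)
    return out


def site_occupancy(contact: ContactSeries,
                   sites: dict[str, tuple[int, int]],
                   bound_mask: np.ndarray) -> dict[str, float]:
    """Fraction of bound frames whose dominant-contact residue is in each
    site, plus the remainder under "other".

    Sites are inclusive residue-number ranges and must be disjoint.  With no
    bound frames every probability is NaN.
    """
    covered = set()
    for name, (lo, hi) in sites.items():
        if hi < lo:
            raise ValueError(f"site {name}: empty range {lo}-{hi}")
        span = set(range(lo, hi + 1))
        if covered & span:
            raise ValueError("binding sites must be disjoint residue ranges")
        covered |= span

    bound_mask = np.asarray(bound_mask, dtype=bool)
    n_bound = int(bound_mask.sum())
    if n_bound == 0:
        return {name: float("nan") for name in [*sites, "other"]}
    resnums, by_seq = contact.by_sequence_position()
    dom = dominant_residue(by_seq[:, bound_mask], resnums)
    out = {}
    assigned = np.zeros(n_bound, dtype=bool)
    for name, (lo, hi) in sites.items():
        in_site = (dom >= lo) & (dom <= hi)
        out[name] = float(in_site.mean())
        assigned |= in_site
    out["other"] = float((~assigned).mean())
    return out


# ---------------------------------------------------------------------------
# salt bridges
# ---------------------------------------------------------------------------

#: Default monitored pairs (residue numbers): H6-E11, E11-H13, D23-K28.
SALT_BRIDGE_PRESETS = [(6, 11), (11, 13), (23, 28)]

_CENTRE_NAMES = {"ASP": "OD", "GLU": "OE", "LYS": "NZ", "ARG": "CZ"}


def _group_centre(system: MolecularSystem, chain: str, resnum: int,
                  coordinates: np.ndarray) -> np.ndarray:
    idx = system.residue_atom_indices(chain, resnum)
    if len(idx) == 0:
        raise ValueError(f"unknown residue {chain}:{resnum}")
    resname = system.atoms["residue_name"].to_numpy()[idx[0]]
    if resname in _CENTRE_NAMES:
        return coordinates[system.find_atom(chain, resnum,
                                            _CENTRE_NAMES[resname])]
    if resname in ("HIS", "PHE", "TYR"):
        names = system.atoms["name"].to_numpy()[idx]
        ring = idx[np.isin(names, ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])]
        if len(ring):
            return coordinates[ring].mean(axis=0)
    return coordinates[idx].mean(axis=0)


def salt_bridge_monitor(system: MolecularSystem, trajectory: Trajectory,
                        pairs: Sequence[tuple[int, int]] | None = None,
                        thresholds: GeometryThresholds | None = None
                        ) -> dict[tuple[int, int], float]:
    """Fraction of frames with charged-group centres within the cutoff.

    Pairs are same-chain residue-number pairs; the fraction is averaged over
    the receptor chains.
    """
    thresholds = thresholds or GeometryThresholds()
    pairs = list(pairs) if pairs is not None else list(SALT_BRIDGE_PRESETS)
    chains = sorted({c for c, _ in system.receptor_residues()})
    out = {}
    for (ra, rb) in pairs:
        hits = 0
        total = 0
        for frame in trajectory:
            for chain in chains:
                ca = _group_centre(system, chain, ra, frame.coordinates)
                cb = _group_centre(system, chain, rb, frame.coordinates)
                delta = ca - cb
                box = _as_box_diagonal(frame.box)
                if box is not None:
                    delta -= box * np.round(delta / box)
                total += 1
                if np.linalg.norm(delta) < thresholds.salt_bridge_cutoff:
                    hits += 1
        out[(ra, rb)] = hits / total if total else float("nan")
    return out
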