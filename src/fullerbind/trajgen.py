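"""Seeded toy binding trajectories.

The generator emulates the statistical structure of nanoparticle-binding
MD runs without integrating any equations of motion: the receptor gets
small-amplitude positional jitter around the built fibril, and the ligand
performs a biased random walk (rigid-body translation + rotation) toward a
chosen binding site.  Two kinetic regimes are produced -- fast runs reach
contact (d_min <= 0.30 nm) within the first few percent of frames, slow
runs take a large fraction of the run -- after which the ligand stays
docked at the target site with a species-dependent residence geometry:

* apolar cages sit with their carbon surface at the bound gap from the
  nearest receptor atom;
* hydroxylated cages dock one hydroxyl toward a chosen acceptor atom of
  the site, with orientational wobble, so that geometric hydrogen bonds
  form in most bound frames.

Everything is driven by one explicit seed; identical specs and seeds give
bitwise-identical trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import minimum_distance
from .system import MolecularSystem, Trajectory

#: Nominal contact time of a fast run (ps); kept well inside the 3 ns
#: fast/slow classification boundary regardless of run length.
_FAST_ARRIVAL_PS = 2000.0


@dataclass
class TrajectorySpec:
    """Parameters of one synthetic binding run.

    ``drift`` (nm/ps) may be None, in which case it is derived from the
    regime's nominal arrival fraction and the run length.  ``bound_gap`` is
    the docked carbon-surface-to-receptor d_min for apolar cages;
    ``bound_da`` is the docked donor-acceptor (hydroxyl O to anchor)
    distance for hydroxylated cages.
    """

    regime: str = "fast"                       # fast / slow
    target_site: Optional[tuple[int, int]] = None
    drift: Optional[float] = None              # nm/ps
    diffusion: float = 0.002                   # nm/sqrt(ps)
    n_frames: int = 500
    frame_interval: float = 100.0              # ps
    seed: int = 0
    jitter: float = 0.02                       # nm receptor jitter
    bound_gap: float = 0.295                   # nm
    bound_da: float = 0.32                     # nm
    gap_noise: float = 0.008                   # nm
    orientation_wobble: float = 8.0            # deg, docked wobble
    anchor_wander: int = 0                     # residues of anchor drift
    rotation_rate: float = 0.01                # rad/sqrt(ps), free tumbling
    slow_fraction: float = 0.35                # run fraction for slow onset

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.regime not in ("fast", "slow"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not (0.2 <= self.slow_fraction <= 0.6):
            raise ValueError("slow_fraction must lie in [0.2, 0.6]")


def _anchor_candidates(system: MolecularSystem,
                       site: tuple[int, int],
                       want_acceptor: bool) -> np.ndarray:
    """Receptor atoms of the target site eligible as docking anchors.

    Wide sites are narrowed to the central few residues so that the
    dominant-contact residue of the docked pose falls inside the site
    rather than on its edge.
    """
    a = system.atoms
    rec = a["role"].to_numpy() == "receptor"
    lo, hi = site
    if hi - lo > 4:
        mid = (lo + hi) // 2
        lo, hi = mid - 2, mid + 2
    in_site = ((a["residue_number"].to_numpy() >= lo)
               & (a["residue_number"].to_numpy() <= hi))
    chains = sorted(set(a["chain_id"][rec]))
    mid_chain = a["chain_id"].to_numpy() == chains[len(chains) // 2]
    el = a["element"].to_numpy()
    mask = rec & in_site & mid_chain
    if want_acceptor:
        mask &= (el == "O") | (el == "N")
    else:
        mask &= el != "H"
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"no anchor candidates in site {site}")
    return idx


def _small_rotation(rng: np.random.Generator, sigma_rad: float) -> Rotation:
    return Rotation.from_rotvec(sigma_rad * rng.standard_normal(3))


def generate_trajectory(system: MolecularSystem,
                        spec: TrajectorySpec) -> Trajectory:
    """Generate a seeded binding trajectory for a built complex.

    The system's reference coordinates define the starting pose; the ligand
    must start at least 2.0 nm (minimum distance) from the receptor.
    """
    rng = np.random.default_rng(spec.seed)
    rec_idx = system.receptor_indices
    lig_idx = system.ligand_indices
    if len(rec_idx) == 0 or len(lig_idx) == 0:
        raise ValueError("system must contain receptor and ligand atoms")

    rec_base = system.coordinates[rec_idx]
    lig_base = system.coordinates[lig_idx]
    d0 = minimum_distance(rec_base, lig_base)
    if d0 < 2.0 - 1e-9:
        raise ValueError(
            f"initial ligand placement too close (d_min={d0:.3f} nm); "
            "the ligand must start >= 2.0 nm from the receptor")

    site = spec.target_site or (
        1, int(system.atoms["residue_number"][rec_idx].max()))
    has_hydroxyl = bool(
        (system.atoms["element"].to_numpy()[lig_idx] == "O").any())
    anchors = _anchor_candidates(system, site, want_acceptor=has_hydroxyl)

    # approach direction: from the site anchor centroid toward the start
    lig_centre0 = lig_base.mean(axis=0)
    lig_local0 = lig_base - lig_centre0
    anchor_centroid = system.coordinates[anchors].mean(axis=0)
    u = lig_centre0 - anchor_centroid
    u /= np.linalg.norm(u)

    # pick the docking anchor: most exposed candidate along the approach
    exposure = (system.coordinates[anchors] - anchor_centroid) @ u
    anchor_order = anchors[np.argsort(-exposure)]
    anchor_atom = int(anchor_order[0])

    # the hydroxyl used for docking (hydroxylated cages only)
    oh_local = None
    if has_hydroxyl:
        names = system.atoms["name"].to_numpy()[lig_idx]
        oh_pos = np.flatnonzero(np.char.startswith(
            names.astype(str), "OH"))
        oh_local = int(oh_pos[0])

    dt = spec.frame_interval
    drift = spec.drift
    if drift is None:
        travel = max(d0 - spec.bound_gap, 0.0)
        run_ps = spec.n_frames * dt
        if spec.regime == "fast":
            arrive = min(0.04 * run_ps, _FAST_ARRIVAL_PS)
        else:
            arrive = spec.slow_fraction * run_ps
        drift = travel / arrive if arrive > 0 else 0.0

    extent = system.coordinates.max(axis=0) - system.coordinates.min(axis=0)
    box = extent + 5.0

    n_atoms = system.n_atoms
    coords = np.empty((spec.n_frames, n_atoms, 3))
    times = np.arange(spec.n_frames) * dt

    centre = lig_centre0.copy()
    orientation = Rotation.identity()
    bound = False
    anchor_current = anchor_atom
    wander_pos = 0

    for i in range(spec.n_frames):
        frame = np.empty((n_atoms, 3))
        rec_frame = rec_base
        if spec.jitter > 0:
            rec_frame = rec_base + spec.jitter * rng.standard_normal(
                rec_base.shape)
        frame[rec_idx] = rec_frame

        if not bound:
            moving = drift > 0 or spec.diffusion > 0
            if moving:
                target = frame[anchor_atom] + u * spec.bound_gap
                step_dir = target - centre
                norm = np.linalg.norm(step_dir)
                if norm > 1e-12:
                    step_dir /= norm
                centre = (centre + drift * dt * step_dir
                          + spec.diffusion * np.sqrt(dt)
                          * rng.standard_normal(3))
                if spec.diffusion > 0:
                    orientation = (_small_rotation(
                        rng, spec.rotation_rate * np.sqrt(dt)) * orientation)
            lig_frame = centre + lig_local0 @ orientation.as_matrix().T
            d = minimum_distance(rec_frame, lig_frame)
            if moving and d <= max(spec.bound_gap, 0.30):
                bound = True

        if bound:
            # slow anchor wander across the site (low-specificity binding)
            if spec.anchor_wander > 0 and rng.random() < 0.05:
                wander_pos = int(np.clip(
                    wander_pos + rng.integers(-1, 2),
                    0, min(spec.anchor_wander, len(anchor_order) - 1)))
                anchor_current = int(anchor_order[wander_pos])
            u_t = Rotation.from_rotvec(
                np.radians(3.0) * rng.standard_normal(3)).apply(u)
            anchor_pos = frame[anchor_current]
            if oh_local is not None:
                # dock the hydroxyl O-H axis onto the acceptor
                wobble = _small_rotation(
                    rng, np.radians(spec.orientation_wobble))
                axis_local = lig_local0[oh_local] / np.linalg.norm(
                    lig_local0[oh_local])
                align, _ = Rotation.align_vectors([-u_t], [axis_local])
                orientation = wobble * align
                da = spec.bound_da + spec.gap_noise * rng.standard_normal()
                lig_local = lig_local0 @ orientation.as_matrix().T
                centre = anchor_pos + u_t * da - lig_local[oh_local]
                lig_frame = centre + lig_local
                d = minimum_distance(rec_frame, lig_frame)
                if d < 0.18:  # steric guard against receptor overlap
                    centre = centre + u_t * (0.18 - d)
                    lig_frame = centre + lig_local
            else:
                orientation = (_small_rotation(
                    rng, np.radians(2.0)) * orientation)
                gap = spec.bound_gap + spec.gap_noise * rng.standard_normal()
                gap = float(np.clip(gap, 0.27, 0.40))
                lig_local = lig_local0 @ orientation.as_matrix().T
                proj = float((lig_local @ (-u_t)).max())
                centre = anchor_pos + u_t * (proj + gap)
                lig_frame = centre + lig_local
                for _ in range(3):
                    d = minimum_distance(rec_frame, lig_frame)
                    if abs(d - gap) < 5e-3:
                        break
                    centre = centre + u_t * (gap - d)
                    lig_frame = centre + lig_local

        frame[lig_idx] = lig_frame
        coords[i] = frame

    boxes = np.tile(box, (spec.n_frames, 1))
    return Trajectory(times=times, coordinates=coords, boxes=boxes)
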