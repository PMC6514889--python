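"""Shrake-Rupley solvent-accessible surface area.

Each atom is expanded by the probe radius and sampled with a deterministic
golden-spiral point set; points occluded by any neighbouring expanded
sphere are removed and the surviving fraction scaled to the sphere area.
Per-atom areas sum exactly to the total.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .config import SasaParameters
from .units import KCAL


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_sasa(coordinates: np.ndarray, radii: np.ndarray,
                       params: SasaParameters | None = None
                       ) -> tuple[float, np.ndarray]:
    """Total and per-atom solvent-accessible surface area, nm^2."""
    params = params or SasaParameters()
    coordinates = np.asarray(coordinates, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive for SASA")
    expanded = radii + params.probe_radius
    unit = sphere_points(params.n_sphere_points)
    tree = cKDTree(coordinates)
    per_atom = np.zeros(len(coordinates))
    r_max = expanded.max()
    for i in range(len(coordinates)):
        pts = coordinates[i] + expanded[i] * unit
        neighbours = tree.query_ball_point(coordinates[i],
                                           expanded[i] + r_max)
        neighbours = [j for j in neighbours if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            dc = np.linalg.norm(coordinates[i] - coordinates[j])
            if dc < 1e-12:
                # coincident atoms: count the surface once, on the atom
                # with the larger radius (lowest index on exact ties)
                if expanded[j] > expanded[i] or (
                        expanded[j] == expanded[i] and j < i):
                    accessible[:] = False
                continue
            d = np.linalg.norm(pts - coordinates[j], axis=1)
            accessible &= d >= expanded[j]
        frac = accessible.mean() if len(pts) else 0.0
        per_atom[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return float(per_atom.sum()), per_atom


def nonpolar_solvation(sasa_nm2: float,
                       params: SasaParameters | None = None) -> float:
    """Nonpolar solvation free energy gamma*SASA + b, kcal/mol."""
    params = params or SasaParameters()
    if sasa_nm2 < 0:
        raise ValueError("SASA must be non-negative")
    return params.gamma * sasa_nm2 + params.b_const


def nonpolar_solvation_kj(sasa_nm2: float,
                          params: SasaParameters | None = None) -> float:
    """Same surface term expressed in kJ/mol for internal bookkeeping."""
    return nonpolar_solvation(sasa_nm2, params) * KCAL
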