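"""Pairwise molecular-mechanics interaction energies (kJ/mol).

These are the gas-phase terms of the binding free energy: Lennard-Jones
4*eps[(sigma/r)^12 - (sigma/r)^6] under the Lorentz-Berthelot combination
rule and Coulomb f*q_i*q_j/(eps_in*r).  The systems are finite, so no
cutoff is applied by default; an optional cutoff exists for parity
experiments against cutoff-based MD setups.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .forcefield import lorentz_berthelot
from .geometry import pair_distances
from .system import MolecularSystem
from .units import COULOMB_CONSTANT

_MIN_DISTANCE = 1e-6


def _cross_distances(system: MolecularSystem, coordinates: np.ndarray,
                     group_a: np.ndarray, group_b: np.ndarray,
                     box) -> np.ndarray:
    d = pair_distances(coordinates[group_a], coordinates[group_b], box)
    if np.any(d < _MIN_DISTANCE):
        raise ValueError("overlapping atoms (zero interatomic distance)")
    return d


def lj_energy(system: MolecularSystem, coordinates: np.ndarray,
              group_a: np.ndarray, group_b: np.ndarray, box=None,
              cutoff: Optional[float] = None,
              pairwise: bool = False):
    """Cross-group Lennard-Jones energy, kJ/mol.

    With ``pairwise=True`` the (len_a, len_b) matrix of pair energies is
    returned instead of its sum (used by the residue decomposition).
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        return 0.0 if not pairwise else np.zeros((group_a.size,
                                                  group_b.size))
    eps_col = system.atoms["lj_epsilon"].to_numpy()
    sig_col = system.atoms["lj_sigma"].to_numpy()
    eps, sig = lorentz_berthelot(eps_col[group_a], sig_col[group_a],
                                 eps_col[group_b], sig_col[group_b])
    d = _cross_distances(system, coordinates, group_a, group_b, box)
    sr6 = (sig / d) ** 6
    e = 4.0 * eps * (sr6 ** 2 - sr6)
    if cutoff is not None:
        e = np.where(d <= cutoff, e, 0.0)
    return e if pairwise else float(e.sum())


def coulomb_energy(system: MolecularSystem, coordinates: np.ndarray,
                   group_a: np.ndarray, group_b: np.ndarray, box=None,
                   solute_dielectric: float = 1.0,
                   cutoff: Optional[float] = None,
                   pairwise: bool = False):
    """Cross-group Coulomb energy, kJ/mol, screened by the solute
    dielectric."""
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        return 0.0 if not pairwise else np.zeros((group_a.size,
                                                  group_b.size))
    q = system.atoms["charge"].to_numpy()
    d = _cross_distances(system, coordinates, group_a, group_b, box)
    e = (COULOMB_CONSTANT * np.outer(q[group_a], q[group_b])
         / (solute_dielectric * d))
    if cutoff is not None:
        e = np.where(d <= cutoff, e, 0.0)
    return e if pairwise else float(e.sum())
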