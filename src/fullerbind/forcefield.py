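"""Self-contained toy force field for the synthetic systems.

The parameter set is deliberately minimal: element-based Lennard-Jones types,
point charges on the polar backbone machinery (N-H / C=O), unit charges on
ionised side-chain centres, and a small C(+0.2)/O(-0.6)/H(+0.4) triad on
fullerenol hydroxyls so every generated system carries an integral total
charge.  Real force-field parameters can be supplied instead through the
topology reader; nothing downstream depends on this particular set.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AtomType:
    charge: float       # e
    lj_epsilon: float   # kJ/mol
    lj_sigma: float     # nm
    radius: float       # nm, used by both the PB dielectric map and SASA


@dataclass
class ToyForceField:
    """Maps every atom of a generated system to exactly one parameter type.

    ``combination_rule`` is Lorentz-Berthelot: arithmetic mean of sigmas,
    geometric mean of well depths.
    """

    combination_rule: str = "lorentz-berthelot"
    types: dict = field(default_factory=lambda: dict(_DEFAULT_TYPES))

    def assign(self, atoms: pd.DataFrame) -> pd.DataFrame:
        """Return a copy of the atom table with parameters filled in."""
        out = atoms.copy()
        charges, eps, sig, rad = [], [], [], []
        for name, element, resname, role in zip(
                out["name"], out["element"], out["residue_name"],
                out["role"]):
            t = self.lookup(name, element, resname, role)
            charges.append(t.charge)
            eps.append(t.lj_epsilon)
            sig.append(t.lj_sigma)
            rad.append(t.radius)
        out["charge"] = charges
        out["lj_epsilon"] = eps
        out["lj_sigma"] = sig
        out["radius"] = rad
        total = out["charge"].sum()
        if abs(total - round(total)) > 1e-9:
            raise ValueError(
                f"toy force field produced non-integral total charge {total}")
        return out

    def lookup(self, name: str, element: str, resname: str,
               role: str) -> AtomType:
        base = name.rstrip("0123456789")  # C17/OH33 etc. -> C/OH
        for key in ((role, resname, name), (role, resname, base),
                    (role, name), (role, base)):
            if key in self.types:
                return self.types[key]
        if element in self.types:
            return self.types[element]
        raise KeyError(f"no toy type for atom {name} ({element}) "
                       f"in {resname}/{role}")


# Element-level LJ/radius baseline (kJ/mol, nm).  Radii are Bondi-like
# van der Waals radii rounded to typical implicit-solvent values.
_ELEMENT_TYPES = {
    "C": AtomType(0.0, 0.36, 0.34, 0.170),
    "N": AtomType(0.0, 0.71, 0.325, 0.155),
    "O": AtomType(0.0, 0.65, 0.30, 0.152),
    # polar hydrogens carry no LJ well (GROMOS-style); they keep a small
    # PB/SASA radius so the dielectric cavity stays closed
    "H": AtomType(0.0, 0.0, 0.10, 0.110),
}

_DEFAULT_TYPES = {
    **_ELEMENT_TYPES,
    # backbone amide: +-0.4 e on N-H and C=O
    ("receptor", "N"): AtomType(-0.4, 0.71, 0.325, 0.155),
    ("receptor", "H"): AtomType(+0.4, 0.0, 0.10, 0.110),
    ("receptor", "C"): AtomType(+0.4, 0.36, 0.34, 0.170),
    ("receptor", "O"): AtomType(-0.4, 0.65, 0.30, 0.152),
    # ionised side-chain centres (one interaction centre per group)
    ("receptor", "ASP", "OD"): AtomType(-1.0, 0.65, 0.30, 0.152),
    ("receptor", "GLU", "OE"): AtomType(-1.0, 0.65, 0.30, 0.152),
    ("receptor", "LYS", "NZ"): AtomType(+1.0, 0.71, 0.325, 0.155),
    ("receptor", "ARG", "CZ"): AtomType(+1.0, 0.36, 0.34, 0.170),
    # charged termini caps (NH3+ nitrogen, COO- oxygen)
    ("receptor", "NT"): AtomType(+0.6, 0.71, 0.325, 0.155),
    ("receptor", "OT"): AtomType(-1.0, 0.65, 0.30, 0.152),
    # fullerene cage carbon: graphitic, apolar
    ("ligand", "C"): AtomType(0.0, 0.28, 0.35, 0.170),
    # fullerenol hydroxyl triad C(+0.2)-O(-0.6)-H(+0.4); the carbon charge
    # lives on the cage carbon bearing the hydroxyl
    ("ligand", "CH"): AtomType(+0.2, 0.28, 0.35, 0.170),
    ("ligand", "OH"): AtomType(-0.6, 0.65, 0.30, 0.152),
    ("ligand", "HO"): AtomType(+0.4, 0.0, 0.10, 0.110),
}


def lorentz_berthelot(eps_i: np.ndarray, sig_i: np.ndarray,
                      eps_j: np.ndarray, sig_j: np.ndarray):
    """Pairwise LJ parameters under the Lorentz-Berthelot rule.

    Accepts 1-D arrays and returns broadcastable (len_i, len_j) matrices.
    """
    eps = np.sqrt(np.outer(eps_i, eps_j))
    sig = 0.5 * (np.asarray(sig_i)[:, None] + np.asarray(sig_j)[None, :])
    return eps, sig
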