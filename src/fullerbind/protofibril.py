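"""Idealised cross-beta protofibril builder.

The receptor model is a stack of ``n_chains`` identical, fully extended
peptide strands.  Strands run along x with a Calpha-Calpha rise of 0.35 nm
and are translated along the fibril axis z by 0.48 nm (the canonical
inter-strand spacing of in-register parallel beta-sheets).  The backbone
zig-zags slightly in y so that all bond lengths take their ideal values
while keeping the stated rise, and carbonyl oxygens / amide hydrogens are
oriented along z so that every inter-chain N-H...O=C pair satisfies the
geometric hydrogen-bond criterion (D-A < 0.35 nm, D-H-A > 150 deg).

Side chains are reduced to one interaction centre per functional group:
a CB pseudo-atom for apolar/polar residues, a full six-atom aromatic ring
for F/Y/H (histidine is given a six-membered toy ring so that one ring
template serves all aromatic residues), a carboxylate centre for D/E, an
amine centre for K and a guanidinium centre for R.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: Calpha-Calpha rise along the strand, nm.
RISE = 0.35
#: Inter-chain spacing along the fibril axis, nm.
CHAIN_SPACING = 0.48

# Ideal backbone bond lengths, nm.
N_CA = 0.147
CA_C = 0.153
C_N = 0.133
C_O = 0.123
N_H = 0.100

# z offsets of backbone atoms relative to the chain's Calpha plane.
_Z_N = -0.03
_Z_C = +0.05

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Aromatic residues modelled with a full six-atom ring.
RING_RESIDUES = {"F", "Y", "H"}
#: Charged side-chain centre atom names.
CHARGED_CENTRES = {"D": "OD", "E": "OE", "K": "NZ", "R": "CZ"}

AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"
AB40_SEQUENCE = AB42_SEQUENCE[:40]

_RING_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
_RING_RADIUS = 0.14
_CENTRE_OFFSET = 0.25
_RING_OFFSET = 0.35
_CB_OFFSET = 0.153


def _solve_backbone_zigzag():
    """y amplitude and x advances reproducing ideal bond lengths.

    With N at y = s*alpha, CA at y = 0, C at y = -s*alpha (s alternating
    along the strand), the three x advances must sum to the rise:
    d1 = |N->CA|_x, d2 = |CA->C|_x, d3 = |C->N'|_x.
    """
    d3 = np.sqrt(C_N ** 2 - (_Z_N - _Z_C) ** 2)

    def gap(alpha):
        d1 = np.sqrt(N_CA ** 2 - alpha ** 2 - _Z_N ** 2)
        d2 = np.sqrt(CA_C ** 2 - alpha ** 2 - _Z_C ** 2)
        return d1 + d2 + d3 - RISE

    alpha = brentq(gap, 0.0, 0.12)
    d1 = np.sqrt(N_CA ** 2 - alpha ** 2 - _Z_N ** 2)
    d2 = np.sqrt(CA_C ** 2 - alpha ** 2 - _Z_C ** 2)
    return alpha, d1, d2, d3


@dataclass
class ProtofibrilModel:
    """Built receptor: atom records plus coordinates plus metadata."""

    n_chains: int
    sequence: str
    atom_records: list
    coordinates: np.ndarray
    fibril_axis: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def build_protofibril(sequence: str, n_chains: int = 3) -> ProtofibrilModel:
    """Build an in-register parallel protofibril of identical strands.

    Chains are labelled A, B, C, ...; residues are numbered 1..L per chain.
    The first residue's backbone nitrogen is an NH3+ cap (atom name NT) and
    the last residue carries an extra carboxylate oxygen (OT), matching a
    peptide at neutral pH.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - set(THREE_LETTER)
    if bad:
        raise ValueError(f"unknown residue letters: {sorted(bad)}")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")

    alpha, d1, d2, d3 = _solve_backbone_zigzag()
    length = len(sequence)

    # Build one template chain at z = 0, then translate copies along z.
    records, coords = [], []

    def add(name, element, resnum, resname, xyz):
        records.append(dict(name=name, element=element,
                            residue_number=resnum, resname3=resname))
        coords.append(xyz)

    # Backbone heavy atoms first (H positions depend on the O below, which
    # is a pure -z translate of the same chain's previous residue O).
    backbone = {}
    for i, letter in enumerate(sequence):
        s = 1.0 if i % 2 == 0 else -1.0
        x_ca = i * RISE
        ca = np.array([x_ca, 0.0, 0.0])
        n = np.array([x_ca - d1, s * alpha, _Z_N])
        c = np.array([x_ca + d2, -s * alpha, _Z_C])
        o = c + np.array([0.0, 0.0, C_O])
        backbone[i] = dict(N=n, CA=ca, C=c, O=o, s=s)

    for i, letter in enumerate(sequence):
        bb = backbone[i]
        resname = THREE_LETTER[letter]
        resnum = i + 1
        s = bb["s"]
        n_name = "NT" if i == 0 else "N"
        add(n_name, "N", resnum, resname, bb["N"])
        # amide hydrogen points at the carbonyl oxygen one chain below
        # (the in-register O of residue i-1 translated by -CHAIN_SPACING z)
        j = i - 1 if i >= 1 else i + 1
        o_below = backbone[j]["O"] + np.array(
            [RISE * (i - 1 - j), 0.0, -CHAIN_SPACING])
        direction = o_below - bb["N"]
        add("H", "H", resnum, resname,
            bb["N"] + N_H * direction / np.linalg.norm(direction))
        add("CA", "C", resnum, resname, bb["CA"])
        add("C", "C", resnum, resname, bb["C"])
        add("O", "O", resnum, resname, bb["O"])
        if i == length - 1:
            add("OT", "O", resnum, resname,
                bb["C"] + np.array([C_O, 0.0, 0.0]))
        # reduced side chain, alternating sides of the sheet (-s y)
        if letter in RING_RESIDUES:
            centre = bb["CA"] + np.array([0.0, -s * _RING_OFFSET, 0.0])
            for k, rname in enumerate(_RING_NAMES):
                theta = 2.0 * np.pi * k / 6.0
                pos = centre + _RING_RADIUS * np.array(
                    [np.cos(theta), 0.0, np.sin(theta)])
                add(rname, "C", resnum, resname, pos)
        elif letter in CHARGED_CENTRES:
            cname = CHARGED_CENTRES[letter]
            element = cname[0] if cname[0] in "NO" else "C"
            add(cname, element, resnum, resname,
                bb["CA"] + np.array([0.0, -s * _CENTRE_OFFSET, 0.0]))
        elif letter != "G":
            add("CB", "C", resnum, resname,
                bb["CA"] + np.array([0.0, -s * _CB_OFFSET, 0.0]))

    template = np.array(coords)
    all_records, all_coords = [], []
    for c in range(n_chains):
        chain_id = chr(ord("A") + c)
        shift = np.array([0.0, 0.0, c * CHAIN_SPACING])
        for rec, xyz in zip(records, template + shift):
            all_records.append(dict(
                name=rec["name"], element=rec["element"],
                residue_number=rec["residue_number"],
                residue_name=rec["resname3"], chain_id=chain_id,
                role="receptor"))
            all_coords.append(xyz)

    return ProtofibrilModel(
        n_chains=n_chains,
        sequence=sequence,
        atom_records=all_records,
        coordinates=np.array(all_coords),
        fibril_axis=np.array([0.0, 0.0, 1.0]),
    )
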