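"""Shared fixtures: built systems and small ad-hoc system factories."""
import numpy as np
import pandas as pd
import pytest

from fullerbind.assemble import build_complex
from fullerbind.system import ATOM_COLUMNS, MolecularSystem


def make_system(atoms, coords):
    """Build a MolecularSystem from a list of per-atom dicts.

    Each dict may specify any ATOM_COLUMNS key; sensible defaults fill the
    rest (carbon receptor atoms with generic LJ parameters).
    """
    rows = []
    for i, spec in enumerate(atoms):
        row = dict(index=i + 1, name="X", element="C", residue_number=1,
                   residue_name="UNK", chain_id="A", role="receptor",
                   charge=0.0, lj_epsilon=0.3, lj_sigma=0.33, radius=0.17)
        row.update(spec)
        rows.append(row)
    df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return MolecularSystem(atoms=df, coordinates=np.asarray(coords,
                                                            dtype=float))


@pytest.fixture(scope="session")
def c60_complex():
    """Abeta42 trimer with a C60 placed 2 nm from the 2-4 site."""
    return build_complex(n_hydroxyl=0, seed=1, target_site=(2, 4))


@pytest.fixture(scope="session")
def oh6_complex():
    """Abeta42 trimer with a C60(OH)6 aimed at the C-terminal site."""
    return build_complex(n_hydroxyl=6, seed=1, target_site=(31, 41))


@pytest.fixture
def random_two_group_system():
    """Factory: n+m random atoms split receptor/ligand, seeded."""

    def _build(n=50, m=30, seed=0, spread=1.5, charges=False):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, spread, size=(n + m, 3))
        atoms = []
        for i in range(n + m):
            role = "receptor" if i < n else "ligand"
            q = float(rng.uniform(-0.5, 0.5)) if charges else 0.0
            atoms.append(dict(role=role, charge=q,
                              element=rng.choice(["C", "N", "O"]),
                              lj_epsilon=float(rng.uniform(0.1, 0.8)),
                              lj_sigma=float(rng.uniform(0.25, 0.38)),
                              residue_number=1 + i // 5))
        return make_system(atoms, coords)

    return _build
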