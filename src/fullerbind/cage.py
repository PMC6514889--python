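"""Fullerene / fullerenol cage models.

C60 is built as a truncated icosahedron (60 vertices, 90 edges, 12 pentagons,
20 hexagons) scaled to a cage radius of 0.355 nm.  Hydroxyl groups are
attached to cage carbons chosen so that the minimum pairwise geodesic (graph)
separation between hydroxylated carbons is maximised -- the natural reading
of "uniformly distributed" on a discrete cage.  The optimum separation is
found exactly by a branch-and-bound search over vertex subsets; which of the
equivalent optimal placements is returned depends deterministically on the
seed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

#: Mean carbon radial distance from the cage centroid, nm.
CAGE_RADIUS = 0.355
#: C-O bond length of a hydroxyl, nm.
C_O_BOND = 0.14
#: O-H bond length of a hydroxyl, nm.
O_H_BOND = 0.10

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _truncated_icosahedron_vertices() -> np.ndarray:
    """The 60 vertices, edge length 2, centred at the origin.

    Canonical coordinates: all cyclic permutations of (0, +-1, +-3phi),
    (+-1, +-(2+phi), +-2phi) and (+-phi, +-2, +-(2phi+1)).
    """
    base = []
    for s2 in (+1, -1):
        for s3 in (+1, -1):
            base.append((0.0, s2 * 1.0, s3 * 3.0 * _PHI))
    for s1 in (+1, -1):
        for s2 in (+1, -1):
            for s3 in (+1, -1):
                base.append((s1 * 1.0, s2 * (2.0 + _PHI), s3 * 2.0 * _PHI))
                base.append((s1 * _PHI, s2 * 2.0, s3 * (2.0 * _PHI + 1.0)))
    verts = set()
    for (x, y, z) in base:
        for p in ((x, y, z), (y, z, x), (z, x, y)):
            verts.add(tuple(np.round(p, 9)))
    v = np.array(sorted(verts))
    assert v.shape == (60, 3)
    return v


@dataclass
class CageModel:
    """Geometry and bonding of a C60(OH)n cage."""

    carbon_positions: np.ndarray          # (60, 3) nm, centred at origin
    cage_radius: float                    # nm
    hydroxyl_sites: list                  # (carbon index, O xyz, H xyz)
    n_hydroxyl: int
    bonds: np.ndarray = field(default=None)          # (90, 2)
    geodesic: np.ndarray = field(default=None)       # (60, 60) hop counts

    @property
    def hydroxyl_carbons(self) -> list[int]:
        return [s[0] for s in self.hydroxyl_sites]

    def min_geodesic_separation(self) -> int:
        """Smallest pairwise graph distance between hydroxylated carbons."""
        carbons = self.hydroxyl_carbons
        if len(carbons) < 2:
            return int(self.geodesic.max())
        return int(min(self.geodesic[i, j]
                       for i, j in itertools.combinations(carbons, 2)))

    def to_atom_records(self, chain_id: str = "L") -> list[dict]:
        """Atom dictionaries (no force-field parameters yet).

        Cage carbons are named C1..C60 with element C; hydroxylated carbons
        are renamed CH<i> so the toy force field can charge them; hydroxyl
        oxygens/hydrogens are OH<i>/HO<i>.
        """
        oh_set = set(self.hydroxyl_carbons)
        records = []
        for i, pos in enumerate(self.carbon_positions):
            name = f"CH{i + 1}" if i in oh_set else f"C{i + 1}"
            records.append(dict(
                name=name, element="C", residue_number=1,
                residue_name="FUL", chain_id=chain_id, role="ligand"))
        for (ci, o_pos, h_pos) in self.hydroxyl_sites:
            records.append(dict(
                name=f"OH{ci + 1}", element="O", residue_number=1,
                residue_name="FUL", chain_id=chain_id, role="ligand"))
            records.append(dict(
                name=f"HO{ci + 1}", element="H", residue_number=1,
                residue_name="FUL", chain_id=chain_id, role="ligand"))
        return records

    def all_positions(self) -> np.ndarray:
        """Coordinates in atom-record order (carbons, then O/H pairs)."""
        coords = [self.carbon_positions]
        for (_, o_pos, h_pos) in self.hydroxyl_sites:
            coords.append(o_pos[None, :])
            coords.append(h_pos[None, :])
        return np.vstack(coords)


def _cage_graph(vertices: np.ndarray):
    """Bond list (edges at the unique nearest-neighbour distance)."""
    d = np.linalg.norm(vertices[:, None, :] - vertices[None, :, :], axis=-1)
    bond_length = np.min(d[d > 1e-9])
    ii, jj = np.where((d > 1e-9) & (d < bond_length * 1.05))
    bonds = np.array([(i, j) for i, j in zip(ii, jj) if i < j])
    return bonds


def _geodesic_matrix(bonds: np.ndarray, n: int = 60) -> np.ndarray:
    data = np.ones(len(bonds))
    adj = csr_matrix((data, (bonds[:, 0], bonds[:, 1])), shape=(n, n))
    adj = adj + adj.T
    return shortest_path(adj, method="BF", unweighted=True).astype(int)


def _subset_exists(geo: np.ndarray, n_pick: int, min_sep: int,
                   start: int, rng: np.random.Generator | None,
                   node_budget: int = 500_000):
    """Find n_pick vertices pairwise >= min_sep apart, containing `start`.

    Depth-first search with candidate-count pruning.  Returns the subset or
    None.  Because the cage graph is vertex-transitive, fixing the first
    vertex loses no generality for the existence question.
    """
    n = geo.shape[0]
    order = np.arange(n)
    if rng is not None:
        rng.shuffle(order)
    budget = [node_budget]

    def dfs(chosen, candidates):
        if len(chosen) == n_pick:
            return list(chosen)
        if len(chosen) + len(candidates) < n_pick:
            return None
        if budget[0] <= 0:
            return None
        budget[0] -= 1
        for k, v in enumerate(candidates):
            rest = [u for u in candidates[k + 1:] if geo[u, v] >= min_sep]
            hit = dfs(chosen + [v], rest)
            if hit is not None:
                return hit
        return None

    candidates = [int(v) for v in order
                  if v != start and geo[v, start] >= min_sep]
    return dfs([start], candidates)


def optimal_hydroxyl_sites(geo: np.ndarray, n_hydroxyl: int,
                           seed: int) -> list[int]:
    """Hydroxyl carbons maximising the minimum pairwise geodesic distance.

    The optimum separation is located by trying decreasing separations until
    a feasible subset exists; the subset returned for the optimal separation
    depends on the seed (all returned subsets attain the optimum).
    """
    if n_hydroxyl <= 1:
        rng = np.random.default_rng(seed)
        return [int(rng.integers(geo.shape[0]))][:n_hydroxyl]
    rng = np.random.default_rng(seed)
    start = int(rng.integers(geo.shape[0]))
    for sep in range(int(geo.max()), 0, -1):
        hit = _subset_exists(geo, n_hydroxyl, sep, start, rng)
        if hit is not None:
            return sorted(hit)
    raise RuntimeError("unreachable: separation 1 always feasible")


def build_cage(n_hydroxyl: int, seed: int = 0) -> CageModel:
    """Build a C60(OH)n cage model.

    Parameters
    ----------
    n_hydroxyl : number of hydroxyl groups, 0..60 (0, 6 and 12 are the
        standard study compositions).
    seed : selects among equivalent optimal hydroxyl placements; the full
        geometry is deterministic given the seed.
    """
    if not (0 <= n_hydroxyl <= 60):
        raise ValueError(f"n_hydroxyl must be in [0, 60], got {n_hydroxyl}")
    verts = _truncated_icosahedron_vertices()
    bonds = _cage_graph(verts)
    geo = _geodesic_matrix(bonds)
    radius = np.linalg.norm(verts, axis=1).mean()
    carbons = verts * (CAGE_RADIUS / radius)

    sites = []
    for ci in optimal_hydroxyl_sites(geo, n_hydroxyl, seed):
        u = carbons[ci] / np.linalg.norm(carbons[ci])
        o_pos = carbons[ci] + C_O_BOND * u
        h_pos = o_pos + O_H_BOND * u
        sites.append((int(ci), o_pos, h_pos))

    return CageModel(
        carbon_positions=carbons,
        cage_radius=CAGE_RADIUS,
        hydroxyl_sites=sites,
        n_hydroxyl=n_hydroxyl,
        bonds=bonds,
        geodesic=geo,
    )
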