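"""File formats: round trips, unit conversion, error reporting."""
import gzip

import numpy as np
import pytest

from fullerbind.errors import ParseError, TopologyError
from fullerbind.structio import (build_system, load_system, read_gro,
                                 read_pdb, read_structure, read_topology,
                                 read_trajectory, write_gro, write_pdb,
                                 write_topology, write_trajectory)
from fullerbind.system import Trajectory
from fullerbind.trajgen import TrajectorySpec, generate_trajectory


def test_pdb_round_trip_preserves_geometry(c60_complex, tmp_path):
    """Write -> read agrees to PDB precision (0.001 A = 1e-4 nm)."""
    path = tmp_path / "complex.pdb"
    write_pdb(c60_complex, path)
    table, coords = read_pdb(path)
    assert len(table) == c60_complex.n_atoms
    assert np.allclose(coords, c60_complex.coordinates, atol=1e-4)
    assert list(table["chain_id"][:1]) == ["A"]
    # HETATM FUL records take the ligand role
    lig = table[table["residue_name"] == "FUL"]
    assert (lig["role"] == "ligand").all()
    assert len(lig) == 60


def test_pdb_angstrom_to_nm_conversion(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(
        "ATOM      1  CA  ALA A   1       3.500   0.000   0.000"
        "  1.00  0.00           C\n")
    table, coords = read_pdb(path)
    assert coords[0, 0] == pytest.approx(0.35)


def test_gro_round_trip_and_chain_recovery(c60_complex, tmp_path):
    path = tmp_path / "complex.gro"
    write_gro(c60_complex, path)
    table, coords, box = read_gro(path)
    assert np.allclose(coords, c60_complex.coordinates, atol=1e-3)
    assert list(np.unique(table["chain_id"])) == ["A", "B", "C", "D"]
    assert (table["role"] == "ligand").sum() == 60
    assert np.all(box > 0)


def test_gro_readable_by_mdanalysis(c60_complex, tmp_path):
    """Cross-check our GRO dialect with an independent reader."""
    mda = pytest.importorskip("MDAnalysis")
    path = tmp_path / "complex.gro"
    write_gro(c60_complex, path)
    u = mda.Universe(str(path))
    assert len(u.atoms) == c60_complex.n_atoms
    assert np.allclose(u.atoms.positions / 10.0,  # A -> nm
                       c60_complex.coordinates, atol=1e-3)


def test_topology_round_trip_and_system_assembly(c60_complex, tmp_path):
    struct = tmp_path / "c.pdb"
    topo = tmp_path / "topology.tsv"
    write_pdb(c60_complex, struct)
    write_topology(c60_complex, topo)
    system = load_system(struct, topo)
    assert np.allclose(system.atoms["charge"],
                       c60_complex.atoms["charge"])
    assert np.allclose(system.atoms["lj_sigma"],
                       c60_complex.atoms["lj_sigma"])
    # donor/acceptor/ring tables rebuilt from file contents
    assert len(system.donors) == len(c60_complex.donors)
    assert len(system.rings) == len(c60_complex.rings)


def test_hydroxyl_oxygen_is_donor_and_acceptor(oh6_complex):
    donors = set(oh6_complex.donors[:, 0])
    acceptors = set(oh6_complex.acceptors)
    el = oh6_complex.atoms["element"].to_numpy()
    role = oh6_complex.atoms["role"].to_numpy()
    lig_o = np.flatnonzero((el == "O") & (role == "ligand"))
    assert len(lig_o) == 6
    for i in lig_o:
        assert i in donors and i in acceptors


def test_topology_row_mismatch_raises(c60_complex, tmp_path):
    struct = tmp_path / "c.pdb"
    topo = tmp_path / "topology.tsv"
    write_pdb(c60_complex, struct)
    write_topology(c60_complex, topo)
    table, coords = read_structure(struct)
    topo_df = read_topology(topo).iloc[:-5]
    with pytest.raises(TopologyError, match="missing"):
        build_system(table, coords, topo_df)


def test_nonintegral_charge_warns(c60_complex, tmp_path):
    topo = tmp_path / "topology.tsv"
    broken = c60_complex.atoms.copy()
    broken.loc[0, "charge"] += 0.3
    sys2 = c60_complex
    import fullerbind.structio as sio
    broken_sys = type(sys2)(atoms=broken, coordinates=sys2.coordinates)
    sio.write_topology(broken_sys, topo)
    with pytest.warns(UserWarning, match="not integral"):
        read_topology(topo)


def test_trajectory_round_trip_plain_and_gzip(c60_complex, tmp_path):
    spec = TrajectorySpec(regime="fast", target_site=(2, 4), n_frames=5,
                          seed=0)
    traj = generate_trajectory(c60_complex, spec)
    for name in ("run.traj", "run.traj.gz"):
        path = tmp_path / name
        write_trajectory(traj, path)
        back = read_trajectory(path, expected_atoms=c60_complex.n_atoms)
        assert back.n_frames == 5
        assert np.allclose(back.coordinates, traj.coordinates, atol=1e-6)
        assert np.array_equal(back.times, traj.times)


def test_single_frame_trajectory_is_valid(tmp_path):
    traj = Trajectory(times=np.array([0.0]),
                      coordinates=np.zeros((1, 4, 3)),
                      boxes=np.ones((1, 3)))
    path = tmp_path / "one.traj"
    write_trajectory(traj, path)
    back = read_trajectory(path)
    assert back.n_frames == 1 and back.n_atoms == 4


def test_truncated_trajectory_reports_frames_recovered(tmp_path):
    traj = Trajectory(times=np.array([0.0, 100.0]),
                      coordinates=np.zeros((2, 3, 3)),
                      boxes=np.ones((2, 3)))
    path = tmp_path / "trunc.traj"
    write_trajectory(traj, path)
    text = path.read_text().splitlines()
    path.write_text("\n".join(text[:-2]) + "\n")  # drop last 2 coord lines
    with pytest.raises(ParseError, match="1 complete frames"):
        read_trajectory(path)


def test_wrong_atom_count_rejected(tmp_path):
    traj = Trajectory(times=np.array([0.0]),
                      coordinates=np.zeros((1, 3, 3)))
    path = tmp_path / "t.traj"
    write_trajectory(traj, path)
    with pytest.raises(ParseError, match="does not match"):
        read_trajectory(path, expected_atoms=99)
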