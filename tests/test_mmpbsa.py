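"""MM/PBSA breakdown identities, decomposition sums, site energies."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_system
from fullerbind.config import (AnalysisConfig, PBParameters,
                               SasaParameters)
from fullerbind.mm import coulomb_energy
from fullerbind.mmpbsa import (EnergyBreakdown, aggregate_breakdowns,
                               frame_energy, mmpbsa_binding_energy,
                               residue_decomposition, site_energy)
from fullerbind.system import Trajectory


@pytest.fixture(scope="module")
def fast_config():
    """Coarse but honest settings to keep PB solves quick in unit tests."""
    return AnalysisConfig(
        pb=PBParameters(grid_spacing=0.1, margin=0.6, tolerance=1e-6),
        sasa=SasaParameters(n_sphere_points=240))


@pytest.fixture(scope="module")
def toy_complex():
    """Charged 8+4-atom receptor/ligand pair within interaction range."""
    rng = np.random.default_rng(2)
    atoms, coords = [], []
    for i in range(8):
        atoms.append(dict(role="receptor", element="O",
                          charge=(-1) ** i * 0.3,
                          residue_number=1 + i // 2, lj_epsilon=0.5,
                          lj_sigma=0.3, radius=0.15))
        coords.append(rng.uniform(0, 0.7, 3))
    for i in range(4):
        atoms.append(dict(role="ligand", element="C", charge=0.2 - 0.1 * i,
                          residue_number=1, lj_epsilon=0.3, lj_sigma=0.34,
                          radius=0.17, chain_id="L"))
        coords.append(np.array([1.1, 0.35, 0.35]) + rng.uniform(0, 0.25, 3))
    coords = np.array(coords)
    # slide the ligand to a 0.4 nm minimum gap so contacts exist
    from fullerbind.geometry import pair_distances

    gap = pair_distances(coords[:8], coords[8:]).min()
    coords[8:, 0] -= gap - 0.4
    return make_system(atoms, coords)


def test_breakdown_identities_hold_exactly():
    """dE_MM, dG_solv and dG_bind are exact sums on any breakdown."""
    b = EnergyBreakdown(dE_vdw=-24.44, dE_elec=0.0, dG_polar=0.0,
                        dG_nonpolar=-3.92)
    assert b.dE_MM == pytest.approx(-24.44, abs=1e-12)
    assert b.dG_solv == pytest.approx(-3.92, abs=1e-12)
    assert b.dG_bind == pytest.approx(-28.36, abs=1e-12)
    assert b.tds == 0.0 and b.tds_ignored


def test_aggregate_breakdowns_mean_and_sem():
    runs = [EnergyBreakdown(dE_vdw=v, dE_elec=0.0, dG_polar=1.0,
                            dG_nonpolar=-1.0) for v in (-10.0, -12.0)]
    agg = aggregate_breakdowns(runs)
    assert agg.dE_vdw == pytest.approx(-11.0)
    assert agg.dE_vdw_sem == pytest.approx(np.std([-10, -12], ddof=1)
                                           / np.sqrt(2))
    assert agg.dG_bind == pytest.approx(agg.dE_MM + agg.dG_solv)
    assert agg.n_runs == 2
    with pytest.raises(ValueError):
        aggregate_breakdowns([])


def test_frame_energy_identity_and_sign(toy_complex, fast_config):
    fe = frame_energy(toy_complex, toy_complex.coordinates, fast_config)
    assert fe.dG_bind == pytest.approx(
        fe.dE_vdw + fe.dE_elec + fe.dG_polar + fe.dG_nonpolar, abs=1e-12)


def test_separated_ligand_has_vanishing_interactions(toy_complex,
                                                     fast_config):
    """Moving the ligand 6 nm away kills every interaction component."""
    coords = toy_complex.coordinates.copy()
    coords[toy_complex.ligand_indices] += np.array([6.0, 0.0, 0.0])
    fe = frame_energy(toy_complex, coords, fast_config)
    assert abs(fe.dE_vdw) < 1e-3
    assert abs(fe.dE_elec) < 0.05
    assert abs(fe.dG_nonpolar + fast_config.sasa.b_const) < 1e-6
    assert abs(fe.dG_polar) < 0.6  # residual grid noise only


def test_repulsive_charges_give_positive_electrostatics(fast_config):
    """Like charges on both sides: dE_elec > 0, matching the brute-force
    sign."""
    atoms = [dict(role="receptor", element="O", charge=0.5, radius=0.15),
             dict(role="ligand", element="O", charge=0.5, radius=0.15,
                  chain_id="L")]
    system = make_system(atoms, [[0, 0, 0], [0.5, 0, 0]])
    fe = frame_energy(system, system.coordinates, fast_config)
    brute = coulomb_energy(system, system.coordinates, [0], [1],
                           solute_dielectric=fast_config.pb
                           .solute_dielectric)
    assert fe.dE_elec > 0
    assert np.sign(fe.dE_elec) == np.sign(brute)


def test_residue_mm_decomposition_sums_exactly(toy_complex, fast_config):
    fe = frame_energy(toy_complex, toy_complex.coordinates, fast_config,
                      per_residue=True)
    df = fe.per_residue
    assert df["dE_vdw"].sum() == pytest.approx(fe.dE_vdw, abs=1e-10)
    assert df["dE_elec"].sum() == pytest.approx(fe.dE_elec, abs=1e-10)


def test_distant_residue_contributes_nothing(toy_complex, fast_config):
    coords = toy_complex.coordinates.copy()
    # push residue 1 (atoms 0-1) far from the ligand
    coords[[0, 1]] -= np.array([5.0, 0.0, 0.0])
    fe = frame_energy(toy_complex, coords, fast_config, per_residue=True)
    row = fe.per_residue.set_index("residue_number").loc[1]
    assert abs(row["dE_vdw"]) < 1e-6
    assert abs(row["dE_elec"]) < 0.02


def test_window_selection_and_empty_window(toy_complex, fast_config):
    coords = np.repeat(toy_complex.coordinates[None], 4, axis=0)
    traj = Trajectory(times=np.array([0.0, 100.0, 200.0, 300.0]),
                      coordinates=coords)
    bd, frames = mmpbsa_binding_energy(toy_complex, traj,
                                       window_ps=150.0, config=fast_config)
    assert len(frames) == 2
    assert bd.dG_bind == pytest.approx(bd.dE_MM + bd.dG_solv)
    with pytest.raises(ValueError, match="empty"):
        mmpbsa_binding_energy(toy_complex, traj, window_ps=-1.0,
                              config=fast_config)


def test_site_energy_completeness_and_no_data(toy_complex, fast_config):
    """A site covering all residues reproduces the whole-trajectory mean
    dG_bind; an unvisited site reports no data, not zero."""
    coords = np.repeat(toy_complex.coordinates[None], 2, axis=0)
    traj = Trajectory(times=np.array([0.0, 100.0]), coordinates=coords)
    bd, _ = mmpbsa_binding_energy(toy_complex, traj, window_ps=1e9,
                                  config=fast_config)
    sites = site_energy(toy_complex, traj, {"all": (1, 4)},
                        window_ps=1e9, config=fast_config)
    assert sites[0].dG_bind == pytest.approx(bd.dG_bind, abs=1e-9)
    assert sites[0].n_frames == 2
    far = site_energy(toy_complex, traj, {"none": (3, 3)},
                      window_ps=1e9, config=fast_config)
    # ligand contacts residue-4 atoms only; residue 3 never dominates
    if far[0].n_frames == 0:
        assert np.isnan(far[0].dG_bind)
    with pytest.raises(ValueError, match="empty range"):
        site_energy(toy_complex, traj, {"bad": (4, 2)}, config=fast_config)


def test_residue_profile_recovers_pinned_contact_site(fast_config):
    """A ligand pinned at the F4 face makes F4 one of the lowest-energy
    residues of the chain-averaged profile."""
    from fullerbind.assemble import build_complex
    from fullerbind.trajgen import TrajectorySpec, generate_trajectory

    system = build_complex(n_hydroxyl=0, seed=1, target_site=(4, 4))
    traj = generate_trajectory(
        system, TrajectorySpec(regime="fast", target_site=(4, 4),
                               n_frames=60, seed=2))
    profile = residue_decomposition(system, traj, window_ps=1500.0,
                                    stride=5, config=fast_config)
    assert 4 in profile.lowest(3)
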