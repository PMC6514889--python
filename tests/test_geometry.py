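"""Geometric detectors vs independent exhaustive oracles and invariants."""
import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_system
from fullerbind.config import GeometryThresholds
from fullerbind.geometry import (BindingTime, binding_time, calpha_rmsd,
                                 classify_ring_orientation, contact_counts,
                                 contact_series, detect_hbonds,
                                 detect_pi_stacking, dominant_residue,
                                 kabsch_rmsd, minimum_distance,
                                 salt_bridge_monitor, site_occupancy)
from fullerbind.system import Trajectory


def brute_min_distance(a, b, box=None):
    best = np.inf
    for p in a:
        for q in b:
            d = np.asarray(p) - np.asarray(q)
            if box is not None:
                d = d - np.asarray(box) * np.round(d / np.asarray(box))
            best = min(best, float(np.linalg.norm(d)))
    return best


# ---------------------------------------------------------------------------
# minimum distance
# ---------------------------------------------------------------------------

def test_minimum_distance_simple_and_periodic():
    assert minimum_distance([[0, 0, 0]], [[0, 0, 0.3]]) == pytest.approx(0.3)
    # atoms 0.1 and 2.9 along z in a 3.0 nm box: nearest image 0.2 nm
    assert minimum_distance([[0, 0, 0.1]], [[0, 0, 2.9]],
                            box=[3.0, 3.0, 3.0]) == pytest.approx(0.2)


def test_minimum_distance_matches_bruteforce():
    rng = np.random.default_rng(4)
    a = rng.uniform(0, 2.5, (50, 3))
    b = rng.uniform(0, 2.5, (50, 3))
    assert minimum_distance(a, b) == pytest.approx(brute_min_distance(a, b))
    box = [2.5, 2.5, 2.5]
    assert minimum_distance(a, b, box) == pytest.approx(
        brute_min_distance(a, b, box))


def test_minimum_distance_rejects_empty_groups():
    with pytest.raises(ValueError):
        minimum_distance(np.empty((0, 3)), [[0, 0, 0]])


def test_triclinic_box_rejected():
    box = np.array([[3, 0.5, 0], [0, 3, 0], [0, 0, 3]])
    with pytest.raises(ValueError, match="triclinic"):
        minimum_distance([[0, 0, 0]], [[1, 1, 1]], box=box)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def test_contact_definition_excludes_hydrogen():
    system = make_system(
        [dict(role="receptor", element="C"),
         dict(role="receptor", element="C", residue_number=2),
         dict(role="ligand", element="C"),
         dict(role="ligand", element="H")],
        [[0, 0, 0], [0, 0, 5.0], [0.53, 0, 0], [0.3, 0, 5.0]])
    counts = contact_counts(system, system.coordinates)
    # one C-C pair at 0.53 nm counts; the C-H pair at 0.3 nm does not
    assert counts.tolist() == [1, 0]


def test_contacts_zero_at_initial_separation(c60_complex):
    counts = contact_counts(c60_complex, c60_complex.coordinates)
    assert counts.sum() == 0


def test_contacts_match_bruteforce(random_two_group_system):
    system = random_two_group_system(n=14, m=6, seed=8, spread=1.0)
    counts = contact_counts(system, system.coordinates)
    el = system.atoms["element"].to_numpy()
    role = system.atoms["role"].to_numpy()
    resnum = system.atoms["residue_number"].to_numpy()
    expected = {}
    for i in range(system.n_atoms):
        for j in range(system.n_atoms):
            if role[i] != "receptor" or role[j] != "ligand":
                continue
            if el[i] == "H" or el[j] == "H":
                continue
            d = np.linalg.norm(system.coordinates[i]
                               - system.coordinates[j])
            if d < 0.54:
                key = resnum[i]
                expected[key] = expected.get(key, 0) + 1
    residues = system.receptor_residues()
    for k, (chain, rn) in enumerate(residues):
        assert counts[k] == expected.get(rn, 0)


def test_contact_cutoff_monotonicity(random_two_group_system):
    system = random_two_group_system(n=30, m=20, seed=3, spread=1.2)
    totals = []
    for cutoff in (0.3, 0.45, 0.54, 0.7):
        th = GeometryThresholds(contact_cutoff=cutoff)
        totals.append(contact_counts(system, system.coordinates,
                                     thresholds=th).sum())
    assert totals == sorted(totals)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _hbond_system(da=0.28, angle_deg=180.0):
    """Donor O-H ... acceptor O with an exact D-H-A angle at the hydrogen.

    Triangle construction: with |DH| = 0.10, |DA| = da and the angle theta
    at H, the law of sines gives the angle at A and hence the direction of
    H as seen from D.
    """
    d = np.array([0.0, 0.0, 0.0])
    a = np.array([da, 0.0, 0.0])
    theta = np.radians(angle_deg)
    ang_a = np.arcsin(np.clip(0.10 * np.sin(theta) / da, -1, 1))
    ang_d = np.pi - theta - ang_a
    h = d + 0.10 * np.array([np.cos(ang_d), np.sin(ang_d), 0.0])
    return make_system(
        [dict(role="receptor", element="O", name="OG"),
         dict(role="receptor", element="H", name="HG"),
         dict(role="ligand", element="O", name="OH1")],
        [d, h, a])


def test_hbond_linear_geometry_detected():
    system = _hbond_system(da=0.28, angle_deg=180.0)
    events = detect_hbonds(system, system.coordinates)
    assert len(events) == 1
    ev = events[0]
    assert ev.distance == pytest.approx(0.28)
    assert ev.angle == pytest.approx(180.0)


@pytest.mark.parametrize("da,angle,expect", [
    (0.34, 149.0, 0),   # angle fails
    (0.36, 180.0, 0),   # distance fails
    (0.34, 151.0, 1),   # both pass
    (0.35, 180.0, 0),   # boundary is strict
])
def test_hbond_boundary_criteria(da, angle, expect):
    system = _hbond_system(da=da, angle_deg=angle)
    assert len(detect_hbonds(system, system.coordinates)) == expect


def test_hbond_angle_measured_at_hydrogen():
    system = _hbond_system(da=0.30, angle_deg=160.0)
    events = detect_hbonds(system, system.coordinates)
    assert len(events) == 1
    assert events[0].angle == pytest.approx(160.0, abs=1e-6)


def test_hbonds_only_for_hydroxylated_cage(c60_complex, oh6_complex):
    """An apolar C60 offers no donors/acceptors: zero intermolecular
    H-bonds no matter the pose; the fullerenol can form them."""
    role = c60_complex.atoms["role"].to_numpy()
    el = c60_complex.atoms["element"].to_numpy()
    assert not np.any((role == "ligand") & ((el == "O") | (el == "N")))
    events = detect_hbonds(c60_complex, c60_complex.coordinates)
    assert events == []
    role6 = oh6_complex.atoms["role"].to_numpy()
    el6 = oh6_complex.atoms["element"].to_numpy()
    assert np.any((role6 == "ligand") & (el6 == "O"))


def test_hbonds_subset_of_heavy_atom_contacts(oh6_complex):
    """Any D-A pair of an H-bond is also an atomic contact (0.35 < 0.54)."""
    from fullerbind.trajgen import TrajectorySpec, generate_trajectory

    traj = generate_trajectory(
        oh6_complex, TrajectorySpec(regime="fast", target_site=(31, 41),
                                    n_frames=40, seed=7))
    th = GeometryThresholds()
    for i in (30, 39):
        coords = traj.coordinates[i]
        events = detect_hbonds(oh6_complex, coords, traj.boxes[i], th)
        for ev in events:
            d = np.linalg.norm(coords[ev.donor] - coords[ev.acceptor])
            assert d < th.contact_cutoff


# ---------------------------------------------------------------------------
# pi-stacking
# ---------------------------------------------------------------------------

def _ring_and_cage(surface_distance, tilt_deg=0.0):
    from fullerbind.cage import build_cage

    cage = build_cage(0, seed=0)
    records = []
    coords = []
    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    centre = np.array([0.0, 0.0, cage.cage_radius + surface_distance])
    rot = Rotation.from_euler("x", tilt_deg, degrees=True)
    for k, name in enumerate(ring_names):
        t = 2 * np.pi * k / 6
        local = 0.14 * np.array([np.cos(t), np.sin(t), 0.0])
        records.append(dict(role="receptor", element="C", name=name,
                            residue_name="PHE", residue_number=4))
        coords.append(centre + rot.apply(local))
    for rec, xyz in zip(cage.to_atom_records(), cage.all_positions()):
        records.append(dict(role="ligand", element=rec["element"],
                            name=rec["name"], residue_name="FUL",
                            residue_number=1, chain_id="L"))
        coords.append(xyz)
    return make_system(records, coords)


@pytest.mark.parametrize("dist,expect", [(0.44, 1), (0.46, 0)])
def test_pistack_distance_boundary(dist, expect):
    system = _ring_and_cage(dist)
    events = detect_pi_stacking(system, system.coordinates)
    assert len(events) == expect
    if expect:
        assert events[0].surface_distance == pytest.approx(dist, abs=1e-6)


@pytest.mark.parametrize("tilt,expected_class", [
    (0.0, "parallel"), (50.0, "herringbone"), (90.0, "t_shaped")])
def test_pistack_tilt_and_orientation(tilt, expected_class):
    system = _ring_and_cage(0.40, tilt_deg=tilt)
    events = detect_pi_stacking(system, system.coordinates)
    assert len(events) == 1
    assert events[0].angle == pytest.approx(tilt, abs=1e-6)
    assert events[0].orientation == expected_class


def test_classify_ring_orientation_bins():
    assert classify_ring_orientation(0.0) == "parallel"
    assert classify_ring_orientation(29.9) == "parallel"
    assert classify_ring_orientation(50.0) == "herringbone"
    assert classify_ring_orientation(75.0) == "t_shaped"
    with pytest.raises(ValueError):
        classify_ring_orientation(120.0)


def test_three_simultaneous_f4_stacks(c60_complex):
    """A cage docked at the F4 face can stack with all three chains'
    aromatic rings at once (the reported maximum)."""
    from fullerbind.trajgen import TrajectorySpec, generate_trajectory

    traj = generate_trajectory(
        c60_complex, TrajectorySpec(regime="fast", target_site=(2, 4),
                                    n_frames=60, seed=3))
    best = 0
    for i in range(40, 60):
        events = detect_pi_stacking(c60_complex, traj.coordinates[i])
        f4 = [e for e in events if e.residue_number == 4]
        best = max(best, len(f4))
    assert best == 3


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def test_rmsd_zero_for_identity_and_rigid_motion():
    rng = np.random.default_rng(0)
    ref = rng.normal(size=(25, 3))
    assert kabsch_rmsd(ref, ref) == pytest.approx(0.0, abs=1e-12)
    rot = Rotation.from_euler("zyx", [40, -25, 110], degrees=True)
    moved = rot.apply(ref) + np.array([1.0, -2.0, 0.5])
    assert kabsch_rmsd(moved, ref) == pytest.approx(0.0, abs=1e-10)


def test_rmsd_four_point_closed_form():
    """Pure uniform displacement along +x of aligned points cannot be
    removed by superposition only when it deforms the shape; here the
    optimal alignment leaves a computable residual."""
    ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    moved = ref.copy()
    moved[0] += [0.2, 0, 0]
    # independent oracle: scipy's quaternion-based alignment
    p = moved - moved.mean(axis=0)
    q = ref - ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(q, p)
    expected = rssd / np.sqrt(len(ref))
    assert kabsch_rmsd(moved, ref) == pytest.approx(expected, abs=1e-9)


def test_rmsd_shape_validation():
    with pytest.raises(ValueError):
        kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


# ---------------------------------------------------------------------------
# binding kinetics, occupancy, salt bridges
# ---------------------------------------------------------------------------

def test_binding_time_fast_slow_unbound():
    times = np.arange(0, 50000.0, 100.0)
    d = np.full_like(times, 1.0)
    d[20:] = 0.29  # reaches 0.30 at 2 ns and stays
    bt = binding_time(times, d)
    assert bt.time_ps == pytest.approx(2000.0) and bt.regime == "fast"
    d2 = np.full_like(times, 1.0)
    d2[200:] = 0.29  # binds at 20 ns
    assert binding_time(times, d2).regime == "slow"
    d3 = np.linspace(2.0, 0.5, len(times))
    assert binding_time(times, d3) == BindingTime(None, "unbound")


def test_binding_time_ignores_grazing_contact():
    """A single dip below 0.30 nm that does not persist is not binding."""
    times = np.arange(0, 20000.0, 100.0)
    d = np.full_like(times, 1.0)
    d[50] = 0.28          # grazing touch
    d[120:] = 0.29        # real binding
    bt = binding_time(times, d)
    assert bt.time_ps == pytest.approx(12000.0)


def test_site_occupancy_bookkeeping():
    counts = np.zeros((42, 10), dtype=int)
    counts[33, :] = 5     # residue 34 dominates every frame
    from fullerbind.geometry import ContactSeries

    contact = ContactSeries(counts=counts, chain_ids=["A"] * 42,
                            residue_numbers=np.arange(1, 43),
                            times=np.arange(10.0))
    occ = site_occupancy(contact, {"31-41": (31, 41), "2-4": (2, 4)},
                        np.ones(10, bool))
    assert occ["31-41"] == 1.0 and occ["2-4"] == 0.0 and occ["other"] == 0.0
    # no bound frames: probabilities undefined
    occ2 = site_occupancy(contact, {"31-41": (31, 41)}, np.zeros(10, bool))
    assert np.isnan(occ2["31-41"]) and np.isnan(occ2["other"])
    with pytest.raises(ValueError, match="disjoint"):
        site_occupancy(contact, {"a": (1, 10), "b": (5, 20)},
                       np.ones(10, bool))


def test_dominant_residue_tie_breaks_low():
    counts = np.zeros((5, 1), dtype=int)
    counts[1] = counts[3] = 7
    dom = dominant_residue(counts, np.arange(1, 6))
    assert dom[0] == 2  # residues 2 and 4 tie; lowest wins


def test_salt_bridge_fractions(c60_complex):
    """Static fibril: D23(-)-K28(+) centres sit within the cutoff on the
    same side of the sheet; fraction from the monitor equals a per-frame
    brute-force count."""
    coords = np.repeat(c60_complex.coordinates[None], 3, axis=0)
    traj = Trajectory(times=np.arange(3.0), coordinates=coords)
    frac = salt_bridge_monitor(c60_complex, traj, pairs=[(23, 28), (6, 11)])
    for pair, value in frac.items():
        assert 0.0 <= value <= 1.0
    # brute force for (23, 28)
    from fullerbind.geometry import _group_centre
    hits = total = 0
    for chain in ("A", "B", "C"):
        ca = _group_centre(c60_complex, chain, 23,
                           c60_complex.coordinates)
        cb = _group_centre(c60_complex, chain, 28,
                           c60_complex.coordinates)
        total += 1
        hits += int(np.linalg.norm(ca - cb) < 0.46)
    assert frac[(23, 28)] == pytest.approx(hits / total)
    with pytest.raises(ValueError, match="unknown residue"):
        salt_bridge_monitor(c60_complex, traj, pairs=[(99, 3)])


# ---------------------------------------------------------------------------
# global invariances
# ---------------------------------------------------------------------------

def test_detectors_invariant_under_rigid_motion(oh6_complex):
    """Rotating + translating the whole system changes no detector
    output (counts, distances to 1e-9, classes)."""
    from fullerbind.trajgen import TrajectorySpec, generate_trajectory

    traj = generate_trajectory(
        oh6_complex, TrajectorySpec(regime="fast", target_site=(31, 41),
                                    n_frames=30, seed=1))
    coords = traj.coordinates[25]
    rot = Rotation.from_euler("xyz", [17, -66, 140], degrees=True)
    moved = rot.apply(coords) + np.array([3.0, -1.0, 2.0])

    assert minimum_distance(
        coords[oh6_complex.receptor_indices],
        coords[oh6_complex.ligand_indices]) == pytest.approx(
        minimum_distance(moved[oh6_complex.receptor_indices],
                         moved[oh6_complex.ligand_indices]), abs=1e-9)
    assert np.array_equal(contact_counts(oh6_complex, coords),
                          contact_counts(oh6_complex, moved))
    ev_a = detect_hbonds(oh6_complex, coords)
    ev_b = detect_hbonds(oh6_complex, moved)
    assert [(e.donor, e.acceptor) for e in ev_a] == \
        [(e.donor, e.acceptor) for e in ev_b]
    pi_a = detect_pi_stacking(oh6_complex, coords)
    pi_b = detect_pi_stacking(oh6_complex, moved)
    assert [(e.residue_number, e.orientation) for e in pi_a] == \
        [(e.residue_number, e.orientation) for e in pi_b]


def test_detectors_invariant_under_periodic_shift(oh6_complex):
    """Shifting a group by a whole box vector leaves periodic detectors
    unchanged."""
    from fullerbind.trajgen import TrajectorySpec, generate_trajectory

    traj = generate_trajectory(
        oh6_complex, TrajectorySpec(regime="fast", target_site=(31, 41),
                                    n_frames=30, seed=1))
    coords = traj.coordinates[29].copy()
    box = traj.boxes[29]
    shifted = coords.copy()
    shifted[oh6_complex.ligand_indices] += box  # one full image
    assert minimum_distance(
        coords[oh6_complex.receptor_indices],
        coords[oh6_complex.ligand_indices], box) == pytest.approx(
        minimum_distance(shifted[oh6_complex.receptor_indices],
                         shifted[oh6_complex.ligand_indices], box),
        abs=1e-9)
    assert np.array_equal(
        contact_counts(oh6_complex, coords, box),
        contact_counts(oh6_complex, shifted, box))
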