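"""Desk-scale study orchestration.

``run_study`` mirrors the design of a multi-run nanoparticle-binding
simulation campaign: for each nanoparticle composition it builds the
receptor-ligand system, generates six seeded toy trajectories split
between fast and slow kinetic regimes, runs every geometric analysis on
all frames and the MM/PBSA energetics on strided frames of the trailing
analysis window, and aggregates components as mean +- SEM across runs.

One toy frame stands for 100 ps, so a 500-frame run plays the role of a
50 ns trajectory and the default analysis window ("last 20 ns") is the
trailing 200 frames.  The per-run seed is ``master_seed + run_index``.
"""
from __future__ import annotations

import hashlib
import json
import sys
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .assemble import build_complex
from .config import AnalysisConfig, PBParameters, SasaParameters
from .geometry import (binding_time, bound_frame_mask, calpha_rmsd,
                       contact_series, detect_hbonds, detect_pi_stacking,
                       dominant_residue, minimum_distance_series,
                       site_occupancy)
from .mmpbsa import (BindingSite, EnergyBreakdown, aggregate_breakdowns,
                     frame_energy, select_window_frames)
from .protofibril import AB42_SEQUENCE
from .system import MolecularSystem, Trajectory
from .trajgen import TrajectorySpec, generate_trajectory

#: Run-index -> regime pattern: three fast and three slow runs per system.
DEFAULT_REGIMES = ("fast", "fast", "slow", "fast", "slow", "slow")


@dataclass
class NanoparticleSpec:
    """One nanoparticle composition and its study conditions.

    ``target_site`` is the injected binding site (the generator docks the
    ligand there); ``sites`` are the ranges evaluated in the site-energy
    table; ``bound_da``/``anchor_wander`` tune the docked-residence
    geometry with hydroxylation (larger donor-acceptor distance and more
    positional wandering for the more hydrophilic cages).
    """

    label: str
    n_hydroxyl: int
    target_site: tuple[int, int]
    sites: dict
    face_residue: Optional[int] = None
    bound_da: float = 0.32
    anchor_wander: int = 0
    n_frames: int = 500
    slow_fraction: float = 0.26   # slow-run onset as a fraction of the run


def default_nanoparticles() -> list[NanoparticleSpec]:
    """The three study compositions with their preferred binding sites."""
    return [
        NanoparticleSpec(
            label="C60", n_hydroxyl=0, target_site=(2, 4),
            sites={"2-4": (2, 4), "23-25": (23, 25), "31-41": (31, 41)}),
        NanoparticleSpec(
            label="C60(OH)6", n_hydroxyl=6, target_site=(31, 41),
            sites={"2-4": (2, 4), "9-11": (9, 11), "17-19": (17, 19),
                   "31-41": (31, 41)},
            bound_da=0.32, slow_fraction=0.40),
        NanoparticleSpec(
            label="C60(OH)12", n_hydroxyl=12, target_site=(4, 14),
            sites={"4-14": (4, 14), "22-23": (22, 23), "34-35": (34, 35)},
            face_residue=11, bound_da=0.33, anchor_wander=4,
            n_frames=1000, slow_fraction=0.42),
    ]


@dataclass
class StudyConfig:
    """Full study specification; defaults reproduce the standard design."""

    sequence: str = AB42_SEQUENCE
    n_chains: int = 3
    runs_per_system: int = 6
    frame_interval: float = 100.0        # ps per toy frame
    window_ps: float = 20000.0           # trailing analysis window
    energy_stride: int = 50              # frames between energy evaluations
    master_seed: int = 2019
    nanoparticles: list = field(default_factory=default_nanoparticles)
    analysis: AnalysisConfig = field(default_factory=lambda: AnalysisConfig(
        pb=PBParameters(grid_spacing=0.15, margin=0.8, tolerance=1.0e-5),
        sasa=SasaParameters(n_sphere_points=384)))

    def config_hash(self) -> str:
        payload = json.dumps(
            {"sequence": self.sequence, "n_chains": self.n_chains,
             "runs": self.runs_per_system, "dt": self.frame_interval,
             "window": self.window_ps, "stride": self.energy_stride,
             "seed": self.master_seed,
             "nanoparticles": [vars(n) for n in self.nanoparticles],
             "analysis": self.analysis.to_dict()},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    """All analyses of one trajectory."""

    run_index: int
    seed: int
    expected_regime: str
    binding_time_ps: Optional[float]
    regime: str
    breakdown: Optional[EnergyBreakdown]
    residue_profile: Optional[pd.DataFrame]
    site_frames: Optional[pd.DataFrame]   # per energy frame: dG + dominant
    hbond_main: float                     # mean events/frame in window
    hbond_side: float
    pistack_mean: float                   # mean events/frame in window
    pistack_max: int
    orientation_counts: dict
    occupancy: dict
    calpha_rmsd_nm: float
    error: Optional[str] = None


@dataclass
class SystemResult:
    spec: NanoparticleSpec
    runs: list
    breakdown: Optional[EnergyBreakdown]
    residue_profile: Optional[pd.DataFrame]
    sites: list
    occupancy: dict


@dataclass
class StudyReport:
    config: StudyConfig
    systems: list
    provenance: dict


def _analyse_run(system: MolecularSystem, traj: Trajectory,
                 spec: NanoparticleSpec, cfg: StudyConfig,
                 run_index: int, seed: int, expected: str) -> RunResult:
    th = cfg.analysis.thresholds
    dmin = minimum_distance_series(system, traj)
    onset = binding_time(traj.times, dmin, th)
    win_idx = select_window_frames(traj, cfg.window_ps)
    window = Trajectory(traj.times[win_idx], traj.coordinates[win_idx],
                        None if traj.boxes is None else traj.boxes[win_idx])

    contacts = contact_series(system, window, th)
    resnums, by_seq = contacts.by_sequence_position()
    bound = bound_frame_mask(traj.times, dmin, th)[win_idx]
    occupancy = site_occupancy(contacts, spec.sites, bound)

    n_main = n_side = 0
    pistack_total = 0
    pistack_max = 0
    orient = {"parallel": 0, "herringbone": 0, "t_shaped": 0}
    for i, frame in enumerate(window):
        for ev in detect_hbonds(system, frame.coordinates, frame.box, th):
            if ev.partner_class == "main_chain":
                n_main += 1
            else:
                n_side += 1
        pis = detect_pi_stacking(system, frame.coordinates, frame.box, th)
        pistack_total += len(pis)
        pistack_max = max(pistack_max, len(pis))
        for ev in pis:
            orient[ev.orientation] += 1
    n_frames = window.n_frames

    rmsd_vals = [calpha_rmsd(system, window.coordinates[i],
                             system.coordinates)
                 for i in range(0, n_frames, max(1, n_frames // 20))]

    # energetics on strided window frames; one frame_energy call per frame
    # feeds the breakdown, the residue profile and the site attribution
    e_idx = win_idx[::cfg.energy_stride]
    frames_dom = dominant_residue(
        by_seq[:, np.searchsorted(win_idx, e_idx)], resnums)
    records, res_tables = [], []
    for k, i in enumerate(e_idx):
        fe = frame_energy(system, traj.coordinates[i], cfg.analysis,
                          per_residue=True)
        records.append(dict(frame=int(i), dE_vdw=fe.dE_vdw,
                            dE_elec=fe.dE_elec, dG_polar=fe.dG_polar,
                            dG_nonpolar=fe.dG_nonpolar,
                            dG_bind=fe.dG_bind,
                            dominant=int(frames_dom[k])))
        res_tables.append(fe.per_residue.assign(frame=int(i)))
    edf = pd.DataFrame(records)
    breakdown = EnergyBreakdown(
        dE_vdw=float(edf["dE_vdw"].mean()),
        dE_elec=float(edf["dE_elec"].mean()),
        dG_polar=float(edf["dG_polar"].mean()),
        dG_nonpolar=float(edf["dG_nonpolar"].mean()))
    res_all = pd.concat(res_tables, ignore_index=True)
    res_profile = (res_all.groupby("residue_number", as_index=False)
                   [["dE_vdw", "dE_elec", "dG_polar", "dG_nonpolar",
                     "dG_total"]].mean())

    return RunResult(
        run_index=run_index, seed=seed, expected_regime=expected,
        binding_time_ps=onset.time_ps, regime=onset.regime,
        breakdown=breakdown, residue_profile=res_profile,
        site_frames=edf,
        hbond_main=n_main / n_frames, hbond_side=n_side / n_frames,
        pistack_mean=pistack_total / n_frames, pistack_max=pistack_max,
        orientation_counts=orient, occupancy=occupancy,
        calpha_rmsd_nm=float(np.mean(rmsd_vals)))


def _aggregate_system(spec: NanoparticleSpec,
                      runs: list[RunResult]) -> SystemResult:
    ok = [r for r in runs if r.error is None and r.breakdown is not None]
    breakdown = aggregate_breakdowns([r.breakdown for r in ok]) if ok \
        else None
    profile = None
    if ok:
        prof = pd.concat([r.residue_profile for r in ok],
                         ignore_index=True)
        profile = prof.groupby("residue_number", as_index=False).mean()
    # site energies: conditional per-frame dG over all runs' energy frames
    sites = []
    if ok:
        frames = pd.concat([r.site_frames.assign(run=r.run_index)
                            for r in ok], ignore_index=True)
        for label, (lo, hi) in spec.sites.items():
            mask = (frames["dominant"] >= lo) & (frames["dominant"] <= hi)
            if mask.sum() == 0:
                sites.append(BindingSite(label, (lo, hi), float("nan"),
                                         float("nan"), 0))
            else:
                per_run = frames[mask].groupby("run")["dG_bind"].mean()
                sites.append(BindingSite(
                    label, (lo, hi), float(per_run.mean()),
                    float(per_run.std(ddof=0)), int(mask.sum())))
    occ = {}
    if ok:
        keys = list(ok[0].occupancy)
        occ = {k: float(np.nanmean([r.occupancy.get(k, np.nan)
                                    for r in ok])) for k in keys}
    return SystemResult(spec=spec, runs=runs, breakdown=breakdown,
                        residue_profile=profile, sites=sites, occupancy=occ)


def run_study(config: StudyConfig | None = None,
              log=sys.stderr) -> StudyReport:
    """Execute the full study; deterministic given the master seed.

    Failures inside a single run are isolated: the run is recorded with
    its error message and excluded from aggregation.
    """
    config = config or StudyConfig()
    systems = []
    for spec in config.nanoparticles:
        t_sys = time.time()
        system = build_complex(
            sequence=config.sequence, n_chains=config.n_chains,
            n_hydroxyl=spec.n_hydroxyl, seed=config.master_seed,
            target_site=spec.target_site, face_residue=spec.face_residue)
        runs = []
        for r in range(config.runs_per_system):
            seed = config.master_seed + r
            expected = DEFAULT_REGIMES[r % len(DEFAULT_REGIMES)]
            try:
                tspec = TrajectorySpec(
                    regime=expected, target_site=spec.target_site,
                    n_frames=spec.n_frames,
                    frame_interval=config.frame_interval, seed=seed,
                    bound_da=spec.bound_da,
                    anchor_wander=spec.anchor_wander,
                    slow_fraction=spec.slow_fraction)
                traj = generate_trajectory(system, tspec)
                runs.append(_analyse_run(system, traj, spec, config, r,
                                         seed, expected))
            except Exception as exc:
                print(f"[{spec.label} run {r}] failed: {exc}",
                      file=log)
                traceback.print_exc(file=log)
                runs.append(RunResult(
                    run_index=r, seed=seed, expected_regime=expected,
                    binding_time_ps=None, regime="error", breakdown=None,
                    residue_profile=None, site_frames=None,
                    hbond_main=0.0, hbond_side=0.0, pistack_mean=0.0,
                    pistack_max=0, orientation_counts={}, occupancy={},
                    calpha_rmsd_nm=float("nan"), error=str(exc)))
        systems.append(_aggregate_system(spec, runs))
        print(f"[{spec.label}] {config.runs_per_system} runs analysed "
              f"in {time.time() - t_sys:.1f} s", file=log)
    provenance = {
        "package": "fullerbind", "version": __version__,
        "master_seed": config.master_seed,
        "config_hash": config.config_hash(),
    }
    return StudyReport(config=config, systems=systems,
                       provenance=provenance)


def study_failed(report: StudyReport) -> bool:
    """True when any run of any system errored (CLI exit status)."""
    return any(r.error is not None for s in report.systems for r in s.runs)


# ---------------------------------------------------------------------------
# reference-table audit
# ---------------------------------------------------------------------------

_COMPONENT_COLUMNS = ["dE_vdw", "dE_elec", "dE_MM", "dG_polar",
                      "dG_nonpolar", "dG_solv", "dG_bind"]


def reference_component_table() -> pd.DataFrame:
    """Published MM/PBSA component table for the three Abeta42 systems
    (kcal/mol), bundled as package data."""
    path = Path(__file__).parent / "data" / "ab42_reference_components.tsv"
    return pd.read_csv(path, sep="\t")


def compare_breakdowns(reference: pd.DataFrame,
                       rounding_tol: float = 0.015,
                       exact_tol: float = 0.005) -> pd.DataFrame:
    """Audit the three additivity identities on a component table.

    For every row checks dE_MM = dE_vdw + dE_elec,
    dG_solv = dG_polar + dG_nonpolar and dG_bind = dE_MM + dG_solv - TdS
    (TdS column optional, default 0).  Residuals within ``exact_tol`` are
    "ok", within ``rounding_tol`` "rounding" (consistent with values
    printed to two decimals), larger ones "violation".
    """
    missing = [c for c in _COMPONENT_COLUMNS if c not in reference.columns]
    if missing:
        raise ValueError(f"reference table lacks columns {missing}")
    tds = reference["TdS"] if "TdS" in reference.columns else 0.0
    rows = []
    for i, row in reference.iterrows():
        checks = {
            "dE_MM": row["dE_vdw"] + row["dE_elec"] - row["dE_MM"],
            "dG_solv": (row["dG_polar"] + row["dG_nonpolar"]
                        - row["dG_solv"]),
            "dG_bind": (row["dE_MM"] + row["dG_solv"]
                        - (tds if np.isscalar(tds) else tds[i])
                        - row["dG_bind"]),
        }
        for identity, resid in checks.items():
            status = ("ok" if abs(resid) <= exact_tol else
                      "rounding" if abs(resid) <= rounding_tol else
                      "violation")
            rows.append(dict(system=row.get("system", str(i)),
                             identity=identity,
                             residual=round(float(resid), 6),
                             status=status))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def _header(report: StudyReport) -> str:
    p = report.provenance
    return (f"# fullerbind {p['version']}  seed={p['master_seed']}  "
            f"config={p['config_hash']}\n")


def write_report(report: StudyReport, out_dir) -> None:
    """Write the machine-readable TSVs plus a human-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    head = _header(report)

    rows = []
    for s in report.systems:
        if s.breakdown is None:
            continue
        d = s.breakdown.as_dict()
        d["system"] = s.spec.label
        rows.append(d)
    with open(out / "breakdown.tsv", "w") as fh:
        fh.write(head)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False,
                                  float_format="%.4f")

    rows = []
    for s in report.systems:
        for site in s.sites:
            rows.append(dict(system=s.spec.label, site=site.label,
                             dG_bind=site.dG_bind,
                             deviation=site.deviation,
                             n_frames=site.n_frames))
    with open(out / "sites.tsv", "w") as fh:
        fh.write(head)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False,
                                  float_format="%.4f")

    rows = []
    for s in report.systems:
        for r in s.runs:
            rows.append(dict(
                system=s.spec.label, run=r.run_index, seed=r.seed,
                expected_regime=r.expected_regime, regime=r.regime,
                binding_time_ps=r.binding_time_ps,
                hbond_main=r.hbond_main, hbond_side=r.hbond_side,
                pistack_mean=r.pistack_mean, pistack_max=r.pistack_max,
                calpha_rmsd_nm=r.calpha_rmsd_nm, error=r.error))
    with open(out / "kinetics.tsv", "w") as fh:
        fh.write(head)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False,
                                  float_format="%.4f")

    rows = []
    for s in report.systems:
        for site_label, p in s.occupancy.items():
            rows.append(dict(system=s.spec.label, site=site_label,
                             probability=p))
    with open(out / "occupancy.tsv", "w") as fh:
        fh.write(head)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False,
                                  float_format="%.4f")

    for s in report.systems:
        if s.residue_profile is None:
            continue
        safe = s.spec.label.replace("(", "").replace(")", "")
        with open(out / f"residue_profile_{safe}.tsv", "w") as fh:
            fh.write(head)
            s.residue_profile.to_csv(fh, sep="\t", index=False,
                                     float_format="%.4f")

    lines = [head.strip(), ""]
    for s in report.systems:
        lines.append(f"== {s.spec.label} ==")
        if s.breakdown is not None:
            b = s.breakdown
            lines.append(
                f"  dG_bind = {b.dG_bind:+.2f} +- {b.dG_bind_sem:.2f} "
                f"kcal/mol  (vdW {b.dE_vdw:+.2f}, elec {b.dE_elec:+.2f}, "
                f"polar {b.dG_polar:+.2f}, nonpolar {b.dG_nonpolar:+.2f}; "
                f"-TdS ignored)")
        recovered = sum(1 for r in s.runs
                        if r.regime == r.expected_regime)
        lines.append(f"  regimes recovered: {recovered}/{len(s.runs)}")
        best = min((x for x in s.sites if np.isfinite(x.dG_bind)),
                   key=lambda x: x.dG_bind, default=None)
        if best is not None:
            lines.append(f"  lowest-energy site: {best.label} "
                         f"({best.dG_bind:+.2f} kcal/mol)")
        lines.append("")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
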