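"""Analysis parameters with literature defaults, plus YAML round-trip.

All cutoffs live here so that every analysis can record the exact
configuration it used.  Defaults follow the values conventionally used for
fullerene-amyloid trajectory analysis: 0.54 nm heavy-atom contacts, 0.35 nm /
150 deg hydrogen bonds, 0.45 nm ring-centroid-to-cage-surface pi-stacking,
binding onset at d_min <= 0.30 nm, and MM/PBSA surface parameters
gamma = 0.542 kcal/mol/nm^2, b = 0.92 kcal/mol with a 0.14 nm probe.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class GeometryThresholds:
    contact_cutoff: float = 0.54      # nm, heavy-atom contact distance
    hbond_da_cutoff: float = 0.35     # nm, donor-acceptor distance (strict <)
    hbond_angle_min: float = 150.0    # deg, D-H-A angle (strict >)
    pistack_cutoff: float = 0.45      # nm, ring centroid to cage surface
    bound_dmin: float = 0.30          # nm, binding onset on d_min
    unbind_dmin: float = 0.45         # nm, loss-of-contact level for
                                      # the binding persistence check
    fast_regime_ns: float = 3.0       # fast/slow classification boundary
    persistence_ps: float = 1000.0    # binding persistence window
    salt_bridge_cutoff: float = 0.46  # nm, charged-group centre distance
    pistack_mode: str = "radial"      # "radial" or "nearest-carbon"

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.type == "float" and getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclass
class SasaParameters:
    probe_radius: float = 0.14        # nm, water probe
    gamma: float = 0.542              # kcal/mol/nm^2, surface tension
    b_const: float = 0.92             # kcal/mol, fit constant
    n_sphere_points: int = 960

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be >= 60")


@dataclass
class PBParameters:
    solute_dielectric: float = 2.0
    solvent_dielectric: float = 80.0
    ionic_strength: float = 0.1       # mol/L
    temperature: float = 310.0        # K
    grid_spacing: float = 0.05        # nm
    margin: float = 0.8               # nm added around the solute bounds
    tolerance: float = 1.0e-6         # relative residual of the solver
    max_iterations: int = 20000

    def __post_init__(self):
        if self.solute_dielectric < 1 or self.solvent_dielectric < 1:
            raise ValueError("dielectric constants must be >= 1")
        if self.grid_spacing <= 0 or self.tolerance <= 0:
            raise ValueError("grid_spacing and tolerance must be positive")


@dataclass
class AnalysisConfig:
    """Bundle of every tunable the pipeline reads."""

    thresholds: GeometryThresholds = field(default_factory=GeometryThresholds)
    sasa: SasaParameters = field(default_factory=SasaParameters)
    pb: PBParameters = field(default_factory=PBParameters)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(
            thresholds=GeometryThresholds(**d.get("thresholds", {})),
            sasa=SasaParameters(**d.get("sasa", {})),
            pb=PBParameters(**d.get("pb", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
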