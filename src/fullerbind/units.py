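"""Physical constants and unit conventions.

Internal units throughout the package: nanometres, picoseconds, kJ/mol and
elementary charges.  Energies are converted to kcal/mol only when reported,
because binding free-energy tables in this field are conventionally printed
in kcal/mol.
"""

#: Coulomb constant f = e^2 N_A / (4 pi eps0), in kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935458

#: kJ per kcal.
KCAL = 4.184

#: Molar gas constant, kJ mol^-1 K^-1.
GAS_CONSTANT = 8.31446261815324e-3

#: Avogadro-derived conversion: 1 mol/L expressed in particles per nm^3.
MOLAR_TO_PER_NM3 = 6.02214076e-4


def kj_to_kcal(x):
    """Convert kJ/mol to kcal/mol."""
    return x / KCAL


def kcal_to_kj(x):
    """Convert kcal/mol to kJ/mol."""
    return x * KCAL


def debye_kappa_sq(ionic_strength_molar: float, solvent_dielectric: float,
                   temperature: float) -> float:
    """Squared inverse Debye screening length, in nm^-2.

    kappa^2 = 8 pi f I / (eps_r R T) for a 1:1 electrolyte, with the ionic
    strength I converted to particles/nm^3.  At 0.1 M, 310 K and eps_r = 80
    this gives a Debye length of ~1 nm.
    """
    import math

    number_density = ionic_strength_molar * MOLAR_TO_PER_NM3
    return (8.0 * math.pi * COULOMB_CONSTANT * number_density
            / (solvent_dielectric * GAS_CONSTANT * temperature))
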