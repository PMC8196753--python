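"""Physical constants and unit conversions.

Internal units throughout the package: Angstrom, kcal/mol, amu, Kelvin,
elementary charge.  Quantities are converted to SI only inside partition
function prefactors (Planck constant, thermal wavelengths) and at output
time (e.g. densities in 1/nm^3 for figure-style exports).
"""

import math

# Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

# Coulomb prefactor: e^2/(4 pi eps0) in kcal/mol * Angstrom
COULOMB = 332.0637133

# SI building blocks
PLANCK_J_S = 6.62607015e-34
KB_J = 1.380649e-23
AVOGADRO = 6.02214076e23
C_CM_S = 2.99792458e10  # speed of light, cm/s
AMU_KG = 1.66053906660e-27
KCALMOL_J = 4184.0 / AVOGADRO  # kcal/mol -> J per molecule
ATM_PA = 101325.0

# kcal/mol/(amu Angstrom^2) -> s^-2 (for normal mode eigenvalues)
OMEGA2_SI = KCALMOL_J / (AMU_KG * 1e-20)


def wavenumber_from_eigenvalue(lam: float) -> float:
    """Harmonic wavenumber (cm^-1) from a mass-weighted Hessian eigenvalue.

    ``lam`` is in kcal/mol/(amu Angstrom^2); negative eigenvalues map to the
    magnitude of the corresponding imaginary frequency.
    """
    omega = math.sqrt(abs(lam) * OMEGA2_SI)
    return omega / (2.0 * math.pi * C_CM_S)


def thermal_wavelength_cubed_inv(mass_amu: float, temperature: float) -> float:
    """Translational partition function per volume, (2 pi m kT)^{3/2}/h^3, in 1/Angstrom^3."""
    m = mass_amu * AMU_KG
    val = (2.0 * math.pi * m * KB_J * temperature) ** 1.5 / PLANCK_J_S**3  # 1/m^3
    return val * 1e-30


def standard_concentration(temperature: float, convention: str = "1atm") -> float:
    """Standard-state number density in 1/Angstrom^3.

    ``1atm``: ideal gas at 1 atm and the given temperature (the convention of
    gas-phase cluster equilibria); ``1M``: 1 mol/L.
    """
    if convention == "1atm":
        return ATM_PA / (KB_J * temperature) * 1e-30
    if convention == "1M":
        return AVOGADRO / 1.0e27
    raise ValueError(f"unknown standard state convention: {convention!r}")
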