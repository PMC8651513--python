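"""Physical constants and unit conversions used throughout the package.

All internal distances are nm, energies kJ/mol (kcal/mol for free-energy
profiles, which is the conventional reporting unit), charges in units of the
elementary charge e, pressures in bar and tensions in mN/m.
"""

#: Boltzmann constant, kJ mol^-1 K^-1 (CODATA 2018).
KB_KJ_PER_MOL_K = 0.00831446261815324

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K = 0.0019872042586408316

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2 (GROMACS convention).
KE_COULOMB = 138.935458

#: 1 kJ mol^-1 nm^-3 expressed in bar.
KJ_PER_MOL_NM3_TO_BAR = 16.605390671738466

#: 1 bar nm = 1e-4 N/m = 0.1 mN/m (dimensional identity used by the
#: Kirkwood-Irving estimator).
BAR_NM_TO_MN_PER_M = 0.1

#: 1 e*nm in Debye (1 e*Angstrom = 4.8032045 D).
E_NM_TO_DEBYE = 48.032045

#: Molar mass of water, g/mol.
WATER_MOLAR_MASS = 18.01528

#: Default temperature (K) for all analyses unless overridden.
DEFAULT_TEMPERATURE = 298.15


def kt_kcal(temperature: float) -> float:
    """k_B*T in kcal/mol at ``temperature`` (K)."""
    return KB_KCAL_PER_MOL_K * temperature


def kt_kj(temperature: float) -> float:
    """k_B*T in kJ/mol at ``temperature`` (K)."""
    return KB_KJ_PER_MOL_K * temperature


def beta_kj(temperature: float) -> float:
    """Inverse temperature 1/(k_B*T) in mol/kJ."""
    return 1.0 / kt_kj(temperature)
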