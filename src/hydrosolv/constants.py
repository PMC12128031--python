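"""Physical constants in the package's internal unit system.

Internal units: lengths in nm, energies in kJ/mol, temperatures in K,
charges in elementary charges (e), masses in amu.  Ångström values are
accepted only at the I/O boundary (box edges of composition tables) and
converted once.
"""

#: Boltzmann constant, kJ mol^-1 K^-1 (CODATA).
KB = 0.008314462618

#: Coulomb constant k_e = 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_K = 138.935458

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23

#: Ångström to nm.
ANGSTROM_TO_NM = 0.1


def thermal_energy(temperature: float) -> float:
    """Return k_B*T in kJ/mol for a temperature in kelvin."""
    return KB * temperature
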