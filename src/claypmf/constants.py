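"""Physical constants and atomic masses used throughout the package.

Energies are kcal/mol, lengths Å, temperatures K everywhere.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL = 1.987204e-3

#: Default simulation temperature (K) of the desorption study conditions.
DEFAULT_TEMPERATURE = 350.0

#: Standard atomic weights (amu) for the elements that occur in the
#: clay / water / atrazine system.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "Cl": 35.45,
    "Ca": 40.078,
}


def kbt(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol."""
    return KB_KCAL * temperature
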