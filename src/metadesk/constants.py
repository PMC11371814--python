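"""Physical constants and unit conventions.

Internal units throughout the package: nm for length, kcal/mol for energy,
ps for time, K for temperature, radians for angles. Lengths in Å are accepted
only at file-format boundaries and converted on read.
"""

# Boltzmann constant, kcal/mol/K
KB_KCAL = 1.987204259e-3

# SI values used only to form the Eyring prefactor k_B*T/h (1/s)
KB_SI = 1.380649e-23  # J/K
H_SI = 6.62607015e-34  # J*s

ANGSTROM_PER_NM = 10.0


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB_KCAL * temperature


def eyring_prefactor(temperature: float) -> float:
    """Attempt frequency k_B*T/h in 1/s (about 6.25e12 at 300 K)."""
    return KB_SI * temperature / H_SI
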