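"""Unit system and physical constants.

Internally everything is expressed in nanometers, nanoseconds and thermal
energy units (k_BT).  SI enters only at the boundary, via the Stokes-Einstein
relation (temperature in K, viscosity in Pa s) and molar concentrations.
"""

BOLTZMANN_J_PER_K = 1.380649e-23

#: 1 m^2/s expressed in nm^2/ns
M2_PER_S_TO_NM2_PER_NS = 1e9

#: number density (nm^-3) of a 1 molar solution
MOLAR_TO_PER_NM3 = 6.02214076e23 / 1e24


def molar_to_number_density(c_molar: float) -> float:
    """Convert a molar concentration to a number density in nm^-3."""
    return c_molar * MOLAR_TO_PER_NM3
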