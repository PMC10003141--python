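"""Physical constants and unit conventions.

Internal units throughout the package: length in nm, time in ns, energy in
kcal/mol, temperature in K.  Rates are ns^-1 unless explicitly tagged.
Permeability coefficients are converted to cm/s only at reporting time.
"""

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: conversion factor: 1 nm/ns = 100 cm/s
NM_PER_NS_TO_CM_PER_S = 100.0

#: conversion factor: 1 ns^-1 = 1e9 s^-1
PER_NS_TO_PER_S = 1.0e9

#: conversion factor: 1 kJ/mol = 0.2390057 kcal/mol
KJ_TO_KCAL = 1.0 / 4.184

#: default simulation temperature, K (planar bilayer systems)
DEFAULT_TEMPERATURE = 293.15


def kt(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
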