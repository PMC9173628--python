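"""Physical constants and unit conversions.

Internal units throughout the package: kcal/mol (energy), Å (length),
fs (time), amu (mass), K (temperature), elementary charge e.
"""

# Boltzmann constant, kcal/mol/K
KB = 1.987204259e-3

# Coulomb constant in kcal·Å/mol/e²
COULOMB_K = 332.0636

# Planck constant over Boltzmann: k_B*T/h = T * KB_OVER_H  [1/s]
# k_B/h = 1.380649e-23 / 6.62607015e-34 = 2.083661912e10 1/(s·K)
KB_OVER_H = 2.083661912e10

# 1 kcal/mol expressed in amu·Å²/fs² (for Langevin dynamics)
KCAL_PER_MOL_TO_AMU_A2_FS2 = 4.184e-4

# Bulk water number density at ambient conditions, molecules/Å³
BULK_WATER_DENSITY = 0.0334

ROOM_T = 298.15
LN10 = 2.302585092994046


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KB * temperature
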