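"""Unit conventions and physical constants.

The package works in an AKMA-like unit system throughout:

* length   — ångström (Å)
* energy   — kcal/mol
* time     — picosecond (ps)
* mass     — unified atomic mass units (amu)
* angles   — radians

One kcal/mol equals ``KCAL_MOL_TO_AMU_A2_PS2`` amu·Å²/ps², so accelerations
computed from kcal/mol/Å forces must be multiplied by that factor.
"""

from __future__ import annotations

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872041

#: 1 kcal/mol expressed in amu·Å²/ps² (4184 J/mol / (1 g/mol · Å²/ps²)).
KCAL_MOL_TO_AMU_A2_PS2 = 418.4

#: Default thermal energy, kcal/mol, for the 310 K thermostat temperature
#: used by the receptor-ligand binding setups this package models.
DEFAULT_KT = 0.6163

#: Default temperature, kelvin.
DEFAULT_TEMPERATURE = 310.0


def kt_from_temperature(temperature_k: float) -> float:
    """Thermal energy kB·T in kcal/mol for a temperature in kelvin."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_KCAL_MOL_K * temperature_k
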