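"""Unit conversions anchored to physical constants.

Stress profiles come in bar with coordinates in nm (the local-stress tool's
convention); curvature parameters are reported in thermal-energy units
(kBT/nm) and forces in pN.  All conversion factors are computed from
scipy.constants at run time for an explicit temperature.
"""

from scipy import constants

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 303.15


def kbt_joule(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kB*T in joules."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return constants.k * temperature


def bar_nm2_to_kbt_per_nm(value: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a stress-profile moment from bar*nm^2 to kBT/nm.

    1 bar = 1e5 J/m^3, so 1 bar*nm^2 = 1e5 J/m^3 * 1e-18 m^2 = 1e-13 J/m
    = 1e-22 J/nm; dividing by kB*T gives the factor (~0.0239 at 303.15 K).
    """
    joule_per_nm = value * constants.bar * 1e-18 * 1e-9
    return joule_per_nm / kbt_joule(temperature)


def kbt_per_nm_to_pn(value: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert a force from kBT/nm to pN (~4.19 pN per kBT/nm at 303.15 K)."""
    newton = value * kbt_joule(temperature) / 1e-9
    return newton * 1e12
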