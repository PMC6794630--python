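"""Unit conversions shared across the package.

Internal convention: SI throughout the solver (m, s, mol m^-3, m^2 s^-1),
micrometres for geometry specifications and pixel sizes, and cm s^-1 for
reported permeability coefficients (the unit the barrier-assay literature
uses).
"""

from __future__ import annotations

import math

UM_PER_M = 1.0e6
M_PER_UM = 1.0e-6
S_PER_HOUR = 3600.0
S_PER_DAY = 86400.0
MOL_M3_PER_MOLAR = 1000.0  # 1 mol/L = 1000 mol/m^3


def convert_rate_molar_per_hour_to_si(rate_molar_per_hour: float) -> float:
    """Convert a volumetric production rate from mol L^-1 h^-1 to mol m^-3 s^-1.

    A secretion rate of 5e-12 M per hour corresponds to 1.4e-12 mol m^-3 s^-1
    (to two significant figures), the distributed amyloid-beta source strength
    used in the accumulation scenario.
    """
    if not math.isfinite(rate_molar_per_hour):
        raise ValueError(f"rate must be finite, got {rate_molar_per_hour!r}")
    return rate_molar_per_hour * MOL_M3_PER_MOLAR / S_PER_HOUR


def molar_to_mol_m3(c_molar: float) -> float:
    """Concentration mol/L -> mol/m^3."""
    return c_molar * MOL_M3_PER_MOLAR


def cm_s_to_m_s(p_cm_s: float) -> float:
    """Permeability cm/s -> m/s."""
    return p_cm_s * 1.0e-2


def m_s_to_cm_s(p_m_s: float) -> float:
    """Permeability m/s -> cm/s."""
    return p_m_s * 1.0e2


def um_to_m(x_um: float) -> float:
    return x_um * M_PER_UM


def m_to_um(x_m: float) -> float:
    return x_m * UM_PER_M
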