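"""Closed-form transport solutions used for verification and diagnostics.

These are independent of the finite-volume solver and of the estimator; the
test suite uses them as oracles, and the reports use them to quantify how far
an assay sits from the quasi-linear regime the two-point protocol assumes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfcx

__all__ = [
    "membrane_influx_per_area",
    "two_point_recovery_fraction",
    "two_compartment_gel_concentration",
]


def _f(z: np.ndarray | float) -> np.ndarray | float:
    """(erfcx(z) - 1 + 2 z / sqrt(pi)) / z^2, the cumulative-flux deficit factor."""
    z = np.asarray(z, dtype=float)
    out = np.ones_like(z)
    nz = z > 0
    out[nz] = (erfcx(z[nz]) - 1.0 + 2.0 * z[nz] / np.sqrt(np.pi)) / z[nz] ** 2
    return out if out.ndim else float(out)


def membrane_influx_per_area(
    p_m_s: float, t_s: float, c_lumen: float, d_lumen: float, d_gel: float
) -> float:
    """Cumulative mass per unit area crossing a membrane between two half-spaces.

    Initial concentration ``c_lumen`` on the luminal side, zero on the gel
    side, membrane permeability P. The exact Laplace-transform solution gives
    instantaneous flux F(t) = C_l P erfcx(beta sqrt(t)) with
    beta = P (D_l^-1/2 + D_g^-1/2), hence cumulative influx

        M(t) = C_l P t f(beta sqrt(t)),   f(z) = (erfcx z - 1 + 2 z/sqrt(pi))/z^2.

    f -> 1 as z -> 0 (the quasi-linear regime) and decays as back-diffusion
    builds a gel-side concentration against the membrane.
    """
    beta = p_m_s * (1.0 / np.sqrt(d_lumen) + 1.0 / np.sqrt(d_gel))
    z = beta * np.sqrt(t_s)
    return c_lumen * p_m_s * t_s * float(_f(z))


def two_point_recovery_fraction(
    p_m_s: float, window_s: float, d_lumen: float, d_gel: float
) -> float:
    """Expected (estimated P) / (true P) for the two-point protocol.

    A control volume that captures the full tracer front measures exactly the
    cumulative influx, so the two-point estimate over [0, t] recovers the
    fraction f(beta sqrt(t)) of the true membrane permeability. Equal to 1 in
    the small-P / fast-gel limit; materially below 1 for leaky barriers.
    """
    beta = p_m_s * (1.0 / np.sqrt(d_lumen) + 1.0 / np.sqrt(d_gel))
    return float(_f(beta * np.sqrt(window_s)))


def two_compartment_gel_concentration(
    p_m_s: float, t_s: float, c_lumen: float, cv_depth_m: float
) -> float:
    """Well-mixed CV approximation: C_g(t) = C_l (1 - exp(-P t / d)).

    Cruder than the half-space solution (no spatial gradients) but a useful
    independent check of early-time accumulation, dC_g/dt ~ P C_l / d.
    """
    return c_lumen * (1.0 - np.exp(-p_m_s * t_s / cv_depth_m))
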