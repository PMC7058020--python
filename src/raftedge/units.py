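"""Unit conversions.

Internal units throughout the package: energy in k_B T, length in nm.
Elastic moduli quoted in mN/m (tilt and area-stretching moduli, lateral
tension) are converted with 1 mN/m = 1e-21 J/nm^2, i.e. 0.25 k_B T/nm^2
for k_B T = 4e-21 J.
"""

from __future__ import annotations

#: Thermal energy in joules used for all mN/m <-> k_B T conversions.
KBT_JOULES = 4.0e-21


def mN_per_m_to_kBT_per_nm2(value: float, kBT_joules: float = KBT_JOULES) -> float:
    """Convert a surface modulus or tension from mN/m to k_B T/nm^2."""
    return value * 1.0e-21 / kBT_joules


def kBT_per_nm2_to_mN_per_m(value: float, kBT_joules: float = KBT_JOULES) -> float:
    """Inverse of :func:`mN_per_m_to_kBT_per_nm2`."""
    return value * kBT_joules / 1.0e-21


def kBT_per_nm_to_pN(value: float, kBT_joules: float = KBT_JOULES) -> float:
    """Convert an energy per unit length (line tension) from k_B T/nm to pN."""
    return value * kBT_joules / 1.0e-9 * 1.0e12


def pN_to_kBT_per_nm(value: float, kBT_joules: float = KBT_JOULES) -> float:
    """Inverse of :func:`kBT_per_nm_to_pN`."""
    return value * 1.0e-9 / 1.0e12 / kBT_joules
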