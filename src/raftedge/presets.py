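"""Bundled parameter presets.

The ``default`` membrane preset is the standard L_o/L_d parameter set used
throughout: splay moduli B_r = 20 k_B T (ordered) and B_s = 10 k_B T
(disordered); monolayer hydrophobic thicknesses h_r = 1.8 nm and
h_s = 1.3 nm; equal tilt moduli Kt = 40 mN/m and stretching moduli
Ka = 120 mN/m in both phases; lateral tension sigma0 = 0.025 k_B T/nm^2
per monolayer; zero spontaneous curvature in both phases.  The standard
inclusion width is 1.3 nm (about one alpha-helix diameter).
"""

from __future__ import annotations

from .parameters import MembraneParameters, MonolayerParameters

__all__ = [
    "DELTA_L",
    "membrane",
    "membrane_presets",
    "inclusion_presets",
]

#: Standard inclusion width (diameter of a single alpha-helix), nm.
DELTA_L = 1.3

_MEMBRANES: dict[str, dict] = {
    "default": dict(
        B_r=20.0, B_s=10.0, h_r=1.8, h_s=1.3,
        Kt_mN_per_m=40.0, Ka_mN_per_m=120.0,
        sigma0=0.025, J_r=0.0, J_s=0.0,
    ),
    # A mismatch-free control: both phases identical to the disordered phase.
    "symmetric": dict(
        B_r=10.0, B_s=10.0, h_r=1.3, h_s=1.3,
        Kt_mN_per_m=40.0, Ka_mN_per_m=120.0,
        sigma0=0.025, J_r=0.0, J_s=0.0,
    ),
}


def membrane(name: str = "default") -> MembraneParameters:
    """Return a bundled :class:`MembraneParameters` preset by name."""
    try:
        raw = _MEMBRANES[name]
    except KeyError:
        raise KeyError(
            f"unknown membrane preset {name!r}; available: {sorted(_MEMBRANES)}"
        ) from None
    common = dict(
        Kt_mN_per_m=raw["Kt_mN_per_m"],
        Ka_mN_per_m=raw["Ka_mN_per_m"],
        sigma0_kBT_per_nm2=raw["sigma0"],
    )
    return MembraneParameters(
        ordered=MonolayerParameters.from_conventional_units(
            B_kBT=raw["B_r"], J0_per_nm=raw["J_r"], h_nm=raw["h_r"], **common
        ),
        disordered=MonolayerParameters.from_conventional_units(
            B_kBT=raw["B_s"], J0_per_nm=raw["J_s"], h_nm=raw["h_s"], **common
        ),
    )


def membrane_presets() -> dict[str, dict]:
    """Raw membrane preset table (values in conventional units)."""
    return {k: dict(v) for k, v in _MEMBRANES.items()}


def inclusion_presets() -> dict[str, dict]:
    """Standard inclusion parameter values used in the reference scans.

    Transmembrane lengths are 2 h_s, h_r + h_s and 2 h_r of the default
    membrane; director jumps and stripe parameters cover the standard cases.
    """
    mem = membrane("default")
    h_r, h_s = mem.ordered.h, mem.disordered.h
    return {
        "deltaL_nm": DELTA_L,
        "transmembrane_h0_nm": [2 * h_s, h_r + h_s, 2 * h_r],
        "transmembrane_dnx": [-0.4, 0.0, +0.4],
        "hydrophobic_dn_mag": [0.2, 0.4, 0.6],
        "stripe_h0_nm": [h_s, 0.5 * (h_r + h_s), h_r],
        "stripe_J0_per_nm": [-0.25, 0.0, +0.25],
        "stripe_B0_kBT": [10.0, 20.0],
    }
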