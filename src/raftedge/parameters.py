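"""Elastic parameters of a lipid monolayer and of a two-phase membrane.

A monolayer in a given phase (liquid-ordered L_o or liquid-disordered L_d)
is described by five elastic constants and one geometric one:

* ``B`` — splay (bending) modulus of the monolayer, k_B T;
* ``Kt`` — tilt modulus, k_B T/nm^2;
* ``Ka`` — lateral compression/stretching modulus, k_B T/nm^2;
* ``J0`` — spontaneous curvature, 1/nm (positive for inverted-cone,
  lysolipid/GM1-like shapes);
* ``sigma0`` — lateral tension per monolayer, k_B T/nm^2;
* ``h`` — hydrophobic thickness of the undeformed monolayer, nm.

The equilibrium stretching under tension is ``alpha0 = sigma0/Ka``
(dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import units

__all__ = ["MonolayerParameters", "MembraneParameters"]


@dataclass(frozen=True)
class MonolayerParameters:
    """Elastic constants and geometry of one monolayer leaflet in one phase."""

    B: float        # splay modulus, k_B T
    Kt: float       # tilt modulus, k_B T/nm^2
    Ka: float       # stretching modulus, k_B T/nm^2
    J0: float       # spontaneous curvature, 1/nm
    h: float        # hydrophobic monolayer thickness, nm
    sigma0: float   # lateral tension per monolayer, k_B T/nm^2

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError(f"splay modulus B must be positive, got {self.B}")
        if self.Kt <= 0:
            raise ValueError(f"tilt modulus Kt must be positive, got {self.Kt}")
        if self.Ka <= 0:
            raise ValueError(f"stretching modulus Ka must be positive, got {self.Ka}")
        if self.h <= 0:
            raise ValueError(f"monolayer thickness h must be positive, got {self.h}")

    @property
    def alpha0(self) -> float:
        """Equilibrium lateral stretching under the imposed tension."""
        return self.sigma0 / self.Ka

    @property
    def flat_thickness(self) -> float:
        """Hydrophobic thickness of the flat, tension-equilibrated monolayer (nm)."""
        return self.h * (1.0 - self.alpha0)

    @property
    def flat_energy_density(self) -> float:
        """Energy density of the flat reference state, k_B T/nm^2.

        In the flat state splay vanishes, so the only nonzero term is the
        frustrated spontaneous curvature, B/2 * J0^2.  This constant is
        subtracted from every raw density so that undeformed bulk phases
        contribute zero energy.
        """
        return 0.5 * self.B * self.J0 ** 2

    def replace(self, **changes) -> "MonolayerParameters":
        return replace(self, **changes)

    @classmethod
    def from_conventional_units(
        cls,
        *,
        B_kBT: float,
        Kt_mN_per_m: float,
        Ka_mN_per_m: float,
        J0_per_nm: float,
        h_nm: float,
        sigma0_kBT_per_nm2: float,
        kBT_joules: float = units.KBT_JOULES,
    ) -> "MonolayerParameters":
        """Build parameters from the units in which they are usually quoted."""
        return cls(
            B=B_kBT,
            Kt=units.mN_per_m_to_kBT_per_nm2(Kt_mN_per_m, kBT_joules),
            Ka=units.mN_per_m_to_kBT_per_nm2(Ka_mN_per_m, kBT_joules),
            J0=J0_per_nm,
            h=h_nm,
            sigma0=sigma0_kBT_per_nm2,
        )


@dataclass(frozen=True)
class MembraneParameters:
    """Per-phase monolayer parameters of an L_o/L_d two-phase membrane.

    ``ordered`` (index *r*) is the liquid-ordered phase of the raft,
    ``disordered`` (index *s*) the surrounding liquid-disordered phase.
    """

    ordered: MonolayerParameters
    disordered: MonolayerParameters

    @property
    def thickness_mismatch(self) -> float:
        """Monolayer thickness difference h_r - h_s, nm."""
        return self.ordered.h - self.disordered.h
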