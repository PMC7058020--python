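"""Boundary conditions of membrane inclusions.

Five inclusion families are supported, each translating into a set of
excluded spans and linear constraints on the deformation fields:

* ``amphipathic_shallow`` — an alpha-helix lying in the headgroup region of
  one leaflet.  The helix pushes lipid heads apart, prescribing a director
  jump of negative x-projection across its span (magnitude from the
  geometric estimates below); rigid rotation of the helix offsets the
  neutral surface between its two edges in proportion to the free mean
  boundary director.  The leaflet is excluded over the span; the opposing
  leaflet is left unconstrained.
* ``hydrophobic_deep`` — a peptide buried among the acyl chains of one
  leaflet.  It pushes tails apart (director jump of positive x-projection,
  magnitude a free parameter) while the neutral surface stays continuous;
  applied across a single grid cell.
* ``hydrophobic_midplane`` — the same, sitting at the monolayer interface
  and splaying the tails of both leaflets; both neutral surfaces continuous.
* ``transmembrane`` — an undeformable protein spanning the bilayer: both
  leaflets excluded over its width, bilayer thickness pinned to the
  protein's hydrophobic length h0 at both edges, boundary directors fixed
  so the across-protein jump is dnx (split symmetrically, n1 = -dnx/2,
  n2 = +dnx/2 per leaflet); its vertical position is free.
* ``lipid_stripe`` — a deformable monolayer stripe of foreign lipid: the
  leaflet's elastic parameters are replaced on the span (splay modulus B0,
  spontaneous curvature J0, thickness h0), with directors and neutral
  surfaces continuous at its edges.  Nothing is excluded.

The director-jump magnitude of a peptide of width ``deltaL`` in a bulk
phase of monolayer thickness ``h`` follows from the geometry of lipids
wrapping a cylinder:  |dn| = deltaL / sqrt((deltaL/2)^2 + (h/2)^2).  At
the phase boundary the jump interpolates between the two phases with the
fraction ``delta`` of the peptide width embedded in the ordered phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

from .layout import RegionLayout
from .parameters import MonolayerParameters
from .solver import LinearConstraint

__all__ = [
    "FAMILIES",
    "InclusionSpec",
    "director_jump_bulk",
    "director_jump_boundary",
    "build_constraints",
]

FAMILIES = (
    "amphipathic_shallow",
    "hydrophobic_deep",
    "hydrophobic_midplane",
    "transmembrane",
    "lipid_stripe",
)


def director_jump_bulk(deltaL: float, h: float) -> float:
    """|dn| of a peptide of width deltaL in a bulk phase of thickness h."""
    if deltaL <= 0 or h <= 0:
        raise ValueError("deltaL and h must be positive")
    return deltaL / math.sqrt((deltaL / 2) ** 2 + (h / 2) ** 2)


def director_jump_boundary(deltaL: float, h_r: float, h_s: float,
                           delta: float) -> float:
    """|dn| of a peptide straddling the phase boundary.

    ``delta`` is the fraction of the peptide width embedded in the ordered
    (h_r) monolayer; delta = 1 and delta = 0 reduce to the bulk values.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    return (delta * director_jump_bulk(deltaL, h_r)
            + (1.0 - delta) * director_jump_bulk(deltaL, h_s))


@dataclass(frozen=True)
class InclusionSpec:
    """Tagged description of one membrane inclusion.

    ``X0`` is the center and ``deltaL`` the width (nm).  Family-specific
    fields: ``dn_mag`` (hydrophobic peptides), ``h0`` (transmembrane length
    or stripe monolayer thickness, nm), ``dnx_u``/``dnx_l`` (transmembrane
    boundary-director x-jumps per leaflet), ``B0``/``J0`` (stripe splay
    modulus and spontaneous curvature).  Single-leaflet families act on
    ``leaflet`` ('upper' by default).
    """

    family: str
    X0: float
    deltaL: float
    dn_mag: float = 0.0
    h0: float | None = None
    dnx_u: float = 0.0
    dnx_l: float = 0.0
    B0: float | None = None
    J0: float = 0.0
    leaflet: str = "upper"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown inclusion family {self.family!r}; "
                             f"choose from {FAMILIES}")
        if self.deltaL <= 0:
            raise ValueError("inclusion width deltaL must be positive")
        if self.leaflet not in ("upper", "lower"):
            raise ValueError("leaflet must be 'upper' or 'lower'")
        if self.family == "transmembrane":
            if self.h0 is None or self.h0 <= 0:
                raise ValueError("transmembrane inclusions need h0 > 0")
            for v in (self.dnx_u, self.dnx_l):
                if abs(v) > 2:
                    raise ValueError("|dnx| cannot exceed 2")
        if self.family == "lipid_stripe" and (self.h0 is None or self.B0 is None):
            raise ValueError("lipid stripes need h0 and B0")

    def at(self, X0: float) -> "InclusionSpec":
        """Copy of this spec re-centered at X0 (for positional scans)."""
        return dc_replace(self, X0=X0)

    def mirrored(self, L: float) -> "InclusionSpec":
        """Counterpart under reflection through the bilayer midplane.

        Swaps the host leaflet (and the per-leaflet transmembrane director
        jumps) and shifts the center by -L, matching
        :meth:`raftedge.layout.RegionLayout.mirrored`.
        """
        other = "lower" if self.leaflet == "upper" else "upper"
        return dc_replace(self, X0=self.X0 - L, leaflet=other,
                          dnx_u=self.dnx_l, dnx_l=self.dnx_u)


def _host_phase_boundary(layout: RegionLayout, leaflet: str) -> float:
    return layout.L if leaflet == "upper" else 0.0


def build_constraints(
    spec: InclusionSpec, layout: RegionLayout
) -> tuple[RegionLayout, tuple[LinearConstraint, ...]]:
    """Translate an inclusion into layout exclusions/overrides + constraints.

    Returns a new layout (with the spans the inclusion occupies excluded,
    or the stripe parameters substituted) and the linear constraint rows
    encoding the inclusion's boundary conditions; feed both to the solver.
    """
    a = spec.X0 - spec.deltaL / 2
    b = spec.X0 + spec.deltaL / 2
    leaf_attr = spec.leaflet
    nf = "n_u" if leaf_attr == "upper" else "n_l"
    hf = "H_u" if leaf_attr == "upper" else "H_l"
    # neutral-surface offsets mirror under leaflet reflection
    s_h = 1.0 if leaf_attr == "upper" else -1.0
    cons: list[LinearConstraint] = []

    if spec.family == "amphipathic_shallow":
        leaf = getattr(layout, leaf_attr)
        host_b = _host_phase_boundary(layout, leaf_attr)
        delta = min(1.0, max(0.0, (b - host_b) / spec.deltaL))
        if layout.membrane is not None:
            h_r = layout.membrane.ordered.h
            h_s = layout.membrane.disordered.h
        else:  # fall back to local thicknesses
            h_r = leaf.params_at(b).h
            h_s = leaf.params_at(a).h
        mag = director_jump_boundary(spec.deltaL, h_r, h_s, delta)
        new_leaf = dc_replace(leaf, excluded_spans=leaf.excluded_spans + ((a, b),))
        new_layout = dc_replace(layout, **{leaf_attr: new_leaf},
                                X0=spec.X0, deltaL=spec.deltaL)
        cons.append(LinearConstraint(
            ((nf, b, 1.0, 0), (nf, a, -1.0, 0)), -mag,
            "amphipathic director jump (heads pushed apart)"))
        # rigid rotation couples the edge offset of the neutral surface to
        # the free mean boundary director
        cons.append(LinearConstraint(
            ((hf, b, s_h, 0), (hf, a, -s_h, 0),
             (nf, a, -spec.deltaL / 2, 0), (nf, b, -spec.deltaL / 2, 0)),
            0.0, "peptide-rotation neutral-surface offset"))
        return new_layout, tuple(cons)

    if spec.family in ("hydrophobic_deep", "hydrophobic_midplane"):
        leaflets = ([leaf_attr] if spec.family == "hydrophobic_deep"
                    else ["upper", "lower"])
        new_layout = layout
        for lf in leaflets:
            leaf = getattr(new_layout, lf)
            new_leaf = dc_replace(leaf,
                                  excluded_cells=leaf.excluded_cells + (spec.X0,))
            new_layout = dc_replace(new_layout, **{lf: new_leaf})
            nfi = "n_u" if lf == "upper" else "n_l"
            hfi = "H_u" if lf == "upper" else "H_l"
            cons.append(LinearConstraint(
                ((nfi, spec.X0, 1.0, 1), (nfi, spec.X0, -1.0, 0)), spec.dn_mag,
                "deep-peptide director jump (tails pushed apart)"))
            cons.append(LinearConstraint(
                ((hfi, spec.X0, 1.0, 1), (hfi, spec.X0, -1.0, 0)), 0.0,
                "neutral-surface continuity across the peptide"))
        new_layout = dc_replace(new_layout, X0=spec.X0, deltaL=spec.deltaL)
        return new_layout, tuple(cons)

    if spec.family == "transmembrane":
        up = dc_replace(layout.upper,
                        excluded_spans=layout.upper.excluded_spans + ((a, b),))
        lo = dc_replace(layout.lower,
                        excluded_spans=layout.lower.excluded_spans + ((a, b),))
        new_layout = dc_replace(
            layout, upper=up, lower=lo,
            excluded_mid_spans=layout.excluded_mid_spans + ((a, b),),
            X0=spec.X0, deltaL=spec.deltaL)
        for edge in (a, b):
            cons.append(LinearConstraint(
                (("H_u", edge, 1.0, 0), ("H_l", edge, -1.0, 0)), spec.h0,
                "transmembrane hydrophobic thickness"))
        # rigid body with fixed director orientation: no tilt, so both edges
        # sit at the same height (the common height itself stays free)
        cons.append(LinearConstraint(
            (("H_u", a, 1.0, 0), ("H_u", b, -1.0, 0)), 0.0,
            "transmembrane rigidity (no tilt)"))
        for fname, dnx in (("n_u", spec.dnx_u), ("n_l", spec.dnx_l)):
            cons.append(LinearConstraint(
                ((fname, a, 1.0, 0),), -dnx / 2, "transmembrane boundary director"))
            cons.append(LinearConstraint(
                ((fname, b, 1.0, 0),), +dnx / 2, "transmembrane boundary director"))
        return new_layout, tuple(cons)

    # lipid_stripe: parameter substitution, continuity is automatic on the
    # shared grid -- no constraints at all
    leaf = getattr(layout, leaf_attr)
    host = leaf.params_at(spec.X0)
    stripe = MonolayerParameters(B=spec.B0, Kt=host.Kt, Ka=host.Ka,
                                 J0=spec.J0, h=spec.h0, sigma0=host.sigma0)
    new_leaf = leaf.with_override(a, b, stripe)
    new_layout = dc_replace(layout, **{leaf_attr: new_leaf},
                            X0=spec.X0, deltaL=spec.deltaL)
    return new_layout, ()
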