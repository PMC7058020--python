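"""Piecewise description of the membrane along the x axis.

The membrane is divided into piecewise-uniform regions.  By convention the
L_o/L_d phase boundary of the *lower* monolayer sits at x = 0 and that of
the *upper* monolayer at x = L (the signed interleaflet boundary shift).
The disordered phase occupies x -> -inf, the ordered phase x -> +inf, so
for L > 0 the intermediate "hybrid" strip 0 < x < L has an ordered lower
leaflet under a disordered upper leaflet.

Inclusions modify the layout by overriding leaflet parameters on a span
(deformable lipid stripes) or by excluding a leaflet from a span entirely
(undeformable peptides and proteins); see :mod:`raftedge.inclusions`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .parameters import MembraneParameters, MonolayerParameters

__all__ = ["LeafletLayout", "RegionLayout"]

_INF = math.inf


@dataclass(frozen=True)
class LeafletLayout:
    """One leaflet: parameter pieces plus spans excluded by inclusions.

    ``pieces`` is an ordered list of ``(x_left, x_right, params)`` covering
    the whole axis (first piece starts at -inf, last ends at +inf).
    ``excluded_spans`` are finite-width spans occupied by an undeformable
    inclusion: the leaflet's lipid fields do not exist there.
    ``excluded_cells`` are point-like exclusions (deeply inserted peptides):
    a single grid cell at the given x is removed from this leaflet's energy
    while the neutral surface stays continuous across it.
    """

    pieces: tuple[tuple[float, float, MonolayerParameters], ...]
    excluded_spans: tuple[tuple[float, float], ...] = ()
    excluded_cells: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.pieces:
            raise ValueError("leaflet needs at least one parameter piece")
        if self.pieces[0][0] != -_INF or self.pieces[-1][1] != _INF:
            raise ValueError("pieces must cover the whole axis")
        for (a0, b0, _), (a1, _b1, _) in zip(self.pieces, self.pieces[1:]):
            if b0 != a1 or not (a0 < b0):
                raise ValueError("pieces must be contiguous and increasing")

    def params_at(self, x: float) -> MonolayerParameters:
        """Leaflet parameters at position x (right-continuous at breakpoints)."""
        for a, b, p in self.pieces:
            if a <= x < b:
                return p
        return self.pieces[-1][2]

    def with_override(
        self, a: float, b: float, params: MonolayerParameters
    ) -> "LeafletLayout":
        """Return a copy with ``params`` substituted on the span [a, b]."""
        if not a < b:
            raise ValueError("override span must have positive width")
        new: list[tuple[float, float, MonolayerParameters]] = []
        for lo, hi, p in self.pieces:
            if hi <= a or lo >= b:
                new.append((lo, hi, p))
                continue
            if lo < a:
                new.append((lo, a, p))
            if hi > b:
                new.append((b, hi, p))
        new.append((a, b, params))
        new.sort(key=lambda t: t[0])
        return replace(self, pieces=tuple(new))

    def breakpoints(self) -> list[float]:
        pts = [a for a, _, _ in self.pieces[1:]]
        for a, b in self.excluded_spans:
            pts += [a, b]
        pts += list(self.excluded_cells)
        return pts


@dataclass(frozen=True)
class RegionLayout:
    """Full piecewise description of the two-leaflet membrane.

    Attributes
    ----------
    upper, lower : LeafletLayout
        Per-leaflet parameter pieces and exclusions.
    L : float
        Signed interleaflet boundary shift, nm (upper-leaflet phase
        boundary at x = L; lower-leaflet boundary fixed at x = 0).
    excluded_mid_spans : spans where the monolayer interface M does not
        exist either (transmembrane inclusions).
    X0, deltaL : center and width of the inclusion, if any (bookkeeping).
    """

    upper: LeafletLayout
    lower: LeafletLayout
    L: float = 0.0
    excluded_mid_spans: tuple[tuple[float, float], ...] = ()
    X0: float | None = None
    deltaL: float | None = None
    membrane: MembraneParameters | None = field(default=None, compare=False)

    @classmethod
    def bare_boundary(cls, membrane: MembraneParameters, L: float = 0.0) -> "RegionLayout":
        """Layout of the plain domain boundary with boundary shift L.

        The disordered phase lies at x < 0 (lower leaflet) / x < L (upper
        leaflet); the ordered phase at larger x.
        """
        s, r = membrane.disordered, membrane.ordered

        def leaflet(xb: float) -> LeafletLayout:
            return LeafletLayout(pieces=((-_INF, xb, s), (xb, _INF, r)))

        return cls(upper=leaflet(L), lower=leaflet(0.0), L=L, membrane=membrane)

    @classmethod
    def uniform(cls, params: MonolayerParameters) -> "RegionLayout":
        """Single-phase membrane (no boundary): identical leaflets everywhere."""
        leaf = LeafletLayout(pieces=((-_INF, 0.0, params), (0.0, _INF, params)))
        mem = MembraneParameters(ordered=params, disordered=params)
        return cls(upper=leaf, lower=leaf, L=0.0, membrane=mem)

    def breakpoints(self) -> list[float]:
        """Finite x positions where the structure changes (for box sizing)."""
        pts = set(self.upper.breakpoints()) | set(self.lower.breakpoints())
        pts.add(0.0)
        pts.add(self.L)
        for a, b in self.excluded_mid_spans:
            pts.update((a, b))
        return sorted(pts)

    def mirrored(self) -> "RegionLayout":
        """Reflection through the bilayer midplane.

        Swaps the leaflets and shifts x by -L so that the lower-leaflet
        phase boundary is again at x = 0; the boundary shift becomes -L.
        The elastic energy is invariant under this operation.
        """
        dxs = -self.L

        def shift_leaf(leaf: LeafletLayout) -> LeafletLayout:
            pieces = tuple(
                (a + dxs if a != -_INF else a, b + dxs if b != _INF else b, p)
                for a, b, p in leaf.pieces
            )
            spans = tuple((a + dxs, b + dxs) for a, b in leaf.excluded_spans)
            cells = tuple(x + dxs for x in leaf.excluded_cells)
            return LeafletLayout(pieces=pieces, excluded_spans=spans, excluded_cells=cells)

        return replace(
            self,
            upper=shift_leaf(self.lower),
            lower=shift_leaf(self.upper),
            L=-self.L,
            excluded_mid_spans=tuple(
                (a + dxs, b + dxs) for a, b in self.excluded_mid_spans
            ),
            X0=None if self.X0 is None else self.X0 + dxs,
        )
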