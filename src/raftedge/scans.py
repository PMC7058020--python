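"""Energy landscapes: boundary-shift and inclusion-position scans.

The headline outputs of the model are one-dimensional energy profiles:

* ``W(L)`` — elastic energy per unit boundary length of the bare domain
  boundary as a function of the interleaflet boundary shift L.  Its
  minimum defines the equilibrium shift L0 (about 3 nm for the default
  parameters) and the line tension of the boundary.
* ``W(X0)`` — energy as a function of the lateral position of an
  inclusion, at fixed boundary shift (by convention the bare-boundary
  optimum, L = +/-L0).  Far plateaus give the bulk-phase energies; the
  minima quantify the affinity of the inclusion for the domain boundary.

Depths are reported relative to the nearer plateau (the convention used
when quoting "minima depth") and relative to the higher of the two
plateaus; Boltzmann factors convert energy differences into lateral
enrichment/depletion ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dfield

import numpy as np

from . import units
from .inclusions import InclusionSpec, build_constraints
from .layout import RegionLayout
from .parameters import MembraneParameters, MonolayerParameters
from .solver import Grid, solve_layout

__all__ = [
    "EnergyProfile",
    "Minimum",
    "boundary_energy_profile",
    "find_equilibrium_shift",
    "inclusion_energy_profile",
    "bulk_self_energy",
    "minima_analysis",
    "line_tension_pN",
    "boltzmann_factor",
]

logger = logging.getLogger(__name__)

#: default abscissa step for scans, nm
SCAN_STEP = 0.25
#: plateau flatness gate, k_B T/nm per nm of abscissa
PLATEAU_SLOPE_TOL = 1e-3


@dataclass(frozen=True)
class Minimum:
    """A local minimum of an energy profile.

    Depths are stored against every useful reference: the spatially nearer
    plateau, each individual plateau, and (as properties) the lower and the
    higher of the two plateaus.  When a profile's plateaus differ strongly,
    the physically meaningful binding depth is the one measured from the
    *lower* plateau — the bulk phase the inclusion would otherwise occupy.
    """

    position: float            # nm (parabolically refined)
    W: float                   # k_B T/nm at the minimum
    depth_nearest: float       # vs the spatially nearer plateau, k_B T/nm
    depth_vs_left: float       # vs the left (x -> -inf) plateau
    depth_vs_right: float      # vs the right (x -> +inf) plateau
    is_global: bool

    @property
    def depth_vs_lower_plateau(self) -> float:
        return min(self.depth_vs_left, self.depth_vs_right)

    @property
    def depth_max_plateau(self) -> float:
        return max(self.depth_vs_left, self.depth_vs_right)


@dataclass
class EnergyProfile:
    """Result of a 1D energy scan."""

    kind: str                  # 'boundary_shift' or 'inclusion_position'
    abscissa: np.ndarray       # L or X0 values, nm
    W: np.ndarray              # k_B T/nm
    L: float | None = None     # fixed boundary shift of an inclusion scan
    plateau_left: float | None = None
    plateau_right: float | None = None
    minima: list[Minimum] = dfield(default_factory=list)
    meta: dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if len(self.abscissa) != len(self.W):
            raise ValueError("abscissa and W must have equal length")

    @property
    def plateau_max(self) -> float | None:
        if self.plateau_left is None or self.plateau_right is None:
            return None
        return max(self.plateau_left, self.plateau_right)

    def global_minimum(self) -> Minimum | None:
        for m in self.minima:
            if m.is_global:
                return m
        return None

    def to_dataframe(self):
        import pandas as pd

        name = "L_nm" if self.kind == "boundary_shift" else "X0_nm"
        return pd.DataFrame({name: self.abscissa, "W_kBT_per_nm": self.W})

    def summary(self) -> dict:
        out = {
            "kind": self.kind,
            "L_nm": self.L,
            "plateau_left_kBT_per_nm": self.plateau_left,
            "plateau_right_kBT_per_nm": self.plateau_right,
            "minima": [
                {
                    "position_nm": m.position,
                    "W_kBT_per_nm": m.W,
                    "depth_vs_nearer_plateau_kBT_per_nm": m.depth_nearest,
                    "depth_vs_lower_plateau_kBT_per_nm": (
                        m.depth_vs_lower_plateau),
                    "is_global": m.is_global,
                }
                for m in self.minima
            ],
        }
        out.update(self.meta)
        return out


def _parabolic_vertex(xs: np.ndarray, ys: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (falls back to i).

    Handles non-uniform abscissa spacing (profiles refined locally around
    their minima are denser there).
    """
    if i == 0 or i == len(xs) - 1:
        return float(xs[i]), float(ys[i])
    a, b, c = np.polyfit(xs[i - 1:i + 2], ys[i - 1:i + 2], 2)
    if a <= 0:
        return float(xs[i]), float(ys[i])
    xv = -b / (2 * a)
    if not xs[i - 1] <= xv <= xs[i + 1]:
        return float(xs[i]), float(ys[i])
    return float(xv), float(c - b * b / (4 * a))


def minima_analysis(profile: EnergyProfile,
                    min_prominence: float = 1e-9) -> list[Minimum]:
    """Locate and refine the local minima of a profile.

    Each minimum's depth is reported relative to the nearer plateau and to
    each individual plateau (for boundary-shift profiles, which have no
    plateaus, depths are relative to the profile ends).  Dips shallower
    than ``min_prominence`` against their immediate neighbours are treated
    as numerical noise.  The list is stored on the profile and returned.
    """
    xs, ys = profile.abscissa, profile.W
    p_l = profile.plateau_left if profile.plateau_left is not None else ys[0]
    p_r = profile.plateau_right if profile.plateau_right is not None else ys[-1]
    minima: list[Minimum] = []
    cand: list[tuple[float, float]] = []
    for i in range(1, len(xs) - 1):
        if (ys[i] < ys[i - 1] and ys[i] <= ys[i + 1]
                and min(ys[i - 1], ys[i + 1]) - ys[i] > min_prominence):
            cand.append(_parabolic_vertex(xs, ys, i))
    if cand:
        w_glob = min(w for _, w in cand)
        mid = 0.5 * (xs[0] + xs[-1])
        for pos, w in cand:
            nearer = p_l if pos < mid else p_r
            minima.append(Minimum(
                position=pos, W=w,
                depth_nearest=float(nearer - w),
                depth_vs_left=float(p_l - w),
                depth_vs_right=float(p_r - w),
                is_global=math.isclose(w, w_glob, rel_tol=0, abs_tol=1e-12),
            ))
    profile.minima = minima
    return minima


def boundary_energy_profile(
    membrane: MembraneParameters,
    L_values: np.ndarray | None = None,
    grid: Grid | None = None,
) -> EnergyProfile:
    """W(L) of the bare domain boundary.

    The profile is symmetric, W(L) = W(-L): reflecting the bilayer through
    its midplane swaps the leaflets and flips the sign of the shift.
    """
    if L_values is None:
        L_values = np.arange(-6.0, 6.0 + SCAN_STEP / 2, SCAN_STEP)
    grid = grid or Grid()
    L_values = np.asarray(L_values, dtype=float)
    Ws = np.empty_like(L_values)
    for i, L in enumerate(L_values):
        try:
            Ws[i] = solve_layout(RegionLayout.bare_boundary(membrane, L=L),
                                 grid=grid).W
        except Exception as exc:
            raise RuntimeError(f"boundary scan failed at L={L:g} nm") from exc
    profile = EnergyProfile(kind="boundary_shift", abscissa=L_values, W=Ws)
    minima_analysis(profile)
    return profile


def find_equilibrium_shift(
    membrane: MembraneParameters,
    L_values: np.ndarray | None = None,
    grid: Grid | None = None,
    profile: EnergyProfile | None = None,
) -> tuple[float, float]:
    """Equilibrium interleaflet boundary shift L0 and W(L0).

    Returns the positive member of the degenerate +/-L0 pair (parabolically
    refined).  If the positive half-axis holds several local minima a
    warning is logged and the deepest is returned.
    """
    if profile is None:
        profile = boundary_energy_profile(membrane, L_values, grid)
    minima = profile.minima or minima_analysis(profile)
    half = [m for m in minima if m.position >= -SCAN_STEP / 2]
    if not half:
        # monotone or flat on the half-axis: minimum at L = 0
        i = int(np.argmin(profile.W))
        pos, w = _parabolic_vertex(profile.abscissa, profile.W, i)
        return abs(pos), w
    if len(half) > 1:
        logger.warning("W(L) is not unimodal on the positive half-axis: "
                       "minima at %s", [round(m.position, 3) for m in half])
    best = min(half, key=lambda m: m.W)
    return abs(best.position), best.W


def inclusion_energy_profile(
    spec: InclusionSpec,
    membrane: MembraneParameters,
    L: float,
    X0_values: np.ndarray | None = None,
    grid: Grid | None = None,
    check_plateaus: bool = True,
    refine_step: float | None = 0.05,
) -> EnergyProfile:
    """W(X0): elastic energy vs lateral inclusion position at fixed L.

    The scan range must reach both bulk plateaus; each plateau is
    estimated as the mean of the outer 10% of its tail and guarded by a
    flatness gate (a sloping tail raises a range-too-small error).  Wells
    detected on the coarse scan are re-sampled at ``refine_step`` before
    the parabolic refinement (some minima are considerably sharper than
    the default 0.25 nm scan step).
    """
    if X0_values is None:
        # the structural modes decay on 1.8-2.5 nm but oscillate with an
        # 8-11 nm period, so the tails flatten to the 1e-3 gate only beyond
        # |X0| ~ 15 nm
        X0_values = np.arange(-20.0, 20.0 + SCAN_STEP / 2, SCAN_STEP)
    X0_values = np.asarray(X0_values, dtype=float)
    grid = grid or Grid()
    base = RegionLayout.bare_boundary(membrane, L=L)

    def W_at(X0: float) -> float:
        layout, cons = build_constraints(spec.at(X0), base)
        try:
            return solve_layout(layout, cons, grid=grid).W
        except Exception as exc:
            raise RuntimeError(f"inclusion scan failed at X0={X0:g} nm") from exc

    Ws = np.array([W_at(X0) for X0 in X0_values])

    if refine_step is not None and len(X0_values) > 2:
        # minima can be sharper than the scan step; densify locally so the
        # parabolic refinement sees the true well
        coarse = np.median(np.diff(X0_values))
        if refine_step < coarse:
            tmp = EnergyProfile(kind="inclusion_position",
                                abscissa=X0_values, W=Ws, L=L)
            for m in minima_analysis(tmp):
                if max(m.depth_vs_left, m.depth_vs_right,
                       m.depth_nearest) < 0.02:
                    continue
                lo, hi = m.position - coarse, m.position + coarse
                extra = np.arange(lo, hi + refine_step / 2, refine_step)
                extra = extra[(extra > X0_values[0]) & (extra < X0_values[-1])]
                mask = np.all(np.abs(extra[:, None] - X0_values[None, :])
                              > refine_step / 4, axis=1)
                extra = extra[mask]
                if len(extra):
                    X0_values = np.concatenate([X0_values, extra])
                    Ws = np.concatenate([Ws, [W_at(x) for x in extra]])
            order = np.argsort(X0_values)
            X0_values, Ws = X0_values[order], Ws[order]

    span = X0_values[-1] - X0_values[0]
    profile = EnergyProfile(kind="inclusion_position", abscissa=X0_values,
                            W=Ws, L=L, meta={"family": spec.family})
    tails = {"left": X0_values <= X0_values[0] + 0.1 * span,
             "right": X0_values >= X0_values[-1] - 0.1 * span}
    # flatness gate, scaled with the profile's dynamic range so that the
    # demand is comparable across landscapes of very different magnitude
    slope_tol = PLATEAU_SLOPE_TOL * max(1.0, float(Ws.max() - Ws.min()))
    for side, mask in tails.items():
        tail_x, tail_w = X0_values[mask], Ws[mask]
        slope = np.max(np.abs(np.diff(tail_w) / np.diff(tail_x)))
        if check_plateaus and slope > slope_tol:
            raise ValueError(
                f"{side} tail of the X0 scan is not flat "
                f"(max slope {slope:.2e} k_BT/nm^2): the scan range "
                "ends before the bulk plateau; widen it")
        setattr(profile, f"plateau_{side}", float(np.mean(tail_w)))
    minima_analysis(profile)
    return profile


def bulk_self_energy(
    spec: InclusionSpec,
    phase: MonolayerParameters,
    grid: Grid | None = None,
) -> float:
    """Self-energy of the inclusion deep inside a uniform bulk phase.

    Far from the domain boundary W(X0) separates into the bare-boundary
    energy plus this value.
    """
    layout, cons = build_constraints(spec.at(0.0), RegionLayout.uniform(phase))
    return solve_layout(layout, cons, grid=grid or Grid()).W


def line_tension_pN(W: float, kBT_joules: float = units.KBT_JOULES) -> float:
    """Convert an energy per unit length from k_B T/nm to pN."""
    if W < 0:
        raise ValueError("line tension must be non-negative")
    return units.kBT_per_nm_to_pN(W, kBT_joules)


def boltzmann_factor(delta_W_per_length: float, effective_length: float) -> float:
    """Lateral enrichment factor exp(dW * l_eff / k_B T).

    ``delta_W_per_length`` is an energy difference per unit boundary length
    (k_B T/nm) and ``effective_length`` the inclusion's effective lateral
    size along the boundary (nm).
    """
    if effective_length <= 0:
        raise ValueError("effective_length must be positive")
    return math.exp(delta_W_per_length * effective_length)
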