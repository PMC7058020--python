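"""Constrained minimization of the discrete elastic energy.

The energy functional is discretized on a uniform grid with the staggered
midpoint scheme of :mod:`raftedge.energy`: every grid interval contributes
``dx * density(midpoint)`` where first derivatives are first-order
differences across the interval and undifferentiated fields are nodal
averages.  Each contribution is a weighted square of an affine function of
the stacked unknowns (n_u, n_l, H_u, H_l, M at every retained node), so
the total energy is a sparse positive-semidefinite quadratic form.  The
minimizer under the linear equality constraints (far-field clamping,
gauge fixing, inclusion conditions) is the solution of the sparse KKT
stationarity system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .energy import DeformationField, interval_tables, node_index, total_energy
from .layout import RegionLayout

__all__ = [
    "Grid",
    "LinearConstraint",
    "QuadraticProblem",
    "EquilibriumResult",
    "assemble",
    "solve_equilibrium",
    "solve_layout",
    "refine_until_converged",
]

logger = logging.getLogger(__name__)

_FIELD_ID = {"n_u": 0, "n_l": 1, "H_u": 2, "H_l": 3, "M": 4}
_NFIELDS = 5


@dataclass(frozen=True)
class Grid:
    """Uniform finite-difference grid specification.

    ``half_width`` is the margin beyond the outermost structural feature of
    the layout; deformations decay on 1--3 nm, so the default 20 nm leaves
    many decay lengths of slack.  Converged production results need at
    least ~15 nm; small boxes are admitted for cheap cross-check problems.
    """

    dx: float = 0.025
    half_width: float = 20.0

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dx > 0.05 + 1e-12:
            raise ValueError("grid spacing must be in (0, 0.05] nm")
        if self.half_width < 2.0:
            raise ValueError("half_width below 2 nm cannot contain any decay tail")

    def nodes(self, layout: RegionLayout) -> np.ndarray:
        bps = layout.breakpoints()
        lo = min(bps) - self.half_width
        hi = max(bps) + self.half_width
        i0 = int(np.floor(lo / self.dx))
        i1 = int(np.ceil(hi / self.dx))
        return np.arange(i0, i1 + 1) * self.dx


@dataclass(frozen=True)
class LinearConstraint:
    """One linear equality on the unknown fields.

    ``terms`` is a tuple of ``(field, x, coeff, node_offset)``: the
    coefficient multiplies the field value at the grid node nearest to
    ``x`` shifted by ``node_offset`` nodes.  ``tag`` names the physical
    condition the row encodes.
    """

    terms: tuple[tuple[str, float, float, int], ...]
    rhs: float
    tag: str


@dataclass
class QuadraticProblem:
    """Discrete energy 1/2 u^T Q u + b^T u + c with equality constraints A u = d."""

    x: np.ndarray
    layout: RegionLayout
    Q: sp.csr_matrix
    b: np.ndarray
    c: float
    A: sp.csr_matrix
    d: np.ndarray
    tags: list[str]
    active: np.ndarray          # bool mask over the full 5*N unknown space
    reduced_index: np.ndarray   # full index -> reduced index (-1 if removed)

    @property
    def n_unknowns(self) -> int:
        return self.Q.shape[0]

    def energy_value(self, u: np.ndarray) -> float:
        return float(0.5 * u @ (self.Q @ u) + self.b @ u + self.c)


@dataclass
class EquilibriumResult:
    field: DeformationField
    W: float                    # k_B T/nm, from total_energy on the minimizer
    W_quadratic: float          # same, from the assembled quadratic form
    problem: QuadraticProblem
    diagnostics: dict = dfield(default_factory=dict)


def _removed_nodes(layout: RegionLayout, x: np.ndarray) -> set[tuple[int, int]]:
    """(field_id, node) pairs whose unknowns do not exist (excluded interiors)."""
    removed: set[tuple[int, int]] = set()
    dx = x[1] - x[0]
    for leaf, nf, hf in ((layout.upper, "n_u", "H_u"), (layout.lower, "n_l", "H_l")):
        for a, b in leaf.excluded_spans:
            if b - a < 2 * dx - 1e-12:
                raise ValueError(
                    f"excluded span [{a:g}, {b:g}] narrower than two grid cells "
                    f"(dx={dx:g} nm); refine the grid or widen the inclusion"
                )
            ia, ib = node_index(x, a), node_index(x, b)
            for i in range(ia + 1, ib):
                removed.add((_FIELD_ID[nf], i))
                removed.add((_FIELD_ID[hf], i))
    for a, b in layout.excluded_mid_spans:
        ia, ib = node_index(x, a), node_index(x, b)
        for i in range(ia + 1, ib):
            removed.add((_FIELD_ID["M"], i))
    return removed


def _default_constraints(layout: RegionLayout, x: np.ndarray) -> list[LinearConstraint]:
    """Far-field clamping at the box edges and the vertical gauge pin."""
    rows: list[LinearConstraint] = []
    for xe in (x[0], x[-1]):
        for f in ("n_u", "n_l"):
            rows.append(LinearConstraint(((f, xe, 1.0, 0),), 0.0, "far-field director"))
        pu = layout.upper.params_at(xe)
        pl = layout.lower.params_at(xe)
        rows.append(LinearConstraint(
            (("H_u", xe, 1.0, 0), ("M", xe, -1.0, 0)),
            pu.flat_thickness, "far-field thickness"))
        rows.append(LinearConstraint(
            (("M", xe, 1.0, 0), ("H_l", xe, -1.0, 0)),
            pl.flat_thickness, "far-field thickness"))
    rows.append(LinearConstraint((("M", x[0], 1.0, 0),), 0.0, "gauge"))
    return rows


def assemble(layout: RegionLayout, grid: Grid,
             constraints: tuple[LinearConstraint, ...] = ()) -> QuadraticProblem:
    """Discretize the renormalized energy as a constrained quadratic problem."""
    x = grid.nodes(layout)
    dx = grid.dx
    n_nodes = len(x)
    n_full = _NFIELDS * n_nodes

    removed = _removed_nodes(layout, x)
    active = np.ones(n_full, dtype=bool)
    for fid, i in removed:
        active[i * _NFIELDS + fid] = False
    reduced_index = np.full(n_full, -1, dtype=np.int64)
    reduced_index[active] = np.arange(int(active.sum()))

    ii = np.arange(n_nodes - 1)

    def gidx(fname: str, nodes: np.ndarray) -> np.ndarray:
        return nodes * _NFIELDS + _FIELD_ID[fname]

    rows_q: list[np.ndarray] = []
    cols_q: list[np.ndarray] = []
    vals_q: list[np.ndarray] = []
    b_full = np.zeros(n_full)
    c_total = 0.0

    def add_family(cols: np.ndarray, coefs: np.ndarray, r: np.ndarray,
                   w: np.ndarray) -> None:
        """Accumulate sum_i w_i (r_i + coefs_i . u[cols_i])^2."""
        nonlocal c_total
        # Q += 2 w a a^T   (outer products, vectorized over intervals)
        outer = 2.0 * w[:, None, None] * coefs[:, :, None] * coefs[:, None, :]
        k = cols.shape[1]
        rows_q.append(np.repeat(cols, k, axis=1).ravel())
        cols_q.append(np.tile(cols, (1, k)).ravel())
        vals_q.append(outer.reshape(len(w), -1).ravel())
        np.add.at(b_full, cols.ravel(), ((2.0 * w * r)[:, None] * coefs).ravel())
        c_total += float(np.sum(w * r**2))

    for leaflet, leaf, sl in (("upper", layout.upper, +1.0),
                              ("lower", layout.lower, -1.0)):
        tab, excluded = interval_tables(leaf, x)
        keep = ~excluded
        idx = ii[keep]
        m = len(idx)
        if m == 0:
            continue
        B, Kt, Ka = tab["B"][keep], tab["Kt"][keep], tab["Ka"][keep]
        J0, h, s0 = tab["J0"][keep], tab["h"][keep], tab["sigma0"][keep]
        a0 = tab["alpha0"][keep]
        nf = "n_u" if leaflet == "upper" else "n_l"
        hf = "H_u" if leaflet == "upper" else "H_l"
        n_i, n_j = gidx(nf, idx), gidx(nf, idx + 1)
        H_i, H_j = gidx(hf, idx), gidx(hf, idx + 1)
        M_i, M_j = gidx("M", idx), gidx("M", idx + 1)
        one = np.ones(m)

        # splay: (dn/dx + J0)^2, weight dx*B/2 -- renormalized by -B/2 J0^2
        add_family(np.stack([n_i, n_j], axis=1),
                   np.stack([-one / dx, one / dx], axis=1),
                   J0, 0.5 * dx * B)
        c_total -= float(np.sum(0.5 * dx * B * J0**2))
        # tilt: (nbar -/+ dH/dx)^2, weight dx*Kt/2
        add_family(np.stack([n_i, n_j, H_i, H_j], axis=1),
                   np.stack([0.5 * one, 0.5 * one,
                             sl * one / dx, -sl * one / dx], axis=1),
                   np.zeros(m), 0.5 * dx * Kt)
        # stretching: (alpha - alpha0)^2, weight dx*Ka/2
        add_family(np.stack([H_i, H_j, M_i, M_j, n_i, n_j], axis=1),
                   np.stack([-sl / (2 * h), -sl / (2 * h),
                             sl / (2 * h), sl / (2 * h),
                             h / (2 * dx), -h / (2 * dx)], axis=1),
                   1.0 - a0, 0.5 * dx * Ka)
        # lateral tension: (dH/dx)^2, weight dx*sigma0/2
        add_family(np.stack([H_i, H_j], axis=1),
                   np.stack([-one / dx, one / dx], axis=1),
                   np.zeros(m), 0.5 * dx * s0)

    Q_full = sp.coo_matrix(
        (np.concatenate(vals_q), (np.concatenate(rows_q), np.concatenate(cols_q))),
        shape=(n_full, n_full),
    ).tocsr()
    Q = Q_full[active][:, active]
    b = b_full[active]

    all_rows = list(_default_constraints(layout, x)) + list(constraints)
    a_rows, a_cols, a_vals, d, tags = [], [], [], [], []
    for r_i, con in enumerate(all_rows):
        for fname, xpos, coeff, off in con.terms:
            node = node_index(x, xpos) + off
            if not 0 <= node < n_nodes:
                raise ValueError(f"constraint {con.tag!r} references x={xpos} "
                                 "outside the box")
            g = node * _NFIELDS + _FIELD_ID[fname]
            rj = reduced_index[g]
            if rj < 0:
                raise ValueError(
                    f"constraint {con.tag!r} references the removed unknown "
                    f"{fname}@node {node}")
            a_rows.append(r_i)
            a_cols.append(rj)
            a_vals.append(coeff)
        d.append(con.rhs)
        tags.append(con.tag)
    A = sp.coo_matrix((a_vals, (a_rows, a_cols)),
                      shape=(len(all_rows), int(active.sum()))).tocsr()

    return QuadraticProblem(x=x, layout=layout, Q=Q, b=b, c=c_total,
                            A=A, d=np.array(d), tags=tags,
                            active=active, reduced_index=reduced_index)


def _field_from_vector(problem: QuadraticProblem, u: np.ndarray) -> DeformationField:
    full = np.full(len(problem.active), np.nan)
    full[problem.active] = u
    n_nodes = len(problem.x)
    comp = full.reshape(n_nodes, _NFIELDS)
    return DeformationField(x=problem.x, n_u=comp[:, 0], n_l=comp[:, 1],
                            H_u=comp[:, 2], H_l=comp[:, 3], M=comp[:, 4])


def solve_equilibrium(problem: QuadraticProblem,
                      residual_tol: float = 1e-8) -> EquilibriumResult:
    """Solve the KKT stationarity system of the constrained quadratic problem.

    Returns the unique constrained minimizer together with the energy W
    recomputed by :func:`raftedge.energy.total_energy` on the minimizer;
    the quadratic-form value is kept alongside as a cross-check (the two
    agree to well below 1e-6 k_B T/nm on a correct assembly).
    """
    n = problem.n_unknowns
    m = problem.A.shape[0]
    # the energy is invariant under a rigid vertical translation; make sure
    # some constraint (normally the gauge pin) removes that mode
    trans = np.zeros(len(problem.active))
    trans[2::_NFIELDS] = 1.0  # H_u
    trans[3::_NFIELDS] = 1.0  # H_l
    trans[4::_NFIELDS] = 1.0  # M
    trans = trans[problem.active]
    if np.linalg.norm(problem.A @ trans) < 1e-12:
        raise np.linalg.LinAlgError(
            "singular stationarity system: the global vertical translation "
            "(H_u, H_l, M shifted together) is an unconstrained rigid mode; "
            "add a gauge pin")
    K = sp.bmat([[problem.Q, problem.A.T], [problem.A, None]], format="csc")
    rhs = np.concatenate([-problem.b, problem.d])
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", spla.MatrixRankWarning)
            z = spla.spsolve(K, rhs)
    except (RuntimeError, spla.MatrixRankWarning) as exc:
        raise np.linalg.LinAlgError(
            "singular stationarity system: an unconstrained rigid mode remains "
            "(e.g. the global vertical translation; check the gauge pin)"
        ) from exc
    if not np.all(np.isfinite(z)):
        raise np.linalg.LinAlgError(
            "singular stationarity system: an unconstrained rigid mode remains "
            "(e.g. the global vertical translation; check the gauge pin)")
    resid = np.linalg.norm(K @ z - rhs)
    scale = np.linalg.norm(rhs)
    if scale > 0 and resid > residual_tol * scale:
        # iterative refinement fallback
        corr = spla.lsqr(K, rhs - K @ z, atol=1e-13, btol=1e-13)[0]
        z = z + corr
        resid = np.linalg.norm(K @ z - rhs)
        if resid > residual_tol * max(scale, 1.0):
            raise np.linalg.LinAlgError(
                f"KKT solve did not reach the residual tolerance "
                f"({resid:.2e} vs {residual_tol:.0e} * {scale:.2e})")
    u = z[:n]
    field = _field_from_vector(problem, u)
    W_quad = problem.energy_value(u)
    W = total_energy(field, problem.layout)
    if abs(W - W_quad) > 1e-6:
        logger.warning("energy cross-check mismatch: functional %.3e vs "
                       "quadratic form %.3e k_BT/nm", W, W_quad)
    return EquilibriumResult(field=field, W=W, W_quadratic=W_quad,
                             problem=problem,
                             diagnostics={"kkt_residual": float(resid),
                                          "n_unknowns": n,
                                          "n_constraints": m})


def solve_layout(layout: RegionLayout,
                 constraints: tuple[LinearConstraint, ...] = (),
                 grid: Grid | None = None) -> EquilibriumResult:
    """Assemble and solve in one step."""
    grid = grid or Grid()
    return solve_equilibrium(assemble(layout, grid, tuple(constraints)))


def refine_until_converged(layout: RegionLayout,
                           constraints: tuple[LinearConstraint, ...] = (),
                           rel_tol: float = 1e-3,
                           grid: Grid | None = None,
                           max_refinements: int = 6) -> EquilibriumResult:
    """Repeat the solve on finer and wider grids until W stabilizes.

    Starting from ``grid`` (default dx = 0.05 nm, half-width 15 nm), each
    level halves dx and adds 5 nm of half-width; the ladder stops when the
    relative change of W between consecutive levels drops below
    ``rel_tol``.  The convergence ladder is recorded in the diagnostics.
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    grid = grid or Grid(dx=0.05, half_width=15.0)
    ladder: list[dict] = []
    prev: EquilibriumResult | None = None
    for level in range(max_refinements + 1):
        g = Grid(dx=grid.dx / 2**level,
                 half_width=grid.half_width + 5.0 * level)
        res = solve_layout(layout, constraints, g)
        ladder.append({"dx": g.dx, "half_width": g.half_width, "W": res.W})
        if prev is not None:
            if abs(res.W - prev.W) <= rel_tol * abs(res.W) + 1e-9:
                res.diagnostics["ladder"] = ladder
                return res
        prev = res
    raise RuntimeError(
        f"energy did not converge to rel_tol={rel_tol:g} after "
        f"{max_refinements} refinements; ladder: {ladder}")
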