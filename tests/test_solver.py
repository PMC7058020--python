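import numpy as np
import pytest

from raftedge import (Grid, InclusionSpec, RegionLayout, build_constraints,
                      refine_until_converged, solve_equilibrium, solve_layout,
                      total_energy)
from raftedge.solver import assemble

# bare-boundary energy at L = 0 computed once on a dense grid
# (dx = 0.00625 nm, half-width 30 nm) -- frozen reference
W_L0_DENSE = 0.746445
# same for the equilibrium shift L = 3 nm
W_L3_DENSE = 0.278853


def small_random_layouts(membrane, rng, n=3):
    """Small solvable layouts exercising boundaries and stripes."""
    layouts = []
    for _ in range(n):
        kind = rng.integers(0, 2)
        if kind == 0:
            layouts.append((RegionLayout.bare_boundary(
                membrane, L=float(rng.uniform(-1.5, 1.5))), ()))
        else:
            spec = InclusionSpec(
                "lipid_stripe", X0=float(rng.uniform(-0.5, 0.5)), deltaL=1.3,
                h0=float(rng.uniform(1.3, 1.8)), B0=10.0,
                J0=float(rng.uniform(-0.25, 0.25)))
            layouts.append(build_constraints(
                spec, RegionLayout.bare_boundary(membrane, L=0.0)))
    return layouts


class TestSolve:
    def test_uniform_membrane_minimizer_is_the_ground_state(
            self, default_membrane, coarse_grid):
        res = solve_layout(RegionLayout.uniform(default_membrane.disordered),
                           grid=coarse_grid)
        assert res.W == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.field.n_u, 0.0, atol=1e-10)
        flat = default_membrane.disordered.flat_thickness
        np.testing.assert_allclose(res.field.H_u - res.field.M, flat,
                                   atol=1e-10)

    def test_bare_boundary_energy_matches_dense_reference(
            self, default_membrane, coarse_grid):
        for L, ref in ((0.0, W_L0_DENSE), (3.0, W_L3_DENSE)):
            res = solve_layout(RegionLayout.bare_boundary(default_membrane, L),
                               grid=coarse_grid)
            assert res.W == pytest.approx(ref, rel=5e-3)
        assert W_L0_DENSE > W_L3_DENSE  # the shifted boundary is cheaper

    def test_quadratic_form_equals_functional_on_solution(
            self, default_membrane, coarse_grid):
        res = solve_layout(RegionLayout.bare_boundary(default_membrane, 3.0),
                           grid=coarse_grid)
        assert abs(res.W - res.W_quadratic) < 1e-6

    def test_quadratic_form_equals_functional_on_random_vectors(
            self, default_membrane, tiny_grid, rng):
        """The assembled (Q, b, c) is the discrete functional, exactly."""
        layout = RegionLayout.bare_boundary(default_membrane, 0.5)
        problem = assemble(layout, tiny_grid)
        from raftedge.solver import _field_from_vector

        for _ in range(10):
            u = rng.normal(scale=0.05, size=problem.n_unknowns)
            field = _field_from_vector(problem, u)
            assert problem.energy_value(u) == pytest.approx(
                total_energy(field, layout, decay_tol=np.inf), abs=1e-9)

    def test_solution_is_a_constrained_minimum(self, default_membrane,
                                               tiny_grid, rng):
        """Brute-force optimality: random feasible perturbations only ever
        raise the energy (checked through the functional, not the solver)."""
        from scipy.linalg import null_space

        for layout, cons in small_random_layouts(default_membrane, rng):
            problem = assemble(layout, tiny_grid, tuple(cons))
            res = solve_equilibrium(problem)
            u_min = _vector_of(res)
            assert np.allclose(problem.A @ u_min, problem.d, atol=1e-8)
            Z = null_space(problem.A.toarray())
            W0 = problem.energy_value(u_min)
            for _ in range(20):
                v = Z @ rng.normal(size=Z.shape[1])
                v /= np.linalg.norm(v)
                for t in (1e-3, -1e-3, 0.1, -0.1):
                    assert problem.energy_value(u_min + t * v) >= W0 - 1e-10

    def test_finite_difference_hessian_oracle(self, default_membrane,
                                              tiny_grid):
        """Independent route: rebuild the Hessian and gradient of the energy
        purely from finite differences of total_energy and solve the dense
        KKT system; the sparse solver must land on the same energy."""
        spec = InclusionSpec("lipid_stripe", X0=0.0, deltaL=1.3, h0=1.55,
                             B0=10.0, J0=0.25)
        layout, cons = build_constraints(
            spec, RegionLayout.bare_boundary(default_membrane, L=0.0))
        problem = assemble(layout, tiny_grid, cons)
        res = solve_equilibrium(problem)

        n = problem.n_unknowns
        from raftedge.solver import _field_from_vector

        def f(u):
            return total_energy(_field_from_vector(problem, u), layout,
                                decay_tol=np.inf)

        eps = 1.0  # the energy is exactly quadratic: any step is exact
        e = np.eye(n)
        f0 = f(np.zeros(n))
        fi = np.array([f(eps * e[i]) for i in range(n)])
        g = np.empty(n)
        H = np.empty((n, n))
        for i in range(n):
            fmi = f(-eps * e[i])
            g[i] = (fi[i] - fmi) / (2 * eps)
            H[i, i] = (fi[i] - 2 * f0 + fmi) / eps**2
        for i in range(n):
            for j in range(i + 1, n):
                # only neighbouring unknowns interact; skip distant pairs
                if abs(i - j) > 12:
                    H[i, j] = H[j, i] = 0.0
                    continue
                fij = f(eps * (e[i] + e[j]))
                H[i, j] = H[j, i] = (fij - fi[i] - fi[j] + f0) / eps**2

        A = problem.A.toarray()
        m = A.shape[0]
        K = np.block([[H, A.T], [A, np.zeros((m, m))]])
        rhs = np.concatenate([-g, problem.d])
        z = np.linalg.solve(K, rhs)
        W_oracle = f(z[:n])
        assert res.W == pytest.approx(W_oracle, rel=5e-3)

    def test_minimizer_decays_into_the_box_edges(self, default_membrane):
        # With the lateral tension on, the soft bilayer-bending branch
        # leaves a tiny slow tail (decay length ~25 nm), so the director
        # amplitude in the outer 10% of the box is small but not zero.
        res = solve_layout(RegionLayout.bare_boundary(default_membrane, 3.0),
                           grid=Grid(dx=0.05, half_width=20.0))
        f = res.field
        outer = max(2, int(0.1 * len(f.x)))
        for arr in (f.n_u, f.n_l):
            peak = np.max(np.abs(arr))
            edge = max(np.max(np.abs(arr[:outer])),
                       np.max(np.abs(arr[-outer:])))
            assert edge < 1e-2 * peak

        # What matters for box adequacy is the energy: the renormalized
        # density of the discrete functional in the outer box is negligible.
        from raftedge.energy import interval_energy_densities

        layout = res.problem.layout
        for leaflet in ("upper", "lower"):
            _, dens, _ = interval_energy_densities(f, layout, leaflet)
            peak = np.max(np.abs(dens))
            edge = max(np.max(np.abs(dens[:outer])),
                       np.max(np.abs(dens[-outer:])))
            assert edge < 1e-5 * peak

    def test_enlarging_the_box_never_raises_the_energy(self, default_membrane):
        # Dirichlet clamping over-constrains: W decreases with half-width
        Ws = [solve_layout(RegionLayout.bare_boundary(default_membrane, 3.0),
                           grid=Grid(0.05, hw)).W for hw in (12.0, 16.0, 20.0)]
        assert Ws[0] >= Ws[1] - 1e-9 and Ws[1] >= Ws[2] - 1e-9

    def test_singular_system_without_gauge_is_reported(self, default_membrane,
                                                       coarse_grid):
        problem = assemble(RegionLayout.bare_boundary(default_membrane, 0.0),
                           coarse_grid)
        i = problem.tags.index("gauge")
        keep = [j for j in range(problem.A.shape[0]) if j != i]
        problem.A = problem.A[keep]
        problem.d = problem.d[keep]
        with pytest.raises(np.linalg.LinAlgError, match="rigid mode"):
            solve_equilibrium(problem)


class TestRefinement:
    def test_ladder_converges_for_the_bare_boundary(self, default_membrane):
        res = refine_until_converged(
            RegionLayout.bare_boundary(default_membrane, 3.0),
            rel_tol=1e-3, grid=Grid(dx=0.05, half_width=15.0))
        ladder = res.diagnostics["ladder"]
        assert len(ladder) >= 2
        assert res.W == pytest.approx(W_L3_DENSE, rel=1e-2)

    def test_trivial_case_stops_at_the_first_comparison(self, default_membrane):
        res = refine_until_converged(
            RegionLayout.uniform(default_membrane.disordered),
            grid=Grid(dx=0.05, half_width=10.0))
        assert len(res.diagnostics["ladder"]) == 2

    def test_nonpositive_tolerance_rejected(self, default_membrane):
        with pytest.raises(ValueError, match="rel_tol"):
            refine_until_converged(
                RegionLayout.uniform(default_membrane.disordered), rel_tol=0.0)


class TestValidation:
    def test_too_narrow_exclusion_rejected(self, default_membrane, coarse_grid):
        spec = InclusionSpec("transmembrane", X0=0.0, deltaL=0.08, h0=2.6)
        layout, cons = build_constraints(
            spec, RegionLayout.bare_boundary(default_membrane, 3.0))
        with pytest.raises(ValueError, match="narrower than two grid cells"):
            assemble(layout, coarse_grid, cons)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            Grid(dx=0.2)
        with pytest.raises(ValueError):
            Grid(dx=0.025, half_width=1.0)

    def test_constraint_outside_box_rejected(self, default_membrane,
                                             coarse_grid):
        from raftedge import LinearConstraint

        bad = LinearConstraint((("n_u", 500.0, 1.0, 0),), 0.0, "stray")
        with pytest.raises(ValueError, match="outside the simulation box"):
            assemble(RegionLayout.bare_boundary(default_membrane, 3.0),
                     coarse_grid, (bad,))


def _vector_of(res):
    """Recover the reduced unknown vector from a solved field."""
    problem = res.problem
    full = np.column_stack([res.field.n_u, res.field.n_l, res.field.H_u,
                            res.field.H_l, res.field.M]).ravel()
    return full[problem.active]
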