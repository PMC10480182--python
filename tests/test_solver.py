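"""Solver verification: assembly oracles, wall model, laminar benchmarks."""

import numpy as np
import pytest

from stenoflow import (
    FluidProperties,
    SolverSettings,
    assemble_transport_equation,
    build_geometry,
    compute_eddy_viscosity,
    compute_residuals,
    generate_mesh,
    solve_steady_rans,
)
from stenoflow.solver import (
    C_MU,
    KAPPA,
    LinearSystem,
    YPLUS_LAM,
    _green_gauss,
    _initial_field,
    _production,
    apply_wall_functions,
    wall_law_uplus,
)
from .conftest import BLOOD, laminar_settings, make_uniform_inlet


class TestEddyViscosity:
    def test_unit_case(self):
        fluid = FluidProperties(1.0, 1.0)
        assert compute_eddy_viscosity(1.0, 1.0, fluid) == pytest.approx(0.09)

    def test_zero_turbulence(self):
        assert compute_eddy_viscosity(0.0, 1.0, BLOOD) == 0.0

    def test_formula_oracle(self):
        k = 0.0016335
        eps = C_MU**0.75 * k**1.5 / 0.0014
        expected = 1060.0 * C_MU * k**2 / eps
        assert compute_eddy_viscosity(k, eps, BLOOD) == pytest.approx(expected, rel=1e-12)


class TestResiduals:
    def _random_system(self, rng, ni=5, nj=5):
        shape = (ni, nj)
        sys_ = LinearSystem(
            aP=rng.uniform(2, 3, shape),
            aE=rng.uniform(-1, 0, shape),
            aW=rng.uniform(-1, 0, shape),
            aN=rng.uniform(-1, 0, shape),
            aS=rng.uniform(-1, 0, shape),
            b=rng.normal(size=shape),
        )
        return sys_

    def test_exact_solution_zero_residual(self):
        rng = np.random.default_rng(7)
        sys_ = self._random_system(rng)
        x = sys_.solve()
        assert compute_residuals(sys_, x) < 1e-12

    def test_zero_iterate(self):
        rng = np.random.default_rng(8)
        sys_ = self._random_system(rng)
        # x = 0: residual |b| over scale |b|
        assert compute_residuals(sys_, np.zeros_like(sys_.b)) == pytest.approx(1.0)

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(9)
        sys_ = self._random_system(rng)
        x = rng.normal(size=sys_.b.shape)
        A = sys_.matrix().toarray()
        r = np.abs(A @ x.ravel() - sys_.b.ravel()).sum()
        scale = np.abs(sys_.aP.ravel() * x.ravel()).sum() + np.abs(sys_.b).sum()
        assert compute_residuals(sys_, x) == pytest.approx(r / scale, rel=1e-12)


class TestAssembly:
    def test_pure_diffusion_five_point_laplacian(self, straight_duct_mesh):
        """Zero velocity: the scalar equation reduces to the Laplacian stencil."""
        m = straight_duct_mesh
        inlet = make_uniform_inlet(m, 0.0)
        settings = SolverSettings(turbulence_enabled=True)
        flow = _initial_field(m, inlet, BLOOD, settings)
        flow.Fx[:] = 0.0
        flow.Fy[:] = 0.0
        sys_ = assemble_transport_equation("k", m, flow, BLOOD, settings, inlet)
        gamma = BLOOD.dynamic_viscosity + flow.mu_t[0, 0]  # uniform
        # square cells: D = gamma * A/d = gamma for all four faces
        i, j = 3, 4
        assert sys_.aE[i, j] == pytest.approx(-gamma, rel=1e-12)
        assert sys_.aW[i, j] == pytest.approx(-gamma, rel=1e-12)
        assert sys_.aN[i, j] == pytest.approx(-gamma, rel=1e-12)
        assert sys_.aS[i, j] == pytest.approx(-gamma, rel=1e-12)
        assert sys_.aP[i, j] == pytest.approx(4 * gamma, rel=1e-12)

    def test_first_order_upwind_uniform_flow(self, straight_duct_mesh):
        """Uniform velocity on a uniform grid: textbook upwind coefficients."""
        m = straight_duct_mesh
        u0 = 0.3
        inlet = make_uniform_inlet(m, u0, k0=1e-4, eps0=1e-4)
        settings = SolverSettings(
            turbulence_enabled=False, convection_scheme="first-order-upwind"
        )
        flow = _initial_field(m, inlet, BLOOD, settings)
        sys_ = assemble_transport_equation("k", m, flow, BLOOD, settings, inlet)
        dy = m.Y[0, 1] - m.Y[0, 0]
        D = BLOOD.dynamic_viscosity  # square cells: gamma*A/d = gamma
        F = BLOOD.density * u0 * dy
        i, j = 3, 4
        assert sys_.aW[i, j] == pytest.approx(-(D + F), rel=1e-12)
        assert sys_.aE[i, j] == pytest.approx(-D, rel=1e-12)
        assert sys_.aP[i, j] == pytest.approx(4 * D + F, rel=1e-12)

    def test_production_linear_shear(self, straight_duct_mesh):
        """P_k on U = gamma*y matches mu_t * gamma^2 (pure shear)."""
        m = straight_duct_mesh
        shear = 40.0
        inlet = make_uniform_inlet(m, 0.0)
        settings = SolverSettings()
        flow = _initial_field(m, inlet, BLOOD, settings)
        flow.U = shear * m.yc.copy()
        flow.V = np.zeros_like(flow.U)
        flow.mu_t = np.full_like(flow.U, 0.01)
        gu = _green_gauss(m, flow.U)  # zero-gradient BCs: interior exact
        gv = _green_gauss(m, flow.V)
        pk_std = _production(m, flow, gu, gv, kato_launder=False)
        pk_kl = _production(m, flow, gu, gv, kato_launder=True)
        interior = np.s_[2:-2, 2:-2]
        assert np.allclose(pk_std[interior], 0.01 * shear**2, rtol=1e-10)
        # for pure shear the Kato-Launder form coincides with the standard one
        assert np.allclose(pk_kl[interior], pk_std[interior], rtol=1e-10)


class TestWallModel:
    def test_wall_law_crossover(self):
        """Log-law and linear sublayer meet near y+ = 11 (within 5%)."""
        lin = 11.0
        logv = np.log(9.8 * 11.0) / KAPPA
        assert abs(lin - logv) / lin < 0.05
        assert wall_law_uplus(5.0) == 5.0
        assert wall_law_uplus(100.0) == pytest.approx(np.log(9.8 * 100.0) / KAPPA)

    def test_wall_quantities(self, straight_duct_mesh):
        m = straight_duct_mesh
        inlet = make_uniform_inlet(m, 0.66, k0=0.0016, eps0=0.05)
        settings = SolverSettings()
        flow = _initial_field(m, inlet, BLOOD, settings)
        wall = apply_wall_functions(m, flow, BLOOD)
        # imposed wall-cell dissipation matches the equilibrium closed form
        k = np.maximum(flow.k[:, -1], 1e-14)
        y = m.dist_wall_n
        expected = C_MU**0.75 * k**1.5 / (KAPPA * y)
        assert np.allclose(wall["epsN"], expected, rtol=1e-12)
        assert np.all(wall["tauN"] >= 0)

    def test_zero_velocity_zero_shear(self, straight_duct_mesh):
        m = straight_duct_mesh
        inlet = make_uniform_inlet(m, 0.0, k0=1e-4, eps0=1e-3)
        settings = SolverSettings()
        flow = _initial_field(m, inlet, BLOOD, settings)
        flow.U[:] = 0.0
        wall = apply_wall_functions(m, flow, BLOOD)
        assert np.allclose(wall["tauN"], 0.0)


class TestLaminarBenchmarks:
    def test_plane_poiseuille(self):
        """Developed planar channel flow: centreline/bulk = 3/2 within 2%."""
        D = 0.02
        g = build_geometry(D, 0.0, inlet_run=4, stenosis_length=4, outlet_run=4)
        m = generate_mesh(g, 96, 32, 1.1, "planar")
        u0 = 100.0 * BLOOD.kinematic_viscosity / D  # Re = 100
        inlet = make_uniform_inlet(m, u0)
        flow, rep = solve_steady_rans(m, inlet, BLOOD, laminar_settings())
        assert rep.converged
        i = int(0.92 * m.ni)
        ubulk = flow.Fx[i].sum() / (BLOOD.density * m.inlet_area)
        assert flow.U[i].max() / ubulk == pytest.approx(1.5, rel=0.02)

    def test_hagen_poiseuille(self):
        """Developed pipe flow: centreline/bulk = 2 within 2%."""
        D = 0.02
        g = build_geometry(D, 0.0, inlet_run=4, stenosis_length=4, outlet_run=4)
        m = generate_mesh(g, 96, 24, 1.1, "axisymmetric")
        u0 = 100.0 * BLOOD.kinematic_viscosity / D
        inlet = make_uniform_inlet(m, u0)
        flow, rep = solve_steady_rans(m, inlet, BLOOD, laminar_settings())
        assert rep.converged
        i = int(0.92 * m.ni)
        ubulk = flow.Fx[i].sum() / (BLOOD.density * m.inlet_area)
        assert flow.U[i].max() / ubulk == pytest.approx(2.0, rel=0.02)

    def test_mass_conservation_and_symmetry(self):
        """Converged duct flow conserves mass globally and is mirror-symmetric."""
        g = build_geometry(0.02, 0.0, inlet_run=2, stenosis_length=2, outlet_run=2)
        m = generate_mesh(g, 48, 16, 1.1, "planar")
        u0 = 100.0 * BLOOD.kinematic_viscosity / 0.02  # Re = 100
        inlet = make_uniform_inlet(m, u0)
        flow, rep = solve_steady_rans(
            m, inlet, BLOOD, laminar_settings(residual_tolerance=1e-7)
        )
        assert rep.converged
        m_in = flow.Fx[0].sum()
        assert abs(flow.Fx[-1].sum() - m_in) / m_in < 1e-6
        ubulk = m_in / (BLOOD.density * m.inlet_area)
        assert np.max(np.abs(flow.U - flow.U[:, ::-1])) < 1e-6 * ubulk


class TestTurbulentRun:
    def test_turbulent_duct_invariants(self):
        """k stays non-negative, eps floored, mu_t consistent, mass conserved."""
        g = build_geometry(0.02, 0.0, inlet_run=2, stenosis_length=2, outlet_run=4)
        m = generate_mesh(g, 48, 16, 1.15, "planar")
        from stenoflow import build_uniform_ti_inlet

        inlet = build_uniform_ti_inlet(0.66, 0.05, 0.0014, m)
        flow, rep = solve_steady_rans(m, inlet, BLOOD, SolverSettings())
        assert rep.converged
        assert np.all(flow.k >= 0)
        assert np.all(flow.eps >= 1e-12)
        m_in = flow.Fx[0].sum()
        assert abs(flow.Fx[-1].sum() - m_in) / m_in < 1e-6
        # mu_t is the relaxed eddy viscosity: consistent with k, eps up to
        # the final under-relaxation increment
        target = compute_eddy_viscosity(flow.k, flow.eps, BLOOD)
        target = np.minimum(target, 1e5 * BLOOD.dynamic_viscosity)
        assert np.median(np.abs(flow.mu_t - target) / (target + 1e-12)) < 0.05

    def test_determinism(self):
        g = build_geometry(0.02, 0.5, inlet_run=2, stenosis_length=2, outlet_run=4)
        m = generate_mesh(g, 48, 16, 1.15, "planar")
        from stenoflow import build_uniform_ti_inlet

        inlet = build_uniform_ti_inlet(0.66, 0.05, 0.0014, m)
        f1, r1 = solve_steady_rans(m, inlet, BLOOD, SolverSettings())
        f2, r2 = solve_steady_rans(m, inlet, BLOOD, SolverSettings())
        assert r1.iterations_used == r2.iterations_used
        assert np.array_equal(f1.U, f2.U)
        assert np.array_equal(f1.k, f2.k)

    def test_grid_refinement_consistency(self):
        """Throat peak velocity moves < 2% under a 1.5x refinement."""
        g = build_geometry(0.02, 0.5)
        from stenoflow import build_uniform_ti_inlet

        peaks = []
        for ni, nj in ((96, 20), (144, 30)):
            m = generate_mesh(g, ni, nj, 1.15, "axisymmetric")
            inlet = build_uniform_ti_inlet(0.66, 0.05, 0.0014, m)
            flow, rep = solve_steady_rans(m, inlet, BLOOD, SolverSettings())
            assert rep.converged
            i_apex = np.argmin(np.abs(m.axial_station - g.apex_station))
            peaks.append(flow.U[i_apex].max())
        assert abs(peaks[1] - peaks[0]) / peaks[0] < 0.02
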