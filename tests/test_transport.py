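"""Constant-field fluxes, network electrodiffusion, charge and currents."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import biovolt as bv
from biovolt.params import F, R, ParameterSet
from biovolt.operators import CellOperators, EnvOperators
from biovolt.transport import bernoulli

P = ParameterSet()


class TestGHKFlux:
    def test_zero_at_nernst_potential(self):
        for z, ci, co in ((1, 10.0, 100.0), (-1, 30.0, 105.0),
                          (2, 1e-4, 1.0)):
            Vn = R * P.T / (z * F) * np.log(co / ci)
            f = bv.ghk_flux(ci, co, Vn, 1e-18, z, P)
            scale = bv.ghk_flux(ci, co, Vn + 0.05, 1e-18, z, P)
            assert abs(f) < 1e-12 * abs(scale)

    def test_fickian_limit_at_zero_voltage(self):
        f = bv.ghk_flux(20.0, 10.0, 0.0, 7.5e-18, 1, P)
        assert f == pytest.approx((7.5e-18 / P.d_mem) * 10.0, rel=1e-12)
        # efflux positive when c_in > c_out
        assert f > 0

    def test_constant_field_quadrature_oracle(self):
        """Integrate the Nernst-Planck ODE across the membrane with a
        linear potential profile and shoot for the steady flux."""
        z, ci, co, V = 1, 10.0, 100.0, -0.05
        D = 1e-9 * P.d_mem  # P = 1 nm/s
        u = z * V * F / (R * P.T)
        d = P.d_mem

        def steady_flux(J):
            # c' = -J/D + (u/d) c, c(0)=ci; return c(d) - co
            sol = solve_ivp(lambda x, c: -J / D + (u / d) * c,
                            (0, d), [ci], rtol=1e-10, atol=1e-12)
            return sol.y[0, -1] - co

        from scipy.optimize import brentq
        J_oracle = brentq(steady_flux, -1e-4, 1e-4, xtol=1e-18)
        assert bv.ghk_flux(ci, co, V, D, z, P) == pytest.approx(
            J_oracle, rel=1e-5)

    @settings(deadline=None, max_examples=40)
    @given(ci=st.floats(0.01, 200), co=st.floats(0.01, 200),
           V=st.floats(-0.15, 0.15), z=st.sampled_from([-2, -1, 1, 2]))
    def test_antisymmetry(self, ci, co, V, z):
        """Swapping compartments and negating V negates the flux."""
        a = bv.ghk_flux(ci, co, V, 1e-18, z, P)
        b = bv.ghk_flux(co, ci, -V, 1e-18, z, P)
        assert a == pytest.approx(-b, rel=1e-9, abs=1e-30)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            bv.ghk_flux(-1.0, 10.0, 0.0, 1e-18, 1, P)


class TestNetworkFlux:
    def test_uniform_state_no_flux(self, hex7_world):
        ops = hex7_world.cell_ops
        c = np.full(ops.n_nodes, 5.0)
        V = np.full(ops.n_nodes, -0.05)
        f = bv.network_flux(c, V, np.full(ops.n_faces, 1e-15), ops, z=1,
                            T=P.T)
        assert np.allclose(f, 0.0)

    def test_pure_fickian_without_voltage(self, hex7_world):
        ops = hex7_world.cell_ops
        rng = np.random.default_rng(0)
        c = rng.uniform(1, 10, ops.n_nodes)
        f = bv.network_flux(c, np.zeros(ops.n_nodes), 1e-15, ops, z=1,
                            T=P.T)
        expect = -1e-15 * (c[ops.face_heads] - c[ops.face_tails]) \
            / ops.edge_lengths
        assert np.allclose(f, expect)

    def test_two_node_boltzmann_equilibrium(self):
        """Closed-form oracle: at fixed dV, concentrations relax to the
        Boltzmann ratio c1/c2 = exp(-zF dV/RT) with zero flux."""

        class TwoNode:
            n_nodes = 2
            n_faces = 1
            face_tails = np.array([0])
            face_heads = np.array([1])
            edge_lengths = np.array([1e-6])

        ops = TwoNode()
        z, dV = 1, -0.03
        V = np.array([0.0, dV])
        ratio_oracle = np.exp(-z * F * (V[1] - V[0]) / (R * P.T))
        # at exactly the Boltzmann ratio the flux vanishes
        c_eq = np.array([1.0, ratio_oracle])
        f = bv.network_flux(c_eq, V, np.array([1e-12]), ops, z=z, T=P.T)
        assert abs(f[0]) < 1e-18
        # and relaxation from a uniform start approaches that ratio
        c = np.array([1.0, 1.0])
        for _ in range(12000):
            f = bv.network_flux(c, V, np.array([1e-12]), ops, z=z, T=P.T)
            c += np.array([-f[0], f[0]]) * 1e-3 / 1e-6
        assert c[1] / c[0] == pytest.approx(ratio_oracle, rel=1e-4)

    def test_bernoulli_limits(self):
        assert bernoulli(0.0) == pytest.approx(1.0)
        assert bernoulli(1e-12) == pytest.approx(1.0, abs=1e-9)
        x = np.array([-3.0, 0.5, 8.0])
        assert np.allclose(bernoulli(x), x / np.expm1(x))


class TestUpdateConcentrations:
    def test_zero_fluxes_leave_state_unchanged(self, hex7_world):
        from biovolt.transport import FluxSet, update_concentrations
        s = bv.initial_state(hex7_world)
        before = s.c_cells.copy()
        n_ion = len(hex7_world.ions)
        g = hex7_world.cell_grid
        fx = FluxSet(phi_mem=np.zeros((n_ion, g.n_membranes)),
                     phi_gj=np.zeros((n_ion, g.n_gj)))
        update_concentrations(s, fx, 0.1, hex7_world)
        assert np.array_equal(s.c_cells, before)

    def test_constant_efflux_analytic_oracle(self, single_cell_world):
        """dc = -Phi * sigma * t / v for a constant membrane efflux."""
        from biovolt.transport import FluxSet, update_concentrations
        world = single_cell_world
        s = bv.initial_state(world)
        g = world.cell_grid
        n_ion = len(world.ions)
        phi = np.zeros((n_ion, g.n_membranes))
        phi[0, :] = 1e-7
        c0 = s.c_cells[0, 0]
        for _ in range(10):
            update_concentrations(s, FluxSet(phi_mem=phi), 0.1, world)
        expect = c0 - 1e-7 * g.cell_surface_areas[0] * 1.0 \
            / g.cell_volumes[0]
        assert s.c_cells[0, 0] == pytest.approx(expect, rel=1e-12)

    def test_membrane_transfer_conserves_total_moles(self, hex7_world):
        from biovolt.transport import FluxSet, update_concentrations
        world = hex7_world
        s = bv.initial_state(world)
        g = world.cell_grid
        n_ion = len(world.ions)
        rng = np.random.default_rng(0)
        phi = rng.normal(size=(n_ion, g.n_membranes)) * 1e-7
        tot0 = (s.c_cells @ g.cell_volumes
                + s.c_env @ world.env_node_volumes)
        update_concentrations(
            s, FluxSet(phi_mem=phi,
                       phi_env=np.zeros((n_ion, world.env_ops.n_faces))),
            0.05, world)
        tot1 = (s.c_cells @ g.cell_volumes
                + s.c_env @ world.env_node_volumes)
        assert np.allclose(tot1, tot0, rtol=1e-12)

    def test_invalid_dt_rejected(self, hex7_world):
        from biovolt.transport import FluxSet, update_concentrations
        s = bv.initial_state(hex7_world)
        with pytest.raises(ValueError, match="dt"):
            update_concentrations(s, FluxSet(phi_mem=np.zeros((1, 1))),
                                  0.0, hex7_world)


class TestChargeAndCurrent:
    def test_charge_density_values(self):
        ions = [bv.IonSpec("Na", 1), bv.IonSpec("Cl", -1),
                bv.IonSpec("Dye", -1, tracer=True)]
        c = np.array([[100.0], [100.0], [50.0]])
        assert bv.charge_density(c, ions)[0] == pytest.approx(0.0)
        c = np.array([[101.0], [100.0], [50.0]])  # 1 mM excess cation
        assert bv.charge_density(c, ions)[0] == pytest.approx(F, rel=1e-12)

    def test_charge_rate_identity(self, hex7_world):
        """Finite-difference oracle: d(rho)/dt equals F sum z_i times the
        per-ion concentration rate (Eq-8 structure)."""
        ions = [bv.IonSpec("Na", 1), bv.IonSpec("Cl", -1)]
        rng = np.random.default_rng(1)
        c0 = rng.uniform(50, 150, (2, 7))
        dcdt = rng.normal(size=(2, 7))
        dt = 1e-3
        drho = (bv.charge_density(c0 + dt * dcdt, ions)
                - bv.charge_density(c0, ions)) / dt
        assert np.allclose(drho, F * (np.array([1, -1]) @ dcdt), rtol=1e-9)

    def test_conductivity_values(self):
        assert bv.conductivity_from_diffusion(1e-9, [0.0], [1]) == 0.0
        sig = bv.conductivity_from_diffusion(
            1e-9, [5.38, 151.1, 34.7, 80.0], [1, 1, -1, -1], 310.0)
        assert 0.9 < sig < 1.1     # ~1 S/m for physiological cytosol
        double = bv.conductivity_from_diffusion(
            1e-9, [2 * 5.38, 2 * 151.1, 2 * 34.7, 2 * 160.0 / 2],
            [1, 1, -1, -1], 310.0)
        assert double > sig

    def test_conductivity_linearity(self):
        a = bv.conductivity_from_diffusion(1e-9, [10.0, 10.0], [1, -1])
        b = bv.conductivity_from_diffusion(1e-9, [20.0, 20.0], [1, -1])
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_corrected_current_continuity(self, disc_grid):
        """Residual oracle: div J + d(rho)/dt below 1e-8 of the max term."""
        ops = CellOperators(disc_grid[1])
        ions = [bv.IonSpec("Na", 1), bv.IonSpec("Cl", -1)]
        rng = np.random.default_rng(2)
        fluxes = rng.normal(size=(2, ops.n_faces)) * 1e-6
        vol = ops.grid.cell_volumes
        drho = rng.normal(size=ops.n_nodes)
        drho -= np.sum(drho * vol) / vol.sum()
        J, E = bv.corrected_current(fluxes, ions, ops, drho_dt=drho,
                                    gamma=0.02)
        resid = ops.divergence(J) + drho
        assert np.abs(resid).max() <= 1e-8 * np.abs(drho).max()
        assert np.allclose(E, 0.02 * J)

    def test_zero_flux_zero_current(self, disc_grid):
        ops = CellOperators(disc_grid[1])
        ions = [bv.IonSpec("Na", 1)]
        J, E = bv.corrected_current(np.zeros((1, ops.n_faces)), ions, ops)
        assert np.allclose(J, 0) and np.allclose(E, 0)
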