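"""Discrete gradient/divergence/Laplacian operators and projections."""

import numpy as np
import pytest

import biovolt as bv
from biovolt.operators import CellOperators, EnvOperators


@pytest.fixture(scope="module")
def env_ops():
    return EnvOperators(bv.build_env_grid((1.0, 1.0), 21, None))


@pytest.fixture(scope="module")
def cell_ops(disc_grid):
    return CellOperators(disc_grid[1])


def interior(ops):
    return np.setdiff1d(np.arange(ops.n_nodes), ops.grid.boundary_nodes)


class TestEnvOperators:
    def test_gradient_of_constant_is_zero(self, env_ops):
        assert np.allclose(env_ops.gradient(np.full(env_ops.n_nodes, 7.0)),
                           0.0)

    def test_gradient_exact_for_linear_field(self, env_ops):
        x = env_ops.grid.node_xy[:, 0]
        g = env_ops.gradient(3.0 * x)
        assert np.allclose(g[:env_ops.n_x_faces], 3.0, atol=1e-12)
        assert np.allclose(g[env_ops.n_x_faces:], 0.0, atol=1e-12)

    def test_divergence_of_radial_field_is_two(self, env_ops):
        xy = env_ops.grid.node_xy
        mid = 0.5 * (xy[env_ops.face_tails] + xy[env_ops.face_heads])
        F = np.concatenate([mid[:env_ops.n_x_faces, 0],
                            mid[env_ops.n_x_faces:, 1]])
        div = env_ops.divergence(F)
        assert np.allclose(div[interior(env_ops)], 2.0, atol=1e-10)

    def test_laplacian_is_div_grad(self, env_ops):
        x, y = env_ops.grid.node_xy.T
        f = np.sin(3 * x) * np.cos(2 * y)
        assert np.allclose(env_ops.laplacian(f),
                           env_ops.divergence(env_ops.gradient(f)))

    def test_gradient_convergence_under_refinement(self):
        """Richardson oracle: quadratic-field error halves with spacing."""
        errs = []
        for n in (11, 21):
            ops = EnvOperators(bv.build_env_grid((1.0, 1.0), n, None))
            x = ops.grid.node_xy[:, 0]
            g = ops.gradient(x ** 3)[:ops.n_x_faces]
            xm = 0.5 * (x[ops.face_tails[:ops.n_x_faces]]
                        + x[ops.face_heads[:ops.n_x_faces]])
            errs.append(np.abs(g - 3 * xm ** 2).max())
        assert errs[0] / errs[1] >= 1.9

    def test_poisson_residual(self, env_ops):
        rng = np.random.default_rng(1)
        rhs = np.zeros(env_ops.n_nodes)
        ii = interior(env_ops)
        rhs[ii] = rng.normal(size=len(ii))
        phi = env_ops.solve_poisson(rhs, bc="dirichlet0")
        res = env_ops.laplacian(phi) - rhs
        assert np.abs(res[ii]).max() <= 1e-8 * np.abs(rhs).max()
        assert np.allclose(phi[env_ops.grid.boundary_nodes], 0.0)

    def test_poisson_zero_rhs_gives_zero(self, env_ops):
        phi = env_ops.solve_poisson(np.zeros(env_ops.n_nodes))
        assert np.allclose(phi, 0.0)

    def test_poisson_mirror_symmetry(self, env_ops):
        """A mirror-symmetric source yields a mirror-symmetric potential."""
        n = env_ops.grid.nx
        rhs2d = np.zeros((n, n))
        rhs2d[5, 7] = rhs2d[5, n - 1 - 7] = 1.0
        phi = env_ops.solve_poisson(rhs2d.ravel()).reshape(n, n)
        assert np.allclose(phi, phi[:, ::-1], atol=1e-12)

    def test_neumann_needs_compatible_rhs(self, env_ops):
        with pytest.raises(ValueError, match="Neumann"):
            env_ops.solve_poisson(np.ones(env_ops.n_nodes), bc="neumann")
        x = env_ops.grid.node_xy[:, 0]
        rhs = np.sin(2 * np.pi * x)
        rhs -= rhs.mean()
        phi = env_ops.solve_poisson(rhs, bc="neumann")
        assert abs(phi.mean()) < 1e-12
        res = env_ops.laplacian(phi) - rhs
        assert np.abs(res).max() <= 1e-8 * np.abs(rhs).max()

    def test_projection_properties(self, env_ops):
        rng = np.random.default_rng(2)
        F = rng.normal(size=env_ops.n_faces)
        P1 = env_ops.project_divergence_free(F)
        ii = interior(env_ops)
        assert np.abs(env_ops.divergence(P1)[ii]).max() \
            <= 1e-8 * np.abs(env_ops.divergence(F)).max()
        # idempotent
        P2 = env_ops.project_divergence_free(P1)
        assert np.allclose(P1, P2, atol=1e-12 * np.abs(P1).max())
        # annihilates gradients of rim-vanishing potentials
        x, y = env_ops.grid.node_xy.T
        psi = np.sin(np.pi * x) * np.sin(np.pi * y)
        killed = env_ops.project_divergence_free(env_ops.gradient(psi))
        assert np.abs(killed).max() <= 1e-8 * np.abs(
            env_ops.gradient(psi)).max()
        # divergence-free input is a fixed point
        assert np.allclose(env_ops.project_divergence_free(P1), P1,
                           atol=1e-12 * np.abs(P1).max())

    def test_laplacian_symmetry(self, env_ops):
        L = env_ops.L.toarray()
        assert np.allclose(L, L.T)


class TestCellOperators:
    def test_constant_field_zero_gradient(self, cell_ops):
        assert np.allclose(cell_ops.gradient(
            np.full(cell_ops.n_nodes, 4.0)), 0.0)

    def test_divergence_theorem_per_cell(self, cell_ops):
        """Flux sum over faces equals volume-integrated divergence."""
        rng = np.random.default_rng(3)
        F = rng.normal(size=cell_ops.n_faces)
        div = cell_ops.divergence(F)
        g = cell_ops.grid
        total = np.zeros(g.n_cells)
        A = g.membrane_areas[g.gj_pairs[:, 0]]
        for e, (a, b) in enumerate(g.gj_cell_pairs):
            total[a] -= F[e] * A[e]
            total[b] += F[e] * A[e]
        assert np.allclose(div * g.cell_volumes, total, rtol=1e-12)

    def test_projection_idempotent_and_annihilates_gradients(self,
                                                             cell_ops):
        rng = np.random.default_rng(4)
        F = rng.normal(size=cell_ops.n_faces)
        P1 = cell_ops.project_divergence_free(F)
        P2 = cell_ops.project_divergence_free(P1)
        assert np.allclose(P1, P2, atol=1e-12 * np.abs(P1).max())
        assert np.abs(cell_ops.divergence(P1)).max() \
            <= 1e-8 * np.abs(cell_ops.divergence(F)).max()
        Fg = cell_ops.gradient(rng.normal(size=cell_ops.n_nodes))
        assert np.abs(cell_ops.project_divergence_free(Fg)).max() \
            <= 1e-8 * np.abs(Fg).max()

    def test_projection_with_source_term(self, cell_ops):
        """Continuity: div(J) = -source after correction."""
        rng = np.random.default_rng(5)
        F = rng.normal(size=cell_ops.n_faces)
        src = rng.normal(size=cell_ops.n_nodes)
        vol = cell_ops.grid.cell_volumes
        src -= np.sum(src * vol) / vol.sum()   # compatible source
        J = cell_ops.project_divergence_free(F, source=src)
        assert np.allclose(cell_ops.divergence(J), -src,
                           atol=1e-8 * np.abs(src).max())

    def test_dirichlet_rejected(self, cell_ops):
        with pytest.raises(ValueError):
            cell_ops.solve_poisson(np.zeros(cell_ops.n_nodes),
                                   bc="dirichlet0")

    def test_length_mismatch_rejected(self, cell_ops):
        with pytest.raises(ValueError, match="match"):
            cell_ops.gradient(np.zeros(cell_ops.n_nodes + 1))
        with pytest.raises(ValueError, match="match"):
            cell_ops.divergence(np.zeros(cell_ops.n_faces + 1))
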