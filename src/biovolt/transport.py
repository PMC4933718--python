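"""Passive mass flux, concentration updates, charge and current densities.

Sign convention: all *transmembrane* fluxes are positive **out of the
cell** (the constant-field flux expression below is positive for efflux at
V_mem -> 0 with c_in > c_out); the concentration update negates them for
the intracellular balance.  Network (gap-junction and environment) edge
fluxes are positive from the edge's first node to its second.

Charge density sums only non-tracer species (Eq: rho_e = F * sum_i z_i c_i)
and currents are built from the same species, then corrected to satisfy
the continuity equation with bulk electroneutrality via a divergence-free
projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import F, R, ParameterSet

__all__ = [
    "ghk_flux",
    "network_flux",
    "FluxSet",
    "update_concentrations",
    "charge_density",
    "conductivity_from_diffusion",
    "corrected_current",
]


@dataclass
class FluxSet:
    """One step's worth of fluxes, mol/(s m^2).

    ``phi_mem`` (n_ion, n_mem) transmembrane passive fluxes (positive out
    of the cell), ``phi_pump`` same shape for active transport,
    ``phi_gj`` (n_ion, n_gj) gap-junction edge fluxes (tail -> head),
    ``phi_env`` (n_ion, n_env_faces) or None in cytosol-only mode.
    Tracer rows never enter current computations.
    """

    phi_mem: np.ndarray
    phi_pump: np.ndarray | None = None
    phi_gj: np.ndarray | None = None
    phi_env: np.ndarray | None = None

    @property
    def membrane_total(self) -> np.ndarray:
        if self.phi_pump is None:
            return self.phi_mem
        return self.phi_mem + self.phi_pump


def update_concentrations(state, fluxes: FluxSet, dt: float, world):
    """Advance concentrations by one conservative finite-volume step.

    Cells change by the membrane-area-weighted flux sums over their
    membranes and gap junctions divided by cell volume; environment nodes
    receive the membrane effluxes through the conservative mapping plus
    the face-flux divergence.  Negative concentrations are clipped to
    zero with a warning.  Returns the mutated state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = world.cell_grid
    n_ion = state.c_cells.shape[0]
    eff = fluxes.membrane_total * g.membrane_areas
    for i in range(n_ion):
        out = np.bincount(g.membrane_to_cell, weights=eff[i],
                          minlength=g.n_cells)
        state.c_cells[i] -= dt * out / g.cell_volumes
    if fluxes.phi_gj is not None and g.n_gj:
        tails, heads = g.gj_cell_pairs[:, 0], g.gj_cell_pairs[:, 1]
        eA = fluxes.phi_gj * g.membrane_areas[g.gj_pairs[:, 0]]
        for i in range(n_ion):
            state.c_cells[i] += dt / g.cell_volumes * (
                np.bincount(heads, weights=eA[i], minlength=g.n_cells)
                - np.bincount(tails, weights=eA[i], minlength=g.n_cells))
    if fluxes.phi_env is not None:
        ops = world.env_ops
        n_env = world.env_grid.n_nodes
        for i in range(n_ion):
            gain = np.bincount(world.weights.node_of_membrane,
                               weights=eff[i], minlength=n_env)
            eA = fluxes.phi_env[i] * world.env_face_area
            gain += np.bincount(ops.face_heads, weights=eA,
                                minlength=n_env) \
                - np.bincount(ops.face_tails, weights=eA, minlength=n_env)
            state.c_env[i] += dt * gain / world.env_node_volumes
    for arr in (state.c_cells, state.c_env):
        if (arr < 0).any():
            warnings.warn("clipped negative concentration",
                          RuntimeWarning, stacklevel=2)
            np.clip(arr, 0.0, None, out=arr)
    return state


def ghk_flux(c_in, c_out, V_mem, D_mem, z, params: ParameterSet):
    """Goldman–Hodgkin–Katz (constant-field) transmembrane flux, mol/(s m^2).

    Positive = out of the cell.  At the ion's Nernst potential the flux is
    exactly zero; as ``V_mem -> 0`` the expression reduces to the Fickian
    limit ``P (c_in - c_out)`` with ``P = D_mem / d_mem``.
    """
    c_in = np.asarray(c_in, dtype=float)
    c_out = np.asarray(c_out, dtype=float)
    V_mem = np.asarray(V_mem, dtype=float)
    if (c_in < 0).any() or (c_out < 0).any():
        raise ValueError("negative concentration in ghk_flux")
    P = np.asarray(D_mem, dtype=float) / params.d_mem
    u = z * V_mem * F / (R * params.T)  # dimensionless voltage
    small = np.abs(u) < 1e-6
    us = np.where(small, 1.0, u)
    # u * (c_in - c_out * exp(-u)) / (1 - exp(-u)), stable via expm1;
    # first-order series below the cancellation threshold
    em = -np.expm1(-us)
    flux = P * us * (c_in - c_out * np.exp(-us)) / em
    series = P * ((c_in - c_out) + 0.5 * u * (c_in + c_out))
    return np.where(small, series, flux)


def bernoulli(x):
    """B(x) = x / (e^x - 1), with the limit 1 at x -> 0 (stable)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-9
    xs = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x / 2.0, xs / np.expm1(xs))


def network_flux(c, V, D_edge, grid_ops, u_flow=None, z: int = 0,
                 T: float = 310.0, edge_length=None):
    """Electrodiffusion-advection flux along network edges, mol/(s m^2).

    ``c`` and ``V`` are per-node fields; ``D_edge`` the per-edge
    diffusivity.  The diffusion-drift part uses the exponential-fitting
    (Scharfetter-Gummel / constant-field) face flux

        Phi = (D/L) [B(u) c_tail - B(-u) c_head],  u = z F dV / (R T),

    which is positivity-preserving, reduces to the Fickian difference at
    dV -> 0, and vanishes exactly at the Boltzmann concentration ratio.
    The advective term uses the upwind concentration.  ``edge_length``
    overrides the geometric edge length for the difference quotients (gap
    junctions use the intercellular spacing d_gj rather than the
    centre-to-centre distance).
    """
    c = np.asarray(c, dtype=float)
    V = np.asarray(V, dtype=float)
    D_edge = np.asarray(D_edge, dtype=float)
    if (D_edge < 0).any():
        raise ValueError("negative edge diffusivity")
    tails, heads = grid_ops.face_tails, grid_ops.face_heads
    if len(c) != grid_ops.n_nodes:
        raise ValueError("field length does not match grid")
    if edge_length is None:
        edge_length = grid_ops.edge_lengths
    u = z * F / (R * T) * (V[heads] - V[tails])
    flux = D_edge / edge_length * (bernoulli(u) * c[tails]
                                   - bernoulli(-u) * c[heads])
    if u_flow is not None:
        u_flow = np.asarray(u_flow, dtype=float)
        c_up = np.where(u_flow >= 0, c[tails], c[heads])
        flux = flux + u_flow * c_up
    return flux


def charge_density(c, ions):
    """Net ionic charge density rho_e = F sum_i z_i c_i, C/m^3.

    ``c`` has shape (n_ion, n_region); tracer species are excluded.
    """
    c = np.asarray(c, dtype=float)
    z = np.array([0 if ion.tracer else ion.z for ion in ions], dtype=float)
    return F * (z @ c)


def conductivity_from_diffusion(D, c, z, T: float = 310.0):
    """Electrolyte conductivity sigma = sum_i F^2 z_i^2 D_i c_i / (R T), S/m."""
    D = np.atleast_1d(np.asarray(D, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if (c < 0).any():
        raise ValueError("negative concentration")
    return float(np.sum(F ** 2 * z ** 2 * D * c) / (R * T))


def corrected_current(edge_fluxes, ions, grid_ops, drho_dt=None,
                      gamma: float = 0.02):
    """Net ionic current density on a network, continuity-corrected.

    ``edge_fluxes`` has shape (n_ion, n_edges), per-edge mass flux (mol/(s
    m^2)).  The base current J_o = F sum_i z_i Phi_i is corrected by
    subtracting the gradient of an internal screening potential so that
    ``div J + drho_dt = 0`` holds to solver tolerance.  Returns
    ``(J_edges, E_edges)`` with the mesoscopic field E = gamma * J.
    """
    edge_fluxes = np.asarray(edge_fluxes, dtype=float)
    z = np.array([0 if ion.tracer else ion.z for ion in ions], dtype=float)
    J_o = F * (z @ edge_fluxes)
    J = grid_ops.project_divergence_free(J_o, source=drho_dt)
    return J, gamma * J
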