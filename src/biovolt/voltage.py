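"""Voltages from net regional charges.

Electrolytes screen static charge over a Debye length, so intra- and
extracellular voltages are computed not from a bath Poisson solve but from
a *Maxwell capacitance matrix* over the set of conductive spaces: every
cell, and every internal environment node (the discrete extracellular
cleft regions inside the cluster).  Each membrane contributes a mutual
capacitance c_mem * A_mem between its cell and its local extracellular
conductor (or ground, when the membrane faces the external environment),
and each conductor carries an electrolyte self-capacitance
c_self * (bounding surface area) that ties it to the grounded bath.

``V = M^+ Q`` with the pseudo-inverse computed by SVD.  The simplified
"cytosol only" mode instead treats each cell as an isolated capacitor:
``V_mem = Q_cell / (c_mem * sigma_cell)`` with a well-mixed environment at
V = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CellGrid, EnvGrid, MappingWeights
from .params import EPS0, EPS_R_WATER, F, R, ParameterSet

__all__ = [
    "debye_kappa",
    "self_capacitance",
    "CapacitanceSystem",
    "assemble_capacitance_matrix",
    "solve_voltages",
    "vmem_from_voltages",
    "vmem_cytosol_only",
]


def debye_kappa(C_tot: float, params: ParameterSet,
                eps_r: float = EPS_R_WATER) -> float:
    """Inverse Debye length of a symmetric monovalent electrolyte, 1/m.

    kappa = sqrt(2 F^2 C_tot / (eps_r eps_o R T)); ~1.2e9 1/m for a
    150 mol/m^3 electrolyte at 310 K.
    """
    if C_tot < 0:
        raise ValueError("C_tot must be non-negative")
    return float(np.sqrt(2.0 * F ** 2 * C_tot
                         / (eps_r * EPS0 * R * params.T)))


def self_capacitance(kappa: float, eps_r: float = EPS_R_WATER) -> float:
    """Electrolyte screening self-capacitance per unit area, F/m^2.

    The integrated double-layer charge per unit surface voltage:
    c_self = eps_o eps_r kappa (~0.86 F/m^2 at physiological strength).
    """
    return EPS0 * eps_r * kappa


@dataclass
class CapacitanceSystem:
    """Assembled Maxwell capacitance system.

    Conductors are ordered cells first, then internal environment nodes.
    ``M`` is symmetric with non-positive off-diagonals; each row sum equals
    that conductor's self-capacitance plus any membrane coupling to the
    grounded exterior.
    """

    M: np.ndarray                  # (n_cond, n_cond), F
    M_inv: np.ndarray              # pseudo-inverse
    n_cells: int
    internal_nodes: np.ndarray     # env node index per env conductor
    env_conductor_of_node: np.ndarray  # (n_env_nodes,) -> conductor or -1

    @property
    def n_conductors(self) -> int:
        return len(self.M)


def assemble_capacitance_matrix(cell_grid: CellGrid, env_grid: EnvGrid,
                                weights: MappingWeights,
                                params: ParameterSet) -> CapacitanceSystem:
    """Build M over cells + internal environment nodes.

    Membrane m of cell k couples C = c_mem * A_m to the conductor of its
    nearest environment node; if that node is external the coupling goes to
    ground and only the diagonal term remains.  Self-capacitance uses the
    conductor's bounding surface: total membrane area for cells, total
    mapped membrane area (cleft walls) for internal nodes.
    """
    internal = np.flatnonzero(env_grid.inside_mask)
    if params.mode == "environment" and len(internal) == 0 \
            and cell_grid.n_cells > 1:
        raise ValueError("environment mode requires extracellular regions "
                         "(no internal environment nodes found)")
    n_cell = cell_grid.n_cells
    env_cond = np.full(env_grid.n_nodes, -1, dtype=int)
    env_cond[internal] = n_cell + np.arange(len(internal))
    n_cond = n_cell + len(internal)
    M = np.zeros((n_cond, n_cond))

    mem_cell = cell_grid.membrane_to_cell
    mem_node = weights.node_of_membrane
    mem_cond = env_cond[mem_node]          # -1 => grounded exterior
    C = params.c_mem * cell_grid.membrane_areas
    np.add.at(M, (mem_cell, mem_cell), C)
    int_sel = mem_cond >= 0
    np.add.at(M, (mem_cond[int_sel], mem_cond[int_sel]), C[int_sel])
    np.add.at(M, (mem_cell[int_sel], mem_cond[int_sel]), -C[int_sel])
    np.add.at(M, (mem_cond[int_sel], mem_cell[int_sel]), -C[int_sel])

    # electrolyte self-capacitance on every conductor diagonal
    cell_surface = cell_grid.cell_surface_areas
    M[np.arange(n_cell), np.arange(n_cell)] += params.c_self * cell_surface
    node_mem_area = np.zeros(env_grid.n_nodes)
    np.add.at(node_mem_area, mem_node, cell_grid.membrane_areas)
    floor = 2.0 * env_grid.spacing * cell_grid.h
    area_int = np.maximum(node_mem_area[internal], floor)
    M[n_cell + np.arange(len(internal)),
      n_cell + np.arange(len(internal))] += params.c_self * area_int

    M_inv = np.linalg.pinv(M, rcond=1e-12)
    return CapacitanceSystem(M=M, M_inv=M_inv, n_cells=n_cell,
                             internal_nodes=internal,
                             env_conductor_of_node=env_cond)


def solve_voltages(system: CapacitanceSystem, Q: np.ndarray) -> np.ndarray:
    """V = M_inv Q for the conductor charges Q (C)."""
    Q = np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError("charges must be finite")
    return system.M_inv @ Q


def vmem_from_voltages(V_cell, V_env_local):
    """V_mem per membrane: intracellular minus local extracellular voltage."""
    return np.asarray(V_cell, dtype=float) - np.asarray(V_env_local,
                                                        dtype=float)


def vmem_cytosol_only(Q_cell, cell_grid: CellGrid, params: ParameterSet):
    """Simple-capacitor V_mem = Q_cell / (c_mem * sigma_cell), per cell."""
    return np.asarray(Q_cell, dtype=float) / (
        params.c_mem * cell_grid.cell_surface_areas)
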