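"""Time-stepping engine coordinating geometry, transport, voltages and
membrane dynamics.

Each step applies an operator-split sequence:

1. refresh intervention modifiers for the current time;
2. update channel gates, gap-junction gates and dynamic membrane
   diffusivities from the current voltages/concentrations;
3. compute the flux set: constant-field transmembrane fluxes, pump
   fluxes, gap-junction electrodiffusion, and (environment mode)
   extracellular electrodiffusion with tight-junction scaling;
4. update concentrations (finite volume, conservative membrane <->
   environment mole transfer, Dirichlet boundary re-imposed);
5. recompute charge densities and regional charges;
6. solve voltages (Maxwell capacitance matrix, or the cytosol-only
   single-capacitor relation) and apply any voltage clamps;
7. optionally update electroosmotic flow for the next step's advection.

Currents and fields are diagnostics computed on demand (`compute_fields`),
not every step.

Two simulation modes: ``cytosol_only`` assumes an instantaneously mixed
environment at V = 0 (extracellular concentrations fixed at bath values,
unless a boundary intervention changes the bath), while ``environment``
models discrete extracellular spaces and bulk electrodiffusion on the
environment grid.

Environment voltages: bulk electrolyte screens static charge within a
Debye length, so the extracellular network cannot sustain net charge —
electroneutrality plus current continuity make its potential
*quasi-static*.  Each step therefore solves an Ohmic conduction problem
on the environment grid (face conductances from local electrolyte
composition, scaled by beta_TJ across the cluster boundary, grounded at
the global boundary) driven by the membrane charge injections and
diffusive charge currents.  Tight junctions then produce an
inside-positive transepithelial potential as the voltage needed to push
the steady transcellular current loop through the high-resistance
boundary ring.  Membranes remain capacitive: V_mem follows from each
cell's net charge and V_cell = V_mem + local extracellular potential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import transport
from .electroosmosis import eo_body_force, eo_velocity
from .geometry import (CellGrid, EnvGrid, MappingWeights, RegionMask,
                       build_env_grid, cut_region, map_membranes_to_env)
from .membranes import (GJGate, PumpModel, gj_gate_update, hh_channel_update,
                        ligand_gated_permeability, make_channel,
                        nak_pump_rate)
from .operators import CellOperators, EnvOperators
from .params import F, R, ParameterSet
from .state import (InterventionSchedule, IonSpec, Profile, TissueState,
                    apply_interventions, init_state,
                    membrane_diffusivity_base)
from .voltage import (CapacitanceSystem, assemble_capacitance_matrix,
                      solve_voltages, vmem_cytosol_only, vmem_from_voltages)

__all__ = ["World", "SimResult", "EngineInstability", "build_world",
           "step", "run", "wound", "compute_fields"]


class EngineInstability(RuntimeError):
    """Raised when the explicit update detects numerical blow-up."""


@dataclass
class _LigandChannel:
    target_ion: int       # index of the gated ion
    ligand_ion: int       # index of the gating species
    D_max: float
    K_half: float
    hill: float
    extracellular: bool   # gate senses extracellular vs cytosolic ligand
    mem_idx: np.ndarray


@dataclass
class World:
    """Static description of one simulated tissue (geometry + models)."""

    cell_grid: CellGrid
    env_grid: EnvGrid
    weights: MappingWeights
    cell_ops: CellOperators
    env_ops: EnvOperators
    params: ParameterSet
    ions: list
    profiles: list
    D_mem_base: np.ndarray            # (n_ion, n_mem)
    pump: PumpModel
    pump_scale_mem: np.ndarray        # (n_mem,)
    channels: list = field(default_factory=list)   # (model, mem_idx)
    ligand_channels: list = field(default_factory=list)
    gj_gate: GJGate = field(default_factory=GJGate)
    schedule: InterventionSchedule = field(
        default_factory=InterventionSchedule)
    cap: CapacitanceSystem | None = None
    c_bath: np.ndarray | None = None  # charge-balanced bath concentrations
    env_face_scale: np.ndarray | None = None
    env_face_area: np.ndarray | None = None
    env_node_volumes: np.ndarray | None = None
    env_node_capacitance: np.ndarray | None = None

    @property
    def ion_index(self) -> dict:
        return {ion.name: i for i, ion in enumerate(self.ions)}


def _env_network_geometry(world: World) -> None:
    """Face conduction areas/scalings and node electrolyte volumes.

    Extracellular regions carry full grid-cell electrolyte volumes
    (the model assigns extracellular volumes comparable to cell volumes,
    v_ecm ~ 7.85e-16 m^3, rather than literal nm-scale cleft volumes);
    faces crossing the cluster boundary are scaled by beta_TJ when tight
    junctions are enabled.  Node screening capacitance is set by the
    membrane area each node serves.
    """
    p = world.params
    g = world.env_grid
    ops = world.env_ops
    inside = g.inside_mask
    t_in = inside[ops.face_tails]
    h_in = inside[ops.face_heads]
    # transport between extracellular regions inside the cluster threads
    # the thin paracellular clefts: open fraction d_ecm / (2 r_cell)
    r_cell = float(np.sqrt(np.mean(world.cell_grid.cell_areas) / np.pi)) \
        if world.cell_grid.n_cells else 1e-5
    phi_cleft = min(1.0, p.d_ecm / (2.0 * r_cell))
    area = np.full(ops.n_faces, g.spacing * p.h)
    area[t_in & h_in] *= phi_cleft
    crossing = t_in != h_in
    area[crossing] *= phi_cleft
    scale = np.ones(ops.n_faces)
    if p.tj_enabled:
        scale[crossing] = p.beta_tj
    vol = np.full(g.n_nodes, g.spacing ** 2 * p.h)
    mem_area_per_node = np.zeros(g.n_nodes)
    np.add.at(mem_area_per_node, world.weights.node_of_membrane,
              world.cell_grid.membrane_areas)
    world.env_face_scale = scale
    world.env_face_area = area
    world.env_node_volumes = vol
    cap_node = np.zeros(g.n_nodes)
    floor_a = 2.0 * g.spacing * p.h
    cap_node[inside] = p.c_self * np.maximum(mem_area_per_node[inside],
                                             floor_a)
    world.env_node_capacitance = cap_node


def build_world(cell_grid: CellGrid, ions: list, profiles: list,
                params: ParameterSet,
                schedule: InterventionSchedule | None = None,
                env_grid: EnvGrid | None = None,
                env_nodes_per_side: int = 30,
                pump: PumpModel | None = None,
                gj_gate: GJGate | None = None) -> World:
    """Assemble the static world: grids, operators, membrane models."""
    if env_grid is None:
        env_grid = build_env_grid(cell_grid.world_extent,
                                  env_nodes_per_side, cell_grid)
    weights = map_membranes_to_env(cell_grid, env_grid)
    world = World(
        cell_grid=cell_grid,
        env_grid=env_grid,
        weights=weights,
        cell_ops=CellOperators(cell_grid),
        env_ops=EnvOperators(env_grid),
        params=params,
        ions=list(ions),
        profiles=list(profiles),
        D_mem_base=membrane_diffusivity_base(cell_grid, ions, profiles,
                                             params),
        pump=pump or PumpModel(alpha_o=params.alpha_pump),
        pump_scale_mem=np.zeros(cell_grid.n_membranes),
        schedule=schedule or InterventionSchedule(),
        gj_gate=gj_gate or GJGate(v_half=params.gj_vhalf,
                                  k_slope=params.gj_kslope,
                                  beta_min=params.gj_beta_min,
                                  tau=params.gj_tau),
    )
    ion_index = world.ion_index
    for prof in profiles:
        mem_sel = np.isin(cell_grid.membrane_to_cell,
                          np.asarray(prof.cells, dtype=int))
        world.pump_scale_mem[mem_sel] = prof.pump_scale
        for ch in prof.channels:
            mem_idx = np.flatnonzero(mem_sel)
            if ch.get("kind") in ("ligand_gated", "calcium_gated"):
                world.ligand_channels.append(_LigandChannel(
                    target_ion=ion_index[ch["ion"]],
                    ligand_ion=ion_index[ch["ligand"]],
                    D_max=ch["P_max"] * params.d_mem,
                    K_half=ch["K_half"],
                    hill=ch.get("hill", 1.0),
                    extracellular=(ch.get("kind") != "calcium_gated"
                                   and ch.get("extracellular", True)),
                    mem_idx=mem_idx))
            else:
                model = make_channel(ch["kind"],
                                     D_max=ch["P_max"] * params.d_mem)
                model.name = f"{prof.label}:{ch['kind']}:{len(world.channels)}"
                world.channels.append((model, mem_idx))
    from .state import balanced_concentrations
    world.c_bath = balanced_concentrations(world.ions)[1]
    _env_network_geometry(world)
    return world


def capacitance_system(world: World) -> CapacitanceSystem:
    """Maxwell capacitance system of the world (assembled on demand).

    The engine's environment mode resolves extracellular potentials
    quasi-statically (see module docstring); the full capacitance system
    over cells and internal environment nodes remains available for
    electrostatic analyses and cross-checks.
    """
    if world.cap is None:
        world.cap = assemble_capacitance_matrix(
            world.cell_grid, world.env_grid, world.weights, world.params)
    return world.cap


def initial_state(world: World, channels_active: bool = True) -> TissueState:
    s = init_state(world.cell_grid, world.env_grid, world.ions,
                   world.profiles, world.params)
    _init_gates(world, s)
    _solve_state_voltages(world, s)
    if channels_active:
        for model, mem_idx in world.channels:
            mem_cells = world.cell_grid.membrane_to_cell[mem_idx]
            s.gates[model.name] = model.steady_gates(s.V_mem[mem_idx])
    return s


def _init_gates(world: World, s: TissueState) -> None:
    for model, mem_idx in world.channels:
        s.gates[model.name] = model.steady_gates(s.V_mem[mem_idx])


# ---------------------------------------------------------------------------
# single step

def _dynamic_membrane_D(world: World, s: TissueState,
                        dt: float, update_gates: bool) -> np.ndarray:
    """D_mem (n_ion, n_mem): baseline x intervention scaling + channels."""
    g = world.cell_grid
    D = world.D_mem_base * s.perm_scale[:, g.membrane_to_cell]
    idx = world.ion_index
    for model, mem_idx in world.channels:
        gates = s.gates[model.name]
        if update_gates:
            gates, contrib = hh_channel_update(s.V_mem[mem_idx], gates, dt,
                                               model)
            s.gates[model.name] = gates
        else:
            contrib = model.D_max * model.open_fraction(gates)
        D[idx[model.ion], mem_idx] += contrib
    for lc in world.ligand_channels:
        if lc.extracellular:
            c_lig = s.c_env[lc.ligand_ion][
                world.weights.node_of_membrane[lc.mem_idx]]
        else:
            c_lig = s.c_cells[lc.ligand_ion][
                g.membrane_to_cell[lc.mem_idx]]
        D[lc.target_ion, lc.mem_idx] += ligand_gated_permeability(
            c_lig, lc.D_max, lc.K_half, lc.hill)
    return D


def _voltages_from_charge(world: World, s: TissueState) -> None:
    p = world.params
    g = world.cell_grid
    rho_cells = transport.charge_density(s.c_cells, world.ions)
    Q_cell = rho_cells * g.cell_volumes
    if s.Q_inj is not None:
        Q_cell = Q_cell + s.Q_inj
    if p.mode == "cytosol_only":
        vm = vmem_cytosol_only(Q_cell, g, p)
        s.V_cell = vm.copy()
        s.V_env = np.zeros(world.env_grid.n_nodes)
        s.V_mem = vm[g.membrane_to_cell]
    else:
        # quasi-static environment potential (solved in the flux stage);
        # each cell is a capacitor against its local extracellular
        # potential: c_mem sum_m A_m (V_cell - V_env_m) = Q_cell
        V_env_local = s.V_env[world.weights.node_of_membrane]
        sumAV = np.bincount(g.membrane_to_cell,
                            weights=g.membrane_areas * V_env_local,
                            minlength=g.n_cells)
        s.V_cell = (Q_cell / p.c_mem + sumAV) / g.cell_surface_areas
        s.V_mem = vmem_from_voltages(s.V_cell[g.membrane_to_cell],
                                     V_env_local)


def _solve_state_voltages(world: World, s: TissueState) -> None:
    p = world.params
    g = world.cell_grid
    _voltages_from_charge(world, s)
    if s.clamp_cells is not None and len(s.clamp_cells):
        # the clamp electrode injects whatever charge holds V_mem at the
        # commanded value; the injected charge persists after release and
        # dissipates through ordinary fluxes
        cc = s.clamp_cells
        if s.Q_inj is None:
            s.Q_inj = np.zeros(g.n_cells)
        C = p.c_mem * g.cell_surface_areas[cc]
        vm_mean = _cell_mean_vmem(world, s)
        s.Q_inj[cc] += (s.clamp_value - vm_mean[cc]) * C
        _voltages_from_charge(world, s)
        clamped_mem = np.isin(g.membrane_to_cell, cc)
        s.V_mem[clamped_mem] = s.clamp_value


def _charge_relaxation_time(world: World, s: TissueState) -> float:
    """Fastest charge-relaxation timescale of the explicit update, s.

    Three couplings can destabilise the explicit step: (1) transmembrane
    conductance discharging the membrane capacitor (tau = c_mem / g with
    g = (F^2/RT) sum_i z_i^2 P_i c_i per unit area); (2) gap-junction
    conductance equilibrating the voltages of adjacent cell capacitors;
    (3) environment-face conduction between extracellular conductors.
    The step is subdivided to stay below the fastest of these.
    """
    p = world.params
    g = world.cell_grid
    kT = F ** 2 / (R * p.T)
    D = _dynamic_membrane_D(world, s, 0.0, update_gates=False)
    node_of_mem = world.weights.node_of_membrane
    taus = [np.inf]

    cond = np.zeros(g.n_membranes)
    for i, ion in enumerate(world.ions):
        if ion.tracer:
            continue
        c_hi = np.maximum(s.c_cells[i][g.membrane_to_cell],
                          s.c_env[i][node_of_mem])
        cond += ion.z ** 2 * (D[i] / p.d_mem) * c_hi
    cond *= kT
    if len(cond) and cond.max() > 0:
        taus.append(p.c_mem / cond.max())

    if g.n_gj and p.beta_gj > 0:
        tails, heads = g.gj_cell_pairs[:, 0], g.gj_cell_pairs[:, 1]
        z2c = np.zeros(g.n_gj)
        for i, ion in enumerate(world.ions):
            if ion.tracer or not ion.gj_mobile or ion.balance:
                continue
            z2c += ion.z ** 2 * ion.D_free * 0.5 * (
                s.c_cells[i][tails] + s.c_cells[i][heads])
        g_edge = kT * p.beta_gj * s.beta_gj * z2c / p.d_gj \
            * g.membrane_areas[g.gj_pairs[:, 0]]
        C_cell = p.c_mem * g.cell_surface_areas
        rate = g_edge * (1.0 / C_cell[tails] + 1.0 / C_cell[heads])
        if rate.max() > 0:
            taus.append(1.0 / rate.max())

    return min(taus)


def _env_conduction_solver(world: World, s: TissueState, dt: float):
    """Factorised solver for the environment potential.

    The extracellular network is a conductor with electrolyte screening
    capacitance: (C/dt + L_G) V_new = (C/dt) V_old + I_inj, where L_G is
    the graph Laplacian of face conductances G = (F^2/RT) sum_i z_i^2 D_i
    cbar_i * scale * A/dx and C is the per-node screening capacitance.
    Semi-implicit in V, hence unconditionally stable, and reduces to the
    quasi-static Ohmic solve once transients have relaxed (C/dt << G).
    The global boundary rim is held at ground.  Returns
    ``(solve, C_over_dt)``.
    """
    from scipy import sparse
    from scipy.sparse.linalg import factorized
    p = world.params
    ops = world.env_ops
    et, eh = ops.face_tails, ops.face_heads
    kT = F ** 2 / (R * p.T)
    z2c = np.zeros(ops.n_faces)
    for i, ion in enumerate(world.ions):
        if ion.tracer:
            continue
        z2c += ion.z ** 2 * ion.D_free * 0.5 * (s.c_env[i][et]
                                                + s.c_env[i][eh])
    G = kT * z2c * world.env_face_scale * world.env_face_area \
        / ops.edge_lengths
    n = ops.n_nodes
    C_dt = np.maximum(world.env_node_capacitance,
                      p.c_self * 2.0 * world.env_grid.spacing * p.h) / dt
    rows = np.concatenate([et, eh, et, eh, np.arange(n)])
    cols = np.concatenate([et, eh, eh, et, np.arange(n)])
    vals = np.concatenate([G, G, -G, -G, C_dt])
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n)).tolil()
    for b in world.env_grid.boundary_nodes:
        A.rows[b] = [b]
        A.data[b] = [1.0]
    return factorized(A.tocsc()), C_dt


def step(s: TissueState, dt: float, world: World,
         in_place: bool = False) -> TissueState:
    """Advance the tissue state by ``dt`` seconds.

    The requested step is internally divided into substeps no longer than
    a fraction of the fastest membrane charge-relaxation time, so the
    explicit update stays stable even for high-permeability membranes;
    blow-up that survives substepping raises ``EngineInstability``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not in_place:
        s = s.copy()
    tau = _charge_relaxation_time(world, s)
    n_sub = 1 if not np.isfinite(tau) else int(np.ceil(dt / (0.4 * tau)))
    if n_sub > 4000:
        raise EngineInstability(
            f"membrane relaxation time {tau:.3g}s requires >4000 substeps "
            f"of dt={dt:.3g}s at t={s.t:.4g}s; reduce dt")
    # a fast concentration transient (e.g. a thin cell during start-up)
    # can outrun the voltage-based estimate: retry with finer substeps
    checkpoint = s.copy()
    for attempt in range(4):
        try:
            dt_sub = dt / n_sub
            if world.params.mode == "environment":
                # conduction coefficients drift on concentration
                # timescales; refresh the factorised solver every ~1 s of
                # simulated time or when the substep size changes
                age = getattr(world, "_env_cond_t", None)
                if (age is None or s.t - age > 1.0 or s.t < age
                        or getattr(world, "_env_cond_dt", None) != dt_sub):
                    world._env_cond = _env_conduction_solver(world, s,
                                                             dt_sub)
                    world._env_cond_t = s.t
                    world._env_cond_dt = dt_sub
            for _ in range(n_sub):
                s = _substep(s, dt_sub, world)
            return s
        except EngineInstability:
            if attempt == 3 or n_sub >= 4000:
                raise
            n_sub = min(4 * n_sub, 4000)
            s = checkpoint
            checkpoint = s.copy()
    return s


def _substep(s: TissueState, dt: float, world: World) -> TissueState:
    p = world.params
    g = world.cell_grid
    idx = world.ion_index
    n_ion = len(world.ions)

    apply_interventions(s, world.schedule, s.t, world.ions)

    if world.channels and dt > 1.0e-4 + 1e-12:
        raise EngineInstability(
            "dt too large for Hodgkin-Huxley channels; use dt <= 1e-4 s")

    D_mem = _dynamic_membrane_D(world, s, dt, update_gates=True)

    if p.gj_voltage_sensitive and g.n_gj:
        pairs = g.gj_cell_pairs
        V_gj = s.V_cell[pairs[:, 0]] - s.V_cell[pairs[:, 1]]
        s.beta_gj = gj_gate_update(V_gj, s.beta_gj, dt, world.gj_gate)

    # --- flux set (vectorised over ions) ----------------------------------
    node_of_mem = world.weights.node_of_membrane
    mem_cell = g.membrane_to_cell
    z_col = np.array([ion.z for ion in world.ions],
                     dtype=float)[:, None]
    phi_mem = transport.ghk_flux(
        s.c_cells[:, mem_cell], s.c_env[:, node_of_mem],
        s.V_mem[None, :], D_mem, z_col, p)

    world.pump.blocked = s.pump_blocked
    if world.pump_scale_mem.any() and not s.pump_blocked:
        iNa, iK = idx.get("Na"), idx.get("K")
        if iNa is not None and iK is not None:
            rate = nak_pump_rate(
                s.c_cells[iNa][mem_cell], s.c_env[iK][node_of_mem],
                s.V_mem, p, world.pump,
                c_Na_out=s.c_env[iNa][node_of_mem],
                c_K_in=s.c_cells[iK][mem_cell],
            ) * world.pump_scale_mem
            phi_mem[iNa] += 3.0 * rate
            phi_mem[iK] += -2.0 * rate

    D_free = np.array([ion.D_free for ion in world.ions])[:, None]
    gj_ok = np.array([ion.gj_mobile and not ion.balance
                      for ion in world.ions])[:, None]
    phi_gj = np.zeros((n_ion, g.n_gj))
    if g.n_gj:
        u_gj = getattr(s, "u_gj", None) if p.eo_enabled else None
        tails, heads = g.gj_cell_pairs[:, 0], g.gj_cell_pairs[:, 1]
        D_edge = (p.beta_gj * s.beta_gj)[None, :] * D_free * gj_ok
        dV = (s.V_cell[heads] - s.V_cell[tails])[None, :]
        u = z_col * F / (R * p.T) * dV
        phi_gj = D_edge / p.d_gj * (
            transport.bernoulli(u) * s.c_cells[:, tails]
            - transport.bernoulli(-u) * s.c_cells[:, heads])
        if u_gj is not None:
            c_up = np.where(u_gj[None, :] >= 0, s.c_cells[:, tails],
                            s.c_cells[:, heads])
            phi_gj = phi_gj + u_gj[None, :] * c_up * gj_ok

    A_mem = g.membrane_areas
    vols = g.cell_volumes
    eff_out = phi_mem * A_mem  # mol/s leaving each cell through membrane

    env_mode = p.mode == "environment"
    phi_env = None
    if env_mode:
        # quasi-static environment: solve the Ohmic potential that routes
        # the injected membrane and diffusive charge currents to ground,
        # then evaluate the consistent per-ion drift fluxes
        ops = world.env_ops
        n_env = world.env_grid.n_nodes
        u_env = getattr(s, "u_env", None) if p.eo_enabled else None
        et, eh = ops.face_tails, ops.face_heads
        D_face = D_free * world.env_face_scale[None, :]
        dc = s.c_env[:, eh] - s.c_env[:, et]
        phi_diff = -D_face * dc / ops.edge_lengths[None, :]
        z_chg = np.array([0.0 if ion.tracer else float(ion.z)
                          for ion in world.ions])
        I_mem = F * np.bincount(
            node_of_mem, weights=(z_chg[:, None] * eff_out).sum(0),
            minlength=n_env)
        J_diff = F * (z_chg[:, None] * phi_diff).sum(0) \
            * world.env_face_area
        solve, C_dt = world._env_cond
        b = I_mem + np.bincount(eh, weights=J_diff, minlength=n_env) \
            - np.bincount(et, weights=J_diff, minlength=n_env) \
            + C_dt * s.V_env
        b[world.env_grid.boundary_nodes] = 0.0
        s.V_env = solve(b)
        # total electrodiffusive face flux (Scharfetter-Gummel) at the
        # solved potential, plus advection
        u = z_col * F / (R * p.T) * (s.V_env[eh] - s.V_env[et])[None, :]
        phi_env = D_face / ops.edge_lengths[None, :] * (
            transport.bernoulli(u) * s.c_env[:, et]
            - transport.bernoulli(-u) * s.c_env[:, eh])
        if u_env is not None:
            c_up = np.where(u_env[None, :] >= 0, s.c_env[:, et],
                            s.c_env[:, eh])
            phi_env = phi_env + u_env[None, :] * c_up

    # --- concentration update --------------------------------------------
    d_moles_cells = np.empty((n_ion, g.n_cells))
    for i in range(n_ion):
        d_moles_cells[i] = -np.bincount(mem_cell, weights=eff_out[i],
                                        minlength=g.n_cells)
    if g.n_gj:
        tails, heads = g.gj_cell_pairs[:, 0], g.gj_cell_pairs[:, 1]
        edge_A = g.membrane_areas[g.gj_pairs[:, 0]]
        for i in range(n_ion):
            e = phi_gj[i] * edge_A
            d_moles_cells[i] += (
                np.bincount(heads, weights=e, minlength=g.n_cells)
                - np.bincount(tails, weights=e, minlength=g.n_cells))
    c_cells_new = s.c_cells + dt * d_moles_cells / vols

    if env_mode:
        node_vol = world.env_node_volumes
        n_env = world.env_grid.n_nodes
        et, eh = world.env_ops.face_tails, world.env_ops.face_heads
        d_moles_env = np.empty((n_ion, n_env))
        for i in range(n_ion):
            e = phi_env[i] * world.env_face_area
            d_moles_env[i] = (
                np.bincount(node_of_mem, weights=eff_out[i],
                            minlength=n_env)
                + np.bincount(eh, weights=e, minlength=n_env)
                - np.bincount(et, weights=e, minlength=n_env))
        c_env_new = s.c_env + dt * d_moles_env / node_vol
    else:
        c_env_new = s.c_env

    # stability / sanity
    ref = np.maximum(np.abs(s.c_cells), 1.0)
    jump = np.abs(c_cells_new - s.c_cells) / ref
    if not np.isfinite(c_cells_new).all() or jump.max() > 0.5:
        i, c = np.unravel_index(np.nanargmax(jump), jump.shape)
        raise EngineInstability(
            f"concentration of {world.ions[i].name} in cell {c} changed by "
            f">50% in one step at t={s.t:.4g}s; reduce dt below {dt:.3g}s")
    if env_mode and not np.isfinite(c_env_new).all():
        raise EngineInstability(
            f"non-finite environment concentration at t={s.t:.4g}s; "
            f"reduce dt below {dt:.3g}s")
    for arr, label in ((c_cells_new, "cell"), (c_env_new, "env")):
        neg = arr < 0
        if neg.any():
            if arr.min() < -1e-3:
                warnings.warn(
                    f"clipped negative {label} concentration "
                    f"(min {arr.min():.3g} mol/m^3) at t={s.t:.4g}s",
                    RuntimeWarning, stacklevel=2)
            np.clip(arr, 0.0, None, out=arr)
    s.c_cells = c_cells_new
    s.c_env = c_env_new

    # Dirichlet boundary values (open global boundary)
    if p.closed_boundary:
        pass
    elif env_mode:
        b = world.env_grid.boundary_nodes
        for i in range(n_ion):
            s.c_env[i][b] = s.boundary_conc.get(i, world.c_bath[i])
    else:
        for i, val in s.boundary_conc.items():
            s.c_env[i][:] = val
        if not s.boundary_conc:
            s.c_env[:] = world.c_bath[:, None]

    # --- charges and voltages ---------------------------------------------
    if s.inj_cells is not None and len(s.inj_cells):
        if s.Q_inj is None:
            s.Q_inj = np.zeros(g.n_cells)
        s.Q_inj[s.inj_cells] += s.inj_current * dt
    _solve_state_voltages(world, s)

    # --- electroosmotic flow for next step's advection ---------------------
    if p.eo_enabled:
        _update_flows(world, s)

    s.t += dt
    return s


def _update_flows(world: World, s: TissueState) -> None:
    p = world.params
    if world.cell_grid.n_gj:
        pairs = world.cell_grid.gj_cell_pairs
        rho = transport.charge_density(s.c_cells, world.ions)
        rho_e = 0.5 * (rho[pairs[:, 0]] + rho[pairs[:, 1]])
        E = -(s.V_cell[pairs[:, 1]] - s.V_cell[pairs[:, 0]]) / p.d_gj
        s.u_gj = eo_velocity(eo_body_force(rho_e, E), p.r_gj_pore, p.mu,
                             world.cell_ops)
    if p.mode == "environment":
        ops = world.env_ops
        # the physical extracellular charge is the Debye screening charge
        # implied by the local potential, not the (electroneutral) bulk
        rho = world.env_node_capacitance * s.V_env / world.env_node_volumes
        rho_f = 0.5 * (rho[ops.face_tails] + rho[ops.face_heads])
        E = -ops.gradient(s.V_env)
        s.u_env = eo_velocity(eo_body_force(rho_f, E), p.d_ecm / 2.0, p.mu,
                              world.env_ops)


def compute_fields(world: World, s: TissueState) -> dict:
    """Diagnostic currents, fields and flows at the current state.

    Returns per-edge current density and mesoscopic field on the cell
    network, and per-face equivalents on the environment grid (environment
    mode), each continuity-corrected.
    """
    p = world.params
    g = world.cell_grid
    out = {}
    if g.n_gj:
        phi = np.zeros((len(world.ions), g.n_gj))
        for i, ion in enumerate(world.ions):
            if not ion.gj_mobile or ion.balance:
                continue
            phi[i] = transport.network_flux(
                s.c_cells[i], s.V_cell, p.beta_gj * s.beta_gj * ion.D_free,
                world.cell_ops, z=ion.z, T=p.T, edge_length=p.d_gj)
        J, E = transport.corrected_current(phi, world.ions, world.cell_ops,
                                           gamma=p.gamma)
        out["J_cell"], out["E_cell"] = J, E
    if p.mode == "environment":
        phi = np.zeros((len(world.ions), world.env_ops.n_faces))
        for i, ion in enumerate(world.ions):
            phi[i] = transport.network_flux(
                s.c_env[i], s.V_env, ion.D_free * world.env_face_scale,
                world.env_ops, z=ion.z, T=p.T)
        J, E = transport.corrected_current(phi, world.ions, world.env_ops,
                                           gamma=p.gamma)
        out["J_env"], out["E_env"] = J, E
    _update_flows(world, s)
    out["u_gj"] = getattr(s, "u_gj", None)
    out["u_env"] = getattr(s, "u_env", None)
    return out


# ---------------------------------------------------------------------------
# run loop

@dataclass
class SimResult:
    """Recorded trajectories and snapshots of one simulation."""

    times: np.ndarray                 # (n_t,)
    V_mem: np.ndarray                 # (n_t, n_cell), cell-mean V_mem, V
    V_cell: np.ndarray                # (n_t, n_cell), V
    V_env_internal: np.ndarray        # (n_t,), mean internal env voltage, V
    c_cells: np.ndarray               # (n_t, n_ion, n_cell), mol/m^3
    ion_names: list
    snapshots: list = field(default_factory=list)   # (t, fields dict)
    events: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    final_state: TissueState | None = None


def _cell_mean_vmem(world: World, s: TissueState) -> np.ndarray:
    num = np.zeros(world.cell_grid.n_cells)
    den = np.zeros(world.cell_grid.n_cells)
    np.add.at(num, world.cell_grid.membrane_to_cell,
              s.V_mem * world.cell_grid.membrane_areas)
    np.add.at(den, world.cell_grid.membrane_to_cell,
              world.cell_grid.membrane_areas)
    return num / den


def run(world: World, state: TissueState | None = None,
        t_end: float | None = None, dt: float | None = None,
        record_dt: float | None = None, snapshot_dt: float | None = None,
        init_phase: float = 0.0, init_dt: float | None = None,
        wound_at: tuple | None = None,
        config_echo: dict | None = None) -> SimResult:
    """Run a simulation and record trajectories.

    ``init_phase`` simulated seconds are first run with dynamic
    (Hodgkin–Huxley) channels disabled, to bring the tissue to its resting
    state before excitable dynamics switch on.  Deterministic: no random
    numbers are drawn during stepping.
    """
    p = world.params
    dt = p.dt if dt is None else dt
    t_end = p.t_end if t_end is None else t_end
    if record_dt is None:
        record_dt = max(dt, t_end / 2000.0 if t_end > 0 else dt)
    if state is None:
        state = initial_state(world)

    events = []
    if init_phase > 0:
        # settle to rest with dynamic channels off and no interventions
        saved_channels = world.channels
        saved_schedule = world.schedule
        world.channels = []
        world.schedule = InterventionSchedule()
        idt = init_dt or p.dt
        n_init = int(round(init_phase / idt))
        for _ in range(n_init):
            state = step(state, idt, world, in_place=True)
        world.channels = saved_channels
        world.schedule = saved_schedule
        _init_gates(world, state)
        state.t = 0.0
        events.append((0.0, f"initialization phase {init_phase:g}s done"))

    times, vmem, vcell, venv, conc = [], [], [], [], []
    snaps = []
    n_cell0 = world.cell_grid.n_cells
    cell_ids = np.arange(n_cell0)   # survivors' original indices

    def _record(s):
        times.append(s.t)
        vm = np.full(n_cell0, np.nan)
        vc = np.full(n_cell0, np.nan)
        cc = np.full((len(world.ions), n_cell0), np.nan)
        vm[cell_ids] = _cell_mean_vmem(world, s)
        vc[cell_ids] = s.V_cell
        cc[:, cell_ids] = s.c_cells
        vmem.append(vm)
        vcell.append(vc)
        internal = world.env_grid.inside_mask
        venv.append(float(s.V_env[internal].mean()) if internal.any()
                    else 0.0)
        conc.append(cc)

    _record(state)
    n_steps = int(round(t_end / dt))
    next_rec = record_dt
    next_snap = snapshot_dt if snapshot_dt else np.inf
    wound_pending = wound_at is not None
    for k in range(n_steps):
        if wound_pending and state.t >= wound_at[0] - 1e-12:
            state, world = wound(state, world, wound_at[1])
            cell_ids = cell_ids[state.kept_cells]
            wound_pending = False
            events.append((state.t, "wound applied"))
        state = step(state, dt, world, in_place=True)
        if state.t >= next_rec - 1e-12:
            _record(state)
            next_rec += record_dt
        if state.t >= next_snap - 1e-12:
            snaps.append((state.t, compute_fields(world, state)))
            next_snap += snapshot_dt
    if not times or times[-1] < state.t:
        _record(state)

    return SimResult(
        times=np.asarray(times),
        V_mem=np.asarray(vmem),
        V_cell=np.asarray(vcell),
        V_env_internal=np.asarray(venv),
        c_cells=np.asarray(conc),
        ion_names=[ion.name for ion in world.ions],
        snapshots=snaps,
        events=events,
        config=config_echo or {},
        final_state=state,
    )


def wound(s: TissueState, world: World, wound_mask: RegionMask):
    """Cut a wound mid-run: remove cells, re-index state, rebuild world.

    Removed cells spill their contents into the nearest environment nodes
    (total moles are conserved across the re-index); the wound footprint
    reverts to continuous open environment, locally breaking any
    tight-junction barrier; the capacitance system is reassembled for the
    new geometry.
    """
    g_old = world.cell_grid
    new_grid, kept_cells, kept_mem = cut_region(g_old, wound_mask)
    removed = np.setdiff1d(np.arange(g_old.n_cells), kept_cells)

    new_profiles = []
    old_to_new = -np.ones(g_old.n_cells, dtype=int)
    old_to_new[kept_cells] = np.arange(len(kept_cells))
    for prof in world.profiles:
        cells = old_to_new[np.asarray(prof.cells, dtype=int)]
        cells = cells[cells >= 0]
        if len(cells):
            new_profiles.append(Profile(label=prof.label, cells=cells,
                                        P_mem=prof.P_mem,
                                        pump_scale=prof.pump_scale,
                                        channels=prof.channels))
    new_events = []
    for ev in world.schedule.events:
        if ev.cells is not None:
            cells = old_to_new[np.asarray(ev.cells, dtype=int)]
            cells = cells[cells >= 0]
            if not len(cells):
                continue
            from dataclasses import replace
            ev = replace(ev, cells=cells)
        new_events.append(ev)

    new_world = build_world(new_grid, world.ions, new_profiles, world.params,
                            schedule=InterventionSchedule(new_events),
                            env_grid=build_env_grid(
                                new_grid.world_extent, world.env_grid.nx,
                                new_grid),
                            pump=world.pump, gj_gate=world.gj_gate)

    n_ion = len(world.ions)
    new_s = TissueState(
        t=s.t,
        c_cells=s.c_cells[:, kept_cells].copy(),
        c_env=s.c_env.copy(),
        V_cell=s.V_cell[kept_cells].copy(),
        V_env=s.V_env.copy(),
        V_mem=s.V_mem[kept_mem].copy(),
        beta_gj=np.ones(new_grid.n_gj),
        Q_inj=None if s.Q_inj is None else s.Q_inj[kept_cells].copy(),
        perm_scale=s.perm_scale[:, kept_cells].copy(),
        pump_blocked=s.pump_blocked,
        boundary_conc=dict(s.boundary_conc),
    )
    # conserve moles: removed cell contents enter the environment at the
    # nodes nearest the removed cell centres, using the *new* node volumes
    from scipy.spatial import cKDTree
    if len(removed):
        tree = cKDTree(world.env_grid.node_xy)
        _, nearest = tree.query(g_old.cell_centers[removed])
        moles = s.c_cells[:, removed] * g_old.cell_volumes[removed]
        add = np.zeros((n_ion, world.env_grid.n_nodes))
        for i in range(n_ion):
            np.add.at(add[i], nearest, moles[i])
        # re-express env concentrations as moles on old volumes, add, and
        # divide by the new volumes so nothing is created or lost
        old_moles = s.c_env * world.env_node_volumes
        new_s.c_env = (old_moles + add) / new_world.env_node_volumes
    else:
        new_s.c_env = (s.c_env * world.env_node_volumes
                       / new_world.env_node_volumes)
    _init_gates(new_world, new_s)
    _solve_state_voltages(new_world, new_s)
    new_s.kept_cells = kept_cells  # original indices, for trajectory plumbing
    return new_s, new_world
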