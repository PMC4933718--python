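"""Physical state, species definitions, tissue profiles and interventions.

This module is the single source of truth for every dynamical symbol used
by the transport, voltage and membrane-dynamics computations: ion
concentrations in cells and environment, regional voltages, per-membrane
diffusivities, channel gating variables, gap-junction open fractions, and
the timed perturbation schedule.

Charge bookkeeping: printed physiological tables are rarely exactly
electroneutral (they round, and omit minor species such as bicarbonate).
A species can therefore be declared the *balance anion* (``balance=True``):
``init_state`` sets its initial concentration in each compartment so that
the net charge density is exactly zero, which realises the canonical
"V_mem = 0 everywhere" initial condition while using table values verbatim
for the major ions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CellGrid, EnvGrid, RegionMask
from .params import F, ParameterSet

__all__ = [
    "IonSpec",
    "Profile",
    "Intervention",
    "InterventionSchedule",
    "TissueState",
    "init_state",
    "membrane_diffusivity_base",
    "apply_interventions",
]


@dataclass(frozen=True)
class IonSpec:
    """One mobile ionic species.

    ``tracer`` species (reporter dyes, signalling ligands) electrodiffuse
    like any other ion but are excluded from charge density and currents —
    they are assumed present at concentrations too low to affect voltage.
    ``balance`` marks the impermeant anion whose initial concentration is
    adjusted for exact initial electroneutrality.
    """

    name: str
    z: int                       # valence
    D_free: float = 1.0e-9       # free diffusivity, m^2/s
    c_in: float = 1.0            # initial intracellular conc, mol/m^3
    c_out: float = 1.0           # initial extracellular conc, mol/m^3
    tracer: bool = False
    balance: bool = False
    gj_mobile: bool = True       # charged macromolecules do not pass GJs

    def __post_init__(self):
        if self.D_free <= 0:
            raise ValueError(f"ion {self.name}: D_free must be positive")
        if self.c_in < 0 or self.c_out < 0:
            raise ValueError(f"ion {self.name}: negative concentration")


@dataclass
class Profile:
    """Membrane phenotype shared by a set of cells.

    ``P_mem`` maps ion name -> membrane permeability in m/s (converted to a
    membrane diffusivity via D = P * d_mem).  ``pump_scale`` multiplies the
    global maximum Na/K-ATPase rate; ``channels`` is a list of channel
    specification dicts consumed by the engine (kind, ion, P_max, ...).
    """

    label: str
    cells: np.ndarray                  # cell indices
    P_mem: dict = field(default_factory=dict)
    pump_scale: float = 1.0
    channels: list = field(default_factory=list)


@dataclass(frozen=True)
class Intervention:
    """One timed perturbation.

    action is one of ``scale_permeability`` (ion, factor),
    ``block_pump``, ``set_boundary_concentration`` (ion, value),
    ``force_depolarize`` (cells, value = clamped V_mem in volts),
    ``inject_current`` (cells, value = electrode current in A per cell;
    positive depolarizes) or ``wound`` (mask).  Events apply over
    [t_start, t_end) and restore baseline afterwards (wounds are
    permanent; injected charge dissipates through ordinary fluxes).
    """

    t_start: float
    t_end: float
    action: str
    ion: str | None = None
    factor: float | None = None
    value: float | None = None
    cells: np.ndarray | None = None
    mask: RegionMask | None = None

    def active(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


_ACTIONS = {"scale_permeability", "block_pump", "set_boundary_concentration",
            "force_depolarize", "inject_current", "wound"}


@dataclass
class InterventionSchedule:
    events: list = field(default_factory=list)

    def __post_init__(self):
        for ev in self.events:
            if ev.action not in _ACTIONS:
                raise ValueError(f"unknown intervention action {ev.action!r}")
            if ev.t_start >= ev.t_end:
                raise ValueError("intervention must have t_start < t_end")
        # reject contradictory overlaps: same action on the same ion with
        # overlapping windows and different magnitudes
        evs = [e for e in self.events
               if e.action in ("scale_permeability",
                               "set_boundary_concentration")]
        for i, a in enumerate(evs):
            for b in evs[i + 1:]:
                if (a.action == b.action and a.ion == b.ion
                        and a.t_start < b.t_end and b.t_start < a.t_end
                        and (a.factor, a.value) != (b.factor, b.value)):
                    raise ValueError(
                        f"contradictory overlapping {a.action} events "
                        f"on ion {a.ion}")


@dataclass
class TissueState:
    """Full dynamic state of a tissue simulation at one instant."""

    t: float
    c_cells: np.ndarray          # (n_ion, n_cell), mol/m^3
    c_env: np.ndarray            # (n_ion, n_env_node), mol/m^3
    V_cell: np.ndarray           # (n_cell,), V
    V_env: np.ndarray            # (n_env_node,), V
    V_mem: np.ndarray            # (n_mem,), V
    gates: dict = field(default_factory=dict)   # channel name -> gate arrays
    beta_gj: np.ndarray | None = None           # (n_gj,) open fraction
    Q_inj: np.ndarray | None = None             # (n_cell,) electrode charge, C
    # intervention-derived modifiers (recomputed each step)
    perm_scale: np.ndarray | None = None        # (n_ion, n_cell)
    pump_blocked: bool = False
    boundary_conc: dict = field(default_factory=dict)  # ion idx -> value
    clamp_cells: np.ndarray | None = None
    clamp_value: float | None = None
    inj_cells: np.ndarray | None = None
    inj_current: float | None = None

    def copy(self) -> "TissueState":
        return TissueState(
            t=self.t,
            c_cells=self.c_cells.copy(),
            c_env=self.c_env.copy(),
            V_cell=self.V_cell.copy(),
            V_env=self.V_env.copy(),
            V_mem=self.V_mem.copy(),
            gates={k: {g: a.copy() for g, a in v.items()}
                   for k, v in self.gates.items()},
            beta_gj=None if self.beta_gj is None else self.beta_gj.copy(),
            Q_inj=None if self.Q_inj is None else self.Q_inj.copy(),
            perm_scale=(None if self.perm_scale is None
                        else self.perm_scale.copy()),
            pump_blocked=self.pump_blocked,
            boundary_conc=dict(self.boundary_conc),
            clamp_cells=(None if self.clamp_cells is None
                         else np.asarray(self.clamp_cells).copy()),
            clamp_value=self.clamp_value,
            inj_cells=(None if self.inj_cells is None
                       else np.asarray(self.inj_cells).copy()),
            inj_current=self.inj_current,
        )


def membrane_diffusivity_base(cell_grid: CellGrid, ions: list[IonSpec],
                              profiles: list[Profile],
                              params: ParameterSet) -> np.ndarray:
    """Baseline membrane diffusivity D_mem (n_ion, n_mem) from profiles."""
    covered = np.zeros(cell_grid.n_cells, dtype=int)
    for p in profiles:
        covered[np.asarray(p.cells, dtype=int)] += 1
    if not np.all(covered == 1):
        bad = np.flatnonzero(covered != 1)
        raise ValueError(
            f"profiles must cover every cell exactly once; cells {bad[:5]}"
            f" covered {covered[bad[:5]]} times")
    D = np.zeros((len(ions), cell_grid.n_membranes))
    cell_profile = np.empty(cell_grid.n_cells, dtype=int)
    for k, p in enumerate(profiles):
        cell_profile[np.asarray(p.cells, dtype=int)] = k
    mem_profile = cell_profile[cell_grid.membrane_to_cell]
    for k, p in enumerate(profiles):
        sel = mem_profile == k
        for i, ion in enumerate(ions):
            P = p.P_mem.get(ion.name, 0.0)
            if P < 0:
                raise ValueError("negative permeability")
            D[i, sel] = P * params.d_mem
    return D


def balanced_concentrations(ions: list[IonSpec]):
    """Initial (c_in, c_out) vectors with balance species set for exact
    electroneutrality in each compartment."""
    n_ion = len(ions)
    c_in = np.array([ion.c_in for ion in ions], dtype=float)
    c_out = np.array([ion.c_out for ion in ions], dtype=float)
    bal_an = [i for i, ion in enumerate(ions) if ion.balance and ion.z == -1]
    bal_cat = [i for i, ion in enumerate(ions) if ion.balance and ion.z == 1]
    if len(bal_an) > 1 or len(bal_cat) > 1 or any(
            ion.balance and abs(ion.z) != 1 for ion in ions):
        raise ValueError("balance ions: at most one monovalent anion and "
                         "one monovalent cation")
    if not (bal_an or bal_cat):
        return c_in, c_out
    others = [j for j in range(n_ion)
              if not ions[j].balance and not ions[j].tracer]
    zs = np.array([ions[j].z for j in others], dtype=float)
    for c in (c_in, c_out):
        excess = float(zs @ c[others])
        if bal_an:
            c[bal_an[0]] = max(excess, 0.0)
        if bal_cat:
            c[bal_cat[0]] = max(-excess, 0.0)
        if not bal_an and excess > 1e-12:
            raise ValueError("cannot balance: need a balance anion")
        if not bal_cat and excess < -1e-12:
            raise ValueError("cannot balance: need a balance cation")
    return c_in, c_out


def init_state(cell_grid: CellGrid, env_grid: EnvGrid, ions: list[IonSpec],
               profiles: list[Profile], params: ParameterSet) -> TissueState:
    """Allocate and fill the initial tissue state.

    Concentrations come from the IonSpec initial values; the balance anion
    (if any) is adjusted per compartment for exact electroneutrality, after
    which initial voltages are zero by construction for the canonical
    equal-concentration start, or follow from the initial charges
    otherwise.
    """
    membrane_diffusivity_base(cell_grid, ions, profiles, params)  # coverage
    n_ion, n_cell = len(ions), cell_grid.n_cells
    c_in0, c_out0 = balanced_concentrations(ions)
    c_cells = np.repeat(c_in0[:, None], n_cell, axis=1)
    c_env = np.repeat(c_out0[:, None], env_grid.n_nodes, axis=1)

    state = TissueState(
        t=0.0,
        c_cells=c_cells,
        c_env=c_env,
        V_cell=np.zeros(n_cell),
        V_env=np.zeros(env_grid.n_nodes),
        V_mem=np.zeros(cell_grid.n_membranes),
        beta_gj=np.ones(cell_grid.n_gj),
        Q_inj=np.zeros(n_cell),
        perm_scale=np.ones((n_ion, n_cell)),
    )
    return state


def apply_interventions(state: TissueState, schedule: InterventionSchedule,
                        t: float, ions: list[IonSpec]) -> TissueState:
    """Refresh the intervention-derived modifiers for time ``t``.

    Pure with respect to non-targeted fields: modifiers are recomputed from
    scratch, so an event's effect vanishes exactly at its t_end.  Wound
    events are not handled here (they change geometry; see engine.wound).
    """
    ion_index = {ion.name: i for i, ion in enumerate(ions)}
    state.perm_scale = np.ones_like(state.perm_scale)
    state.pump_blocked = False
    state.boundary_conc = {}
    state.clamp_cells = None
    state.clamp_value = None
    state.inj_cells = None
    state.inj_current = None
    for ev in schedule.events:
        if not ev.active(t) or ev.action == "wound":
            continue
        if ev.action == "scale_permeability":
            i = ion_index[ev.ion]
            if ev.cells is None:
                state.perm_scale[i, :] *= ev.factor
            else:
                state.perm_scale[i, np.asarray(ev.cells, int)] *= ev.factor
        elif ev.action == "block_pump":
            state.pump_blocked = True
        elif ev.action == "set_boundary_concentration":
            state.boundary_conc[ion_index[ev.ion]] = ev.value
        elif ev.action == "force_depolarize":
            state.clamp_cells = np.asarray(ev.cells, dtype=int)
            state.clamp_value = ev.value if ev.value is not None else -20e-3
        elif ev.action == "inject_current":
            state.inj_cells = np.asarray(ev.cells, dtype=int)
            state.inj_current = ev.value if ev.value is not None else 1e-9
    return state
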