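"""Active pumps, voltage-gated channels, ligand gates and GJ gating.

Pump thermodynamics
-------------------
The Na/K-ATPase is modelled as a reversible Michaelis–Menten enzyme whose
rate carries the thermodynamic factor (1 - Omega / K_eqm), where Omega is
the mass-action ratio of the pump reaction

    3 Na_in + 2 K_out + ATP  <->  3 Na_out + 2 K_in + ADP + P

and K_eqm follows from the reaction free energy

    dG_pump = dG_ATP + RT ln(Omega) - F V_mem,

with dG_ATP = -37 kJ/mol for hydrolysis.  The pump therefore stalls
exactly where dG_pump = 0 (Omega = K_eqm = exp((F V_mem - dG_ATP)/RT)) and
runs backwards past it.  The -F V_mem term is the electrical work of the
net +1 charge exported per cycle: pumping is *less* favourable at more
negative V_mem.

Voltage-gated channels
----------------------
Hodgkin–Huxley style gating applied to the membrane *diffusion* state:
D_mem(t) = D_max * m^3 h for the generic NaV (classic squid-type rates)
and D_max * n^4 * h for the delayed-rectifier KV1.2 (delayed-rectifier
activation with the published KV1.2 deactivation time constant and slow
inactivation; the ~10 s inactivation gate is what allows a sustained
depolarized resting state when KV1.2 is deficient).  Rates are expressed
at mV/ms scale internally and gates are advanced with the exponential
(Rush–Larsen) update, which keeps them in [0, 1] unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import F, R, ParameterSet

__all__ = [
    "PumpModel",
    "pump_equilibrium_constant",
    "nak_pump_rate",
    "ChannelModel",
    "NaVChannel",
    "KV12Channel",
    "make_channel",
    "hh_channel_update",
    "ligand_gated_permeability",
    "GJGate",
    "gj_gate_steady",
    "gj_gate_update",
]


# ---------------------------------------------------------------------------
# pumps

@dataclass
class PumpModel:
    """Na/K-ATPase kinetic model (3 Na out : 2 K in per ATP)."""

    alpha_o: float = 2.0e-7      # max turnover, mol/(s m^2)
    K_Na: float = 5.0            # Michaelis constants, mol/m^3
    K_K: float = 0.2
    K_ATP: float = 0.15
    blocked: bool = False


def pump_equilibrium_constant(V_mem, params: ParameterSet):
    """Equilibrium mass-action ratio of the Na/K-ATPase reaction.

    K_eqm = exp((F V_mem - dG_ATP) / RT); the pump rate's thermodynamic
    factor (1 - Omega/K_eqm) vanishes exactly at Omega = K_eqm.
    """
    V_mem = np.asarray(V_mem, dtype=float)
    return np.exp((F * V_mem - params.dG_ATP) / (R * params.T))


def nak_pump_rate(c_Na_in, c_K_out, V_mem, params: ParameterSet,
                  model: PumpModel | None = None,
                  c_ATP=None, c_ADP=None, c_P=None,
                  c_Na_out=None, c_K_in=None):
    """Na/K-ATPase cycle rate, mol/(s m^2) of pump cycles.

    Na efflux = +3 * rate, K efflux = -2 * rate under the positive-out
    membrane flux convention.  Saturable Michaelis kinetics in Na_in,
    K_out and ATP, scaled by the thermodynamic factor; a blocked pump
    returns exactly zero.
    """
    model = model or PumpModel()
    if model.blocked:
        return np.zeros_like(np.asarray(V_mem, dtype=float))
    c_ATP = params.c_ATP if c_ATP is None else c_ATP
    c_ADP = params.c_ADP if c_ADP is None else c_ADP
    c_P = params.c_P if c_P is None else c_P
    c_Na_in = np.asarray(c_Na_in, dtype=float)
    c_K_out = np.asarray(c_K_out, dtype=float)
    if (c_Na_in < 0).any() or (c_K_out < 0).any():
        raise ValueError("negative concentration in pump rate")
    sat = ((c_ATP / model.K_ATP) * (c_Na_in / model.K_Na)
           * (c_K_out / model.K_K))
    sat /= ((1 + c_ATP / model.K_ATP) * (1 + c_Na_in / model.K_Na)
            * (1 + c_K_out / model.K_K))
    if c_Na_out is None or c_K_in is None:
        thermo = 1.0
    else:
        c_Na_out = np.asarray(c_Na_out, dtype=float)
        c_K_in = np.asarray(c_K_in, dtype=float)
        eps = 1e-30
        omega = (c_ADP * c_P * np.maximum(c_Na_out, eps) ** 3
                 * np.maximum(c_K_in, eps) ** 2) / (
            np.maximum(c_ATP, eps) * np.maximum(c_Na_in, eps) ** 3
            * np.maximum(c_K_out, eps) ** 2)
        thermo = 1.0 - omega / pump_equilibrium_constant(V_mem, params)
    return model.alpha_o * sat * thermo


# ---------------------------------------------------------------------------
# voltage-gated channels

def _vtrap(x, k):
    """x / (1 - exp(-x/k)) with the analytic limit k at x -> 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7 * k
    xs = np.where(small, 1.0, x)
    return np.where(small, k, xs / (-np.expm1(-xs / k)))


@dataclass
class ChannelModel:
    """Base voltage-gated channel: D_mem(t) = D_max * product(gates^exp)."""

    D_max: float                 # maximum membrane diffusivity, m^2/s
    ion: str = ""
    name: str = "channel"
    gate_names: tuple = ()
    gate_exponents: tuple = ()

    def inf_tau(self, V):  # pragma: no cover - abstract
        raise NotImplementedError

    def steady_gates(self, V) -> dict:
        V = np.asarray(V, dtype=float)
        it = self.inf_tau(V)
        return {g: it[g][0].copy() for g in self.gate_names}

    def open_fraction(self, gates: dict) -> np.ndarray:
        out = 1.0
        for g, e in zip(self.gate_names, self.gate_exponents):
            out = out * gates[g] ** e
        return out


class NaVChannel(ChannelModel):
    """Generic fast voltage-gated sodium channel, m^3 h kinetics.

    The classic squid-type rate functions (activation ramp centred near
    -40 mV, inactivation recovering below ~-60 mV), expressed at the
    -65 mV resting convention.  V in volts; internal rate scale mV/ms.
    """

    def __init__(self, D_max: float, name: str = "NaV"):
        super().__init__(D_max=D_max, ion="Na", name=name,
                         gate_names=("m", "h"), gate_exponents=(3, 1))

    def inf_tau(self, V):
        v = np.asarray(V, dtype=float) * 1e3  # mV
        am = 0.1 * _vtrap(v + 40.0, 10.0)
        bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
        ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
        tau_m = 1e-3 / (am + bm)              # s
        m_inf = am / (am + bm)
        tau_h = 1e-3 / (ah + bh)
        h_inf = ah / (ah + bh)
        return {"m": (m_inf, np.maximum(tau_m, 1e-6)),
                "h": (h_inf, np.maximum(tau_h, 1e-6))}


class KV12Channel(ChannelModel):
    """Delayed-rectifier potassium channel (KV1.2 class), n^4 activation
    with slow inactivation.

    Activation follows the classic delayed-rectifier n-gate rates, which
    leave the channel shut below about -55 mV and recruit it during the
    spike upstroke; the very slow inactivation gate (~10 s) reduces
    available conductance during long depolarized episodes, as observed
    for KV1.2.
    """

    def __init__(self, D_max: float, name: str = "KV12"):
        super().__init__(D_max=D_max, ion="K", name=name,
                         gate_names=("n", "h"), gate_exponents=(4, 1))

    def inf_tau(self, V):
        v = np.asarray(V, dtype=float) * 1e3
        an = 0.01 * _vtrap(v + 55.0, 10.0)
        bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
        n_inf = an / (an + bn)
        # KV1.2 deactivates far more slowly than the generic delayed
        # rectifier: use the published KV1.2 time-constant curve (~90 ms
        # below threshold, a few ms at spike peak)
        tau_n = 1e-3 * 150.0 / (1.0 + np.exp((v + 67.56) / 34.1479))
        h_inf = 1.0 / (1.0 + np.exp((v + 22.0) / 11.3943))
        tau_h = 1e-3 * 15000.0 / (1.0 + np.exp(-(v + 46.56) / 44.1479))
        return {"n": (n_inf, np.maximum(tau_n, 1e-6)),
                "h": (h_inf, np.maximum(tau_h, 1e-6))}


def make_channel(kind: str, D_max: float, **kw) -> ChannelModel:
    kinds = {"NaV": NaVChannel, "KV1.2": KV12Channel, "KV12": KV12Channel}
    if kind not in kinds:
        raise ValueError(f"unknown channel kind {kind!r}")
    return kinds[kind](D_max=D_max, **kw)


def hh_channel_update(V_mem, gates: dict, dt: float, model: ChannelModel):
    """Advance channel gates one step; return (gates', D_mem contribution).

    Uses the exponential update g += (g_inf - g)(1 - exp(-dt/tau)), the
    exact solution of dg/dt = (g_inf - g)/tau over the step for frozen V,
    so gates stay in [0, 1] for any dt; dt <= 1e-4 s is still enforced so
    the voltage coupling is resolved.
    """
    if dt > 1.0e-4 + 1e-12:
        raise ValueError(
            "dt too large for Hodgkin-Huxley gating (need dt <= 1e-4 s)")
    it = model.inf_tau(V_mem)
    new = {}
    for g in model.gate_names:
        g_inf, tau = it[g]
        new[g] = gates[g] + (g_inf - gates[g]) * (-np.expm1(-dt / tau))
    return new, model.D_max * model.open_fraction(new)


# ---------------------------------------------------------------------------
# ligand / calcium gates

def ligand_gated_permeability(c_ligand, D_max: float, K_half: float,
                              hill: float = 1.0):
    """Hill-form ligand-gated diffusivity: D_max c^n / (c^n + K_half^n)."""
    c = np.asarray(c_ligand, dtype=float)
    if (c < 0).any():
        raise ValueError("negative ligand concentration")
    cn = c ** hill
    return D_max * cn / (cn + K_half ** hill)


# ---------------------------------------------------------------------------
# gap-junction voltage gating

@dataclass
class GJGate:
    """Voltage-sensitive gap-junction gate (symmetric in |V_GJ|)."""

    v_half: float = 15.0e-3      # half-closure voltage, V
    k_slope: float = 4.0e-3      # sigmoid slope, V
    beta_min: float = 0.04       # minimum open fraction
    tau: float = 0.5             # relaxation time constant, s


def gj_gate_steady(V_gj, gate: GJGate | None = None):
    """Steady-state open fraction beta_inf(|V_GJ|)."""
    gate = gate or GJGate()
    V = np.abs(np.asarray(V_gj, dtype=float))
    return gate.beta_min + (1.0 - gate.beta_min) / (
        1.0 + np.exp((V - gate.v_half) / gate.k_slope))


def gj_gate_update(V_gj, beta, dt: float, gate: GJGate | None = None):
    """Relax open fractions toward beta_inf with first-order kinetics."""
    gate = gate or GJGate()
    b_inf = gj_gate_steady(V_gj, gate)
    return beta + (b_inf - beta) * (-np.expm1(-dt / gate.tau))
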