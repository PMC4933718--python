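"""Physical constants and solver settings.

All quantities are SI internally: metres, seconds, volts, mol/m^3
(numerically identical to mmol/L), coulombs.  Millivolts and nm/s appear
only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

# Fundamental constants
F = 96485.33  # Faraday constant, C/mol
R = 8.3145  # ideal gas constant, J/(K mol)
Q_E = 1.602176e-19  # elementary charge, C
K_B = 1.380649e-23  # Boltzmann constant, J/K
EPS0 = 8.854e-12  # vacuum permittivity, F/m
EPS_R_WATER = 80.0  # relative permittivity of water


@dataclass
class ParameterSet:
    """Physical parameters and solver settings for a tissue simulation.

    Defaults are the model's standard operating point: a 310 K electrolyte
    system of ~10 um tall cells with 0.022 F/m^2 membranes, 26 nm
    intercellular gaps, and a thermodynamically limited Na/K-ATPase with a
    standard ATP hydrolysis free energy of -37 kJ/mol.
    """

    T: float = 310.0                  # temperature, K
    c_mem: float = 0.022              # membrane capacitance, F/m^2
    c_self: float = 0.86              # electrolyte self-capacitance, F/m^2
    d_mem: float = 7.5e-9             # membrane thickness, m
    d_gj: float = 26.0e-9             # intercellular (gap junction) spacing, m
    d_ecm: float = 25.0e-9            # extracellular cleft width, m
    h: float = 10.0e-6                # system height, m
    mu: float = 5.0e-3                # water viscosity, Pa s
    gamma: float = 0.02               # media resistivity, Ohm m
    dG_ATP: float = -37.0e3           # std free energy of ATP hydrolysis, J/mol
    alpha_pump: float = 2.0e-7        # max Na/K-ATPase rate, mol/(s m^2)
    beta_gj: float = 5.0e-7           # GJ diffusion scaling coefficient
    beta_tj: float = 1.0e-7           # TJ diffusion scaling coefficient
    gj_vhalf: float = 15.0e-3         # GJ voltage-gating half-closure, V
    gj_kslope: float = 4.0e-3         # GJ gating sigmoid slope, V
    gj_beta_min: float = 0.04         # GJ minimum open fraction
    gj_tau: float = 0.5               # GJ gate relaxation time constant, s
    gj_voltage_sensitive: bool = False
    tj_enabled: bool = False
    eo_enabled: bool = False          # electroosmotic flow / advection
    r_gj_pore: float = 6.5e-9         # GJ pore radius for electroosmosis, m
    # fixed nucleotide/phosphate pools for pump thermodynamics, mol/m^3
    # (cytosolic norms: ATP ~1.5, ADP ~0.1, inorganic phosphate ~1; the
    # implied in-vivo dG_ATP is about -44 kJ/mol)
    c_ATP: float = 1.5
    c_ADP: float = 0.1
    c_P: float = 1.0
    closed_boundary: bool = False     # suppress open-boundary Dirichlet swap
    # solver
    dt: float = 0.05                  # time step, s
    t_end: float = 60.0               # simulated end time, s
    mode: str = "cytosol_only"        # "cytosol_only" | "environment"

    def __post_init__(self) -> None:
        if self.mode not in ("cytosol_only", "environment"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("T", "c_mem", "c_self", "d_mem", "d_gj", "d_ecm", "h",
                     "mu", "gamma", "alpha_pump", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")

    @property
    def RT(self) -> float:
        return R * self.T

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)
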