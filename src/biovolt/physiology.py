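"""Closed-form physiology calculators used for cross-checks and reporting.

The Nernst equation gives the equilibrium transmembrane voltage of a
single passively distributed species (the reporter-dye cross-check); the
Goldman equation gives the zero-net-current resting voltage of a
permeability-weighted monovalent ion set.  Because the simulator's
transmembrane fluxes are constant-field fluxes, a pump-free simulated
steady state must satisfy the Goldman equation exactly — deviations
measure either incomplete relaxation or electrogenic pumping.
"""

from __future__ import annotations

import numpy as np

from .params import F, R

__all__ = ["nernst_vmem", "goldman_vmem", "osmotic_pressure"]


def nernst_vmem(c_ext: float, c_int: float, z: int, T: float = 310.0) -> float:
    """Equilibrium potential V = (z R T / F) ln(c_ext / c_int), volts.

    Note the valence multiplies (rather than divides) the thermal voltage
    here, following the source convention for the reported dye check with
    z = +/-1; both conventions agree for monovalent species.
    """
    if c_ext <= 0 or c_int <= 0:
        raise ValueError("concentrations must be positive")
    return z * R * T / F * np.log(c_ext / c_int)


def goldman_vmem(P_cations: dict, P_anions: dict, c_int: dict, c_ext: dict,
                 T: float = 310.0) -> float:
    """Goldman–Hodgkin–Katz resting voltage, volts.

    ``P_cations`` / ``P_anions`` map ion name -> membrane permeability
    (m/s, monovalent species); concentrations in mol/m^3.  For a single
    permeant cation this reduces to the Nernst potential.
    """
    num = sum(P * c_ext[i] for i, P in P_cations.items()) \
        + sum(P * c_int[i] for i, P in P_anions.items())
    den = sum(P * c_int[i] for i, P in P_cations.items()) \
        + sum(P * c_ext[i] for i, P in P_anions.items())
    if den <= 0 or num <= 0:
        raise ValueError("Goldman equation needs nonzero permeant pathways")
    return R * T / F * np.log(num / den)


def osmotic_pressure(c_in, c_out, T: float = 310.0) -> float:
    """Van't Hoff osmotic pressure difference (in minus out), Pa."""
    c_in = np.atleast_1d(np.asarray(c_in, dtype=float))
    c_out = np.atleast_1d(np.asarray(c_out, dtype=float))
    return float(R * T * np.sum(c_in - c_out))
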