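"""Electroosmotic fluid flow estimates in narrow channels.

Fluid in gap-junction pores (r ~ 5-8 nm) and extracellular clefts
(half-width ~ 5-15 nm) is driven by the electric body force F_e = rho_e E.
A Hagen–Poiseuille-type estimate gives the raw channel velocity; since
incompressible flow must be divergence-free, an internal pressure field is
solved for and its gradient subtracted, exactly like the screening
correction applied to currents.

The per-tube Poiseuille law is normalised per channel cross-section here,
u_o = (r^2 / 8 mu) F_e, so that a volume force (N/m^3) yields a velocity;
the channel count and length scale are folded into the exposed geometric
prefactor.
"""

from __future__ import annotations

import numpy as np

__all__ = ["eo_body_force", "eo_velocity"]


def eo_body_force(rho_e, E):
    """Electric body force density F_e = rho_e * E, N/m^3 (elementwise)."""
    return np.asarray(rho_e, dtype=float) * np.asarray(E, dtype=float)


def eo_velocity(F_e, r: float, mu: float, grid_ops, prefactor: float = 1.0):
    """Electroosmotic velocity per network edge/face, m/s.

    ``F_e`` is the per-edge body force; the raw velocity
    u_o = prefactor * (r^2 / 8 mu) * F_e is projected onto the
    divergence-free subspace of the grid (the residual divergence after
    correction is at solver tolerance).
    """
    F_e = np.asarray(F_e, dtype=float)
    u_o = prefactor * (r ** 2 / (8.0 * mu)) * F_e
    if not np.any(u_o):
        return u_o
    return grid_ops.project_divergence_free(u_o)
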