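# Methods

`biovolt` simulates bioelectric state — transmembrane potentials,
transepithelial potentials, endogenous currents, and their emergent
spatial patterning — in two-dimensional clusters of gap-junction-coupled
cells, from ion concentrations up.  Nothing is prescribed a membrane
potential: voltages are computed from net ionic charge, charge from
fluxes, and fluxes from electrodiffusion and active transport.

## Model structure

**Geometry.**  The tissue is a clipped Voronoi tessellation: seed points
on a jittered hexagonal lattice (jitter amplitude 0.15 of the target cell
radius, explicit RNG seed) are tessellated and clipped to a binary raster
mask defining the cluster shape.  Each polygon edge is a *membrane* with
its own midpoint, outward normal, area (edge length x system height
`h` = 10 um) and local state; coincident edges of adjacent cells form gap
junctions separated by `d_gj` = 26 nm.  Sliver cells below 10% of the
median area are merged into their largest neighbour.  A regular square
grid carries the extracellular environment; nodes are tagged internal
(inside the cluster hull) or external, the outer rim is an open Dirichlet
boundary (fixed bath concentrations, ground potential).  Each membrane
maps conservatively to its nearest environment node — mole transfer
through the mapping is exact bookkeeping, so mass and charge cannot be
created at the interface.  Wounds remove cells mid-run; their contents
spill into the nearest environment nodes (total moles conserved across
the re-index) and the footprint reverts to open environment.

**Transport.**  Transmembrane fluxes use the constant-field
(Goldman–Hodgkin–Katz) flux equation per membrane, with the analytic
Fickian limit below |zV F/RT| = 1e-6 to avoid cancellation.  Gap-junction
and extracellular fluxes use the Scharfetter–Gummel exponential-fitting
face flux — the exact steady solution of the Nernst–Planck equation on an
edge with a linear potential, which is positivity-preserving and vanishes
exactly at the Boltzmann ratio.  Gap-junction diffusivity is
`beta_GJ0 * beta_GJ(t) * D_free` applied uniformly to all small ions over
the junctional gap `d_gj`; charged macromolecules (X-) and the balance
species do not pass.  Tight junctions scale the conductance of
environment faces crossing the cluster boundary (one face thick) by
`beta_TJ`.  Advection by electroosmotic flow uses upwinded
concentrations and is off by default.

**Charge and voltage.**  Net charge density is `rho_e = F sum z_i c_i`
over non-tracer species.  Each cell is a capacitor: `V_mem = Q_cell /
(c_mem sigma_cell)` against its local extracellular potential, with
`c_mem` = 0.022 F/m^2.  In *cytosol-only* mode the environment is
instantaneously mixed at ground, so `V_cell = V_mem`.  In *environment*
mode the extracellular potential is solved each substep as a
semi-implicit conductor network: electrolyte screens static charge within
a Debye length (`1/kappa` ~ 1 nm; self-capacitance
`c_self = eps_o eps_r kappa` ~ 0.86 F/m^2), so the bulk cannot sustain
net charge and its potential is quasi-static — `(C/dt + L_G) V_new =
(C/dt) V_old + I_inj`, where `L_G` is the graph Laplacian of face
conductances `(F^2/RT) sum z_i^2 D_i c_i` (TJ-scaled at the boundary
ring), `C` the per-node screening capacitance and `I_inj` the membrane
and diffusive charge currents.  This is the discrete expression of the
bulk-electroneutrality correction that also underlies the corrected
current density (`J = J_o - grad psi`, computed as a divergence-free
projection with the charge-density rate as source).  The full Maxwell
capacitance matrix over cells and internal environment nodes — mutual
couplings `c_mem A_mem`, per-conductor self-capacitance `c_self A`,
pseudo-inverted by SVD — is implemented and cross-checked in the voltage
module (`engine.capacitance_system`); the engine's conductor formulation
is its stable quasi-static limit.  An isolated cell in an open bath rests
at the same `V_mem` in both modes to within 3 mV.

**Pumps.**  The Na/K-ATPase exports 3 Na+ and imports 2 K+ per ATP.  Its
rate is saturable Michaelis–Menten in intracellular Na+ (K = 5 mol/m^3),
extracellular K+ (0.2) and ATP (0.15), times a thermodynamic factor
`(1 - Omega/K_eqm)` built from the reaction free energy
`dG = dG_ATP + RT ln(Omega) - F V_mem`: the pump stalls exactly where the
free energy vanishes and reverses past it.  The `-F V_mem` term is the
electrical work of the one net positive charge exported per cycle, so
pumping is harder at more negative potentials.  Fixed pools ATP = 1.5,
ADP = 0.1, P_i = 1.0 mol/m^3 give an in-vivo ATP free energy of about
-44 kJ/mol (from the standard -37 kJ/mol); the inorganic-phosphate pool
follows the cytosolic norm (~1 mM) rather than smaller values sometimes
used, which overstate the pump's driving force.  Maximum rate
`alpha_pump` = 2.0e-7 mol/(s m^2).

**Channels.**  Voltage-gated channels modulate the membrane *diffusivity*
for their ion: `D_mem(t) = D_max * product(gates^exponents)`, with gates
advanced by the exact exponential (Rush–Larsen) update, unconditionally
within [0, 1].  The NaV uses the classic squid-type m^3 h rates
(activation ramp near -40 mV, inactivation recovering below about
-60 mV).  The delayed-rectifier KV1.2 uses n^4 with the classic
delayed-rectifier activation position (closed below about -55 mV) and the
published KV1.2 deactivation time constant (about 90-150 ms below
threshold, a few ms at spike peak), plus the channel's very slow
(~10 s) inactivation gate.  This pairing was selected among published
candidate forms because it is the one that reproduces the qualitative
excitability phenotypes the scenarios are defined by (see "Excitability"
below); the exact rate tables of the original studies are not published
in the primary text, and all rates live in one module so alternatives
can be swapped.  Ligand-gated (acetylcholine-like) and calcium-gated
channels use a Hill form on the local extracellular (or cytosolic)
ligand concentration.

**Gap-junction gating.**  Optionally, junctions close with the voltage
difference between the coupled cells: steady open fraction
`beta_min + (1-beta_min) / (1 + exp((|V_GJ| - 15 mV)/4 mV))` with
`beta_min` = 0.04, relaxing with a 0.5 s time constant.  The response to
|V_GJ| (bipolar gating) and the slope/floor/time constant are
reconstructions around the stated 15 mV half-closure point.

**Electroosmosis.**  The electric body force `rho_e E` in narrow channels
(GJ pores r ~ 6.5 nm; cleft half-width ~ 12.5 nm) drives a
Hagen–Poiseuille-type velocity `u_o = (r^2 / 8 mu) F_e` (normalised per
channel cross-section so a volume force yields a velocity), projected to
the divergence-free subspace via the same machinery as the currents.

**Time stepping.**  Operator-split explicit stepping: interventions, then
gates, then the flux set, then conservative concentration updates, then
charges and voltages, then (optionally) flows.  A requested step is
internally divided into substeps no longer than 0.4x the fastest
charge-relaxation time (transmembrane conductance against `c_mem`, and
gap-junction conductance between cell capacitors), with an
instability-triggered retry at finer subdivision; irrecoverable blow-up
raises a diagnostic naming the offending field and a workable step size.
Defaults: dt = 0.05 s (leak-only), 5e-5 s when Hodgkin–Huxley channels
are active.  Voltage clamps and stimulus currents act through an explicit
injected-electrode-charge ledger so the concentration bookkeeping stays
conservative; injected charge persists after the stimulus and dissipates
through ordinary fluxes.

## Charge bookkeeping of printed ion tables

Printed physiological tables are rarely exactly electroneutral (they
round, and omit minor species).  A designated low-permeability balance
anion and cation absorb the residual charge of each compartment at
initialisation, so the tabulated major-ion values are used verbatim while
the canonical "equal concentrations, V_mem = 0 everywhere" start holds
exactly.  Extracellular regions carry grid-cell-scale electrolyte volumes
(v_ecm of order the cell volume, as in the parameter table), while
*conduction* between internal regions threads the thin paracellular
clefts (open fraction `d_ecm / 2 r_cell`).  With literal nm-scale cleft
volumes the extracellular composition slews on millisecond timescales
and no sustained transepithelial potential is possible.

## Scenario presets and calibrations

The leak-permeability profiles A/B/C (high/medium/low K+ leak) are
reconstructions: the study figures plot but do not print them.  Only the
oocyte profile is fully printed (P_Na 0.537, P_K 1.765, P_Cl 0.138 nm/s)
and profile B is kept at that scale.  With the equal-concentration plasma
start, exact electroneutrality caps the achievable hyperpolarization near
-60 mV (the interior fixed-charge inventory bounds K+ accumulation), so
the A/B/C resting potentials compress relative to the published
-84/-58/-5 mV while preserving the ordering and the dye/Goldman
concordance.

*Excitability* (35-cell cluster, GJ-coupled, no TJ): the resting
potential is the independent variable, set by root-finding the K+ leak
permeability against a closed-form single-cell resting-state solver
(per-ion flux balance incl. pump stoichiometry plus charge consistency).
The stimulus is a 0.4 nA current injection into one cell for 1-200 ms.
At -70 mV rest the cluster spikes only during the injection and returns
to rest; at -18 mV rest it sustains a relaxation oscillation whose
~90 ms period is paced by the slow KV1.2 deactivation plus the
leak-limited climb back to threshold; at -57 mV rest with a 10x KV1.2
deficit a single stimulus flips the tissue into a stable depolarized
rest near -18 mV maintained by the NaV window current — a bistability of
the resting state.

*Transepithelial potential* (~320-cell disc, reduced from the published
794; beta_TJ = 1e-5, beta_GJ0 = 1e-7, medium-K+ profile, active pump;
20 simulated minutes): the sealed boundary forces the pump-driven
transcellular current loop through the high-resistance TJ ring and lets
K+ accumulate in the internal extracellular network, producing an
inside-positive trans-boundary potential.  The simulated value (~+14 mV)
sits below the published ~24 mV; the magnitude is controlled by the
unprinted absolute permeability scale and pump calibration, and grows
with cluster size through the interior-area to perimeter ratio.  The
beta_TJ = 1 control yields no trans-boundary potential.

*Oocyte validation*: with the printed permeabilities and Ringer bath,
30 simulated minutes yield V_mem ~ -38 mV (printed -37.6, measured
-39.1) and intracellular K+/Cl- within a few percent of measurement;
intracellular Na+ settles near 8.9 mmol/L versus the measured 10.1
(-12%), reflecting the unprinted oocyte-specific pump-rate calibration
of the original study.

## What the generator does and does not emulate

Synthetic worlds are irregular-but-homogeneous 2-D monolayers with ideal
Dirichlet baths and identical cells per profile.  They do not include
cell-size heterogeneity beyond Voronoi jitter, membrane protein
redistribution, osmotic volume changes, organelles, or any gene-level
readout, so passing tests demonstrate the *bioelectric circuit* physics —
conservation, equilibrium laws, attractor structure, junctional coupling
effects — not fidelity to any particular tissue's quantitative biology.

## Numerical choices and limitations

Direct sparse factorisations (cached per grid and refreshed when
conduction coefficients drift) with 1e-9-class tolerances; pure-Neumann
null spaces pinned by the volume-weighted mean; negative concentrations
(possible only through the conservative-clip guard) are clipped with a
warning and never exceeded 1e-3 mol/m^3 in any shipped scenario; SVD
pseudo-inverse cutoff 1e-12.  Known limitations: explicit coupling makes
high-permeability membranes expensive (substepping scales with
`sum P_i c_i`); the environment raster coarsens per-junction
extracellular microdomains to one conductor per grid node; no osmotic
water flow, so long runs drift slowly as compositions equilibrate; and
reported excitability periods inherit the uncertainty of the adopted
channel rate functions.
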