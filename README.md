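# biovolt

A finite-volume simulator of **bioelectric tissue state**: transmembrane
potentials, transepithelial potentials, endogenous ionic currents, and
their emergent spatial patterning in two-dimensional clusters of
gap-junction-coupled cells.

Non-neural cells regulate a resting membrane potential (V_mem), and
spatial patterns of V_mem act as instructive signals in development,
regeneration and cancer.  `biovolt` is built for researchers who want to
ask *mechanistic* questions about those patterns — what combination of
ion channels, pumps, gap junctions (GJ) and tight junctions (TJ) produces
a given voltage pattern, and what happens when it is perturbed — without
prescribing any voltage by hand.

## The model in brief

Ions (Na⁺, K⁺, Cl⁻, Ca²⁺, impermeant anions X⁻, optional tracers) are the
fundamental state.  Per time step the engine:

1. evaluates transmembrane fluxes with the constant-field (GHK) flux
   equation, Φᵢ = (zᵢVF/RT)·Pᵢ·(cᵢⁱⁿ − cᵢᵒᵘᵗ e^(−zᵢVF/RT))/(1 − e^(−zᵢVF/RT)),
   plus a thermodynamically limited Na/K-ATPase
   (3 Na⁺ out : 2 K⁺ in per ATP, rate ∝ Michaelis saturation ×
   (1 − Ω/K_eqm));
2. moves ions between cells (through GJ) and between extracellular
   regions by Nernst–Planck electrodiffusion, with TJ throttling the
   boundary extracellular path;
3. updates concentrations conservatively (finite volume), reduces them to
   net charge ρₑ = F Σ zᵢcᵢ, and computes voltages: each cell is a
   capacitor (V_mem = Q_cell/(c_mem σ_cell)) against the extracellular
   potential, solved as a screened, quasi-static conductor network;
4. optionally applies Hodgkin–Huxley-style voltage-gated channels
   (NaV m³h, delayed-rectifier KV1.2 n⁴ with slow inactivation),
   ligand-gated channels, voltage-gated GJ closure, timed interventions
   (channel openings, pump block, bath changes, current injection,
   wounding) and electroosmotic flow.

Resting potentials, transepithelial potentials and wound currents are
*outcomes* of this loop, not inputs.  See `docs/methods.md` for the full
model description, parameter table rationale, and numerical choices.

## Worked example

Simulate an isolated-cell cluster with the measured *Xenopus*-oocyte
membrane permeabilities (P_Na 0.537, P_K 1.765, P_Cl 0.138 nm/s) in
Ringer's solution, starting from the measured interior, and read off the
resting potential it develops:

```python
import biovolt as bv
from biovolt.presets import preset

cfg = preset("sim1")                  # oocyte scenario, 30 simulated min
world, kwargs = bv.load_config(cfg)
result = bv.run(world, **kwargs)

vm = result.V_mem[-1, 0] * 1e3        # mV, any cell (they are identical)
i = {n: k for k, n in enumerate(result.ion_names)}
print(f"resting V_mem: {vm:.1f} mV")
print("intracellular:",
      {n: round(float(result.c_cells[-1, i[n], 0]), 1)
       for n in ("Na", "K", "Cl")})
```

Output:

```
resting V_mem: -38.0 mV
intracellular: {'Na': 8.9, 'K': 108.2, 'Cl': 35.2}
```

The cell settles at −38 mV — against the measured −39.1 mV, with
intracellular K⁺ and Cl⁻ within a few percent of measurement — with no
voltage prescribed anywhere: it emerges from the permeability profile and
the pump thermodynamics.  The same machinery runs the other presets
(`sim2` attractor states, `sim3` perturbations, `sim4a–c` excitability,
`sim5`–`sim8` multicellular TJ/GJ patterning; `biovolt.presets.PRESET_NAMES`
lists them all).

From a shell:

```bash
biovolt init sim4b            # write the scenario to sim4b.yaml
biovolt run sim4b.yaml --out out/   # CSV + HDF5 + VTK results
biovolt calc nernst --c-ext 1.0 --c-int 0.112 --z -1
```

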