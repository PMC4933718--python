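"""Engine integration: stepping, conservation, attractors, wounding."""

import numpy as np
import pytest

import biovolt as bv
from biovolt.config import build_from_config
from biovolt.physiology import goldman_vmem, nernst_vmem
from biovolt.presets import PROFILE_PMEM, preset


def _single_cell_cfg(radius=2e-5, ions="plasma", P_mem=None, pump=1.0,
                     mode="cytosol_only", **solver):
    return {
        "world": {"shape": "square", "side": 2 * radius,
                  "cell_radius": 2 * radius, "mask_pixels": 40,
                  "env_nodes": 10},
        "ions": ions,
        "profiles": [{"label": "B", "cells": "all",
                      "P_mem": P_mem or {
                          k: v for k, v in PROFILE_PMEM["B"].items()
                          if k != "Dye" or ions == "plasma"},
                      "pump_scale": pump}],
        "solver": {"mode": mode, "beta_gj": 0.0, "t_end": 10.0, **solver},
    }


class TestStepBasics:
    def test_equilibrium_is_a_fixed_point(self):
        """Equal concentrations, no pump, V=0: one step is the identity
        up to round-off."""
        world, _ = build_from_config(_single_cell_cfg(pump=0.0))
        s = bv.initial_state(world)
        before = s.c_cells.copy()
        s = bv.step(s, 0.05, world)
        assert np.array_equal(s.c_cells, before) or np.allclose(
            s.c_cells, before, rtol=1e-14)
        assert np.allclose(s.V_mem, 0.0, atol=1e-15)

    def test_determinism(self):
        world, kwargs = build_from_config(_single_cell_cfg(t_end=5.0))
        r1 = bv.run(world, **{**kwargs, "record_dt": 1.0})
        world2, kwargs2 = build_from_config(_single_cell_cfg(t_end=5.0))
        r2 = bv.run(world2, **{**kwargs2, "record_dt": 1.0})
        assert np.array_equal(r1.V_mem, r2.V_mem)
        assert np.array_equal(r1.c_cells, r2.c_cells)

    def test_zero_t_end_returns_initial_state_only(self):
        world, _ = build_from_config(_single_cell_cfg())
        res = bv.run(world, t_end=0.0, dt=0.05)
        assert len(res.times) == 1 and res.times[0] == 0.0

    def test_local_truncation_order(self):
        """Step-halving oracle: the one-step error of the explicit update
        shrinks ~4x when dt halves (O(dt^2) locally)."""
        def advance(dt, n):
            world, _ = build_from_config(_single_cell_cfg())
            s = bv.initial_state(world)
            for _ in range(n):
                s = bv.step(s, dt, world, in_place=True)
            return s.V_mem[0]

        v_ref = advance(2.5e-4, 16)
        e1 = abs(advance(2e-3, 2) - v_ref)
        e2 = abs(advance(1e-3, 4) - v_ref)
        assert e1 / e2 > 1.8

    def test_instability_diagnostic(self):
        world, _ = build_from_config(_single_cell_cfg())
        s = bv.initial_state(world)
        with pytest.raises(bv.EngineInstability, match="reduce dt"):
            bv.step(s, 1e4, world)


class TestConservation:
    def test_closed_system_conserves_moles_and_charge(self, hex7_world):
        """1000 steps with pumps on and a sealed boundary: every ion's
        total mole count and the total charge are conserved to 1e-9
        relative (finite-volume antisymmetry)."""
        cfg = bv.generate_fixture("hex7", 0)[1]
        cfg["solver"]["mode"] = "environment"
        cfg["solver"]["closed_boundary"] = True
        world, _ = build_from_config(cfg)
        s = bv.initial_state(world)

        def totals(s):
            return (s.c_cells @ world.cell_grid.cell_volumes
                    + s.c_env @ world.env_node_volumes)

        t0 = totals(s)
        for _ in range(1000):
            s = bv.step(s, 0.01, world, in_place=True)
        t1 = totals(s)
        assert np.allclose(t1, t0, rtol=1e-9)
        z = np.array([0 if i.tracer else i.z for i in world.ions], float)
        assert abs(z @ t1 - z @ t0) <= 1e-9 * np.abs(t0).sum()


class TestRestingPhysiology:
    def test_pump_block_converges_to_goldman(self):
        """With the pump silenced the quasi-steady V_mem must satisfy the
        zero-current (Goldman) condition to within 1 mV."""
        cfg = _single_cell_cfg(ions="physio", t_end=80.0, dt=0.05,
                               start_at_rest=True)
        cfg["interventions"] = [{"t_start": 20.0, "t_end": 75.0,
                                 "action": "block_pump"}]
        world, kwargs = build_from_config(cfg)
        res = bv.run(world, **{**kwargs, "record_dt": 1.0})
        i = {n: k for k, n in enumerate(res.ion_names)}
        k70 = np.argmin(np.abs(res.times - 70.0))
        cc = res.c_cells[k70][:, 0]
        prof = world.profiles[0].P_mem
        gv = goldman_vmem({"Na": prof["Na"], "K": prof["K"]},
                          {"Cl": prof["Cl"]},
                          {n: cc[i[n]] for n in ("Na", "K", "Cl")},
                          {n: world.c_bath[i[n]] for n in
                           ("Na", "K", "Cl")}, world.params.T)
        assert abs(res.V_mem[k70, 0] - gv) < 1e-3

    def test_resting_vmem_is_an_attractor(self):
        """Two strongly divergent permeant-ion initial conditions (the
        equal-concentration start vs a shuffled Na/K/Cl split with the
        same impermeant interior content) converge to the same resting
        V_mem within 1 mV.  Small cells are used so concentrations relax
        well inside the simulated 20 minutes."""
        common = [
            {"name": "X", "z": -1, "c_in": 80.0, "c_out": 10.0,
             "gj_mobile": False},
            {"name": "M", "z": -1, "c_in": 0.0, "c_out": 37.0,
             "gj_mobile": False},
            {"name": "Mp", "z": 1, "c_in": 33.0, "c_out": 0.0,
             "gj_mobile": False},
        ]
        starts = [  # both electroneutral with the same fixed interior
            [{"name": "Na", "z": 1, "c_in": 145.0, "c_out": 145.0},
             {"name": "K", "z": 1, "c_in": 5.0, "c_out": 5.0},
             {"name": "Cl", "z": -1, "c_in": 103.0, "c_out": 103.0}],
            [{"name": "Na", "z": 1, "c_in": 20.0, "c_out": 145.0},
             {"name": "K", "z": 1, "c_in": 80.0, "c_out": 5.0},
             {"name": "Cl", "z": -1, "c_in": 53.0, "c_out": 103.0}],
        ]
        finals = []
        for perm in starts:
            cfg = _single_cell_cfg(radius=1e-6, ions=perm + common,
                                   P_mem={"Na": 0.15e-9, "K": 1.9e-9,
                                          "Cl": 0.5e-9},
                                   t_end=1200.0, dt=0.05)
            world, kwargs = build_from_config(cfg)
            res = bv.run(world, **{**kwargs, "record_dt": 60.0})
            finals.append(res.V_mem[-1, 0])
        assert abs(finals[0] - finals[1]) < 1e-3

    def test_dye_reads_out_vmem_via_nernst(self):
        """A z=-1 tracer equilibrates to the Nernst relation against the
        directly computed V_mem within 1 mV."""
        cfg = _single_cell_cfg(radius=1e-6, ions="plasma", t_end=900.0,
                               dt=0.05)
        world, kwargs = build_from_config(cfg)
        res = bv.run(world, **{**kwargs, "record_dt": 60.0})
        i = {n: k for k, n in enumerate(res.ion_names)}
        dye_in = res.final_state.c_cells[i["Dye"], 0]
        v_dye = nernst_vmem(1e-3, dye_in, -1, world.params.T)
        assert abs(v_dye - res.V_mem[-1, 0]) < 1e-3

    def test_environment_and_cytosol_modes_agree(self):
        """An isolated cell in a large open bath rests at the same V_mem
        (within 3 mV) whether the environment is resolved or assumed
        instantaneously mixed."""
        finals = []
        for mode in ("cytosol_only", "environment"):
            cfg = _single_cell_cfg(ions="physio", mode=mode, t_end=60.0,
                                   dt=0.02, start_at_rest=True)
            world, kwargs = build_from_config(cfg)
            res = bv.run(world, **kwargs)
            finals.append(res.V_mem[-1, 0])
        assert abs(finals[0] - finals[1]) < 3e-3

    def test_perturbation_recovery(self):
        """V_mem returns to the unperturbed trajectory within 1 mV after
        a transient permeability intervention ends."""
        base = _single_cell_cfg(ions="physio", t_end=60.0, dt=0.05,
                                start_at_rest=True)
        pert = {**base, "interventions": [
            {"t_start": 5.0, "t_end": 7.0, "action": "scale_permeability",
             "ion": "Na", "factor": 25.0}]}
        vs = []
        for cfg in (base, pert):
            world, kwargs = build_from_config(cfg)
            res = bv.run(world, **{**kwargs, "record_dt": 1.0})
            vs.append(res.V_mem[:, 0])
        # deviates during the event, rejoins afterwards
        t = np.arange(len(vs[0]))
        during = (t >= 5) & (t <= 7)
        assert np.abs(vs[0][during] - vs[1][during]).max() > 5e-3
        assert abs(vs[0][-1] - vs[1][-1]) < 1e-3


class TestWound:
    def test_wound_conserves_moles_and_depolarizes_neighbours(self):
        world, cfg = bv.generate_fixture("wounded_disc", 1)
        world, kwargs = build_from_config(cfg)
        t_w, mask = kwargs["wound_at"]
        s = bv.initial_state(world)
        for _ in range(int(10.0 / 0.05)):
            s = bv.step(s, 0.05, world, in_place=True)
        pre_totals = (s.c_cells @ world.cell_grid.cell_volumes
                      + s.c_env @ world.env_node_volumes)
        pre_vm = s.V_mem.copy()
        pre_grid = world.cell_grid
        s2, world2 = bv.wound(s, world, mask)
        post_totals = (s2.c_cells @ world2.cell_grid.cell_volumes
                       + s2.c_env @ world2.env_node_volumes)
        assert np.allclose(post_totals, pre_totals, rtol=1e-9)
        # survivors adjacent to the wound gained boundary membranes
        kept = s2.kept_cells
        newly_boundary = (world2.cell_grid.boundary_flags.sum()
                          > pre_grid.boundary_flags[np.isin(
                              pre_grid.membrane_to_cell, kept)].sum())
        assert newly_boundary
        # and develop depolarized V_mem relative to pre-wound
        for _ in range(int(10.0 / 0.05)):
            s2 = bv.step(s2, 0.05, world2, in_place=True)
        adjacent = np.unique(world2.cell_grid.membrane_to_cell[
            world2.cell_grid.boundary_flags])
        vm_cell_pre = np.zeros(pre_grid.n_cells)
        np.add.at(vm_cell_pre, pre_grid.membrane_to_cell, pre_vm)
        counts = np.bincount(pre_grid.membrane_to_cell)
        vm_cell_pre /= counts
        vm_new = np.zeros(world2.cell_grid.n_cells)
        np.add.at(vm_new, world2.cell_grid.membrane_to_cell, s2.V_mem)
        vm_new /= np.bincount(world2.cell_grid.membrane_to_cell)
        # compare the most wound-affected survivors against their own
        # pre-wound potentials
        shift = vm_new - vm_cell_pre[kept]
        assert shift.max() > 1e-3   # someone depolarized by >1 mV


class TestGJConnectivity:
    def test_na_patch_depolarizes_more_at_low_gj_connectivity(self):
        """Direction-of-effect: a 15x Na-permeable patch shifts its own
        resting V_mem substantially more when GJ coupling is weak."""
        shifts = {}
        for name in ("sim6_low", "sim6_high"):
            cfg = preset(name)
            cfg["world"]["diameter"] = 50e-6
            world, kwargs = build_from_config(cfg)
            res = bv.run(world, **kwargs)
            patch = world.schedule.events[0].cells
            shifts[name] = (res.V_mem[-1, patch].mean()
                            - res.V_mem[0, patch].mean())
        assert shifts["sim6_low"] > shifts["sim6_high"] + 5e-3
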