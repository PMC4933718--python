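"""State initialisation, interventions, configuration and fixtures."""

import numpy as np
import pytest

import biovolt as bv
from biovolt.config import build_from_config
from biovolt.params import ParameterSet
from biovolt.presets import (PRESET_NAMES, plasma_ions, preset,
                             ringer_ions)
from biovolt.state import (Intervention, InterventionSchedule,
                           apply_interventions, balanced_concentrations)


class TestInitState:
    def test_equal_start_is_electroneutral_and_zero_voltage(
            self, hex7_world):
        s = bv.initial_state(hex7_world)
        rho = bv.charge_density(s.c_cells, hex7_world.ions)
        assert np.abs(rho).max() < 1e-9
        assert np.allclose(s.V_mem, 0.0)
        assert np.allclose(s.V_cell, 0.0)

    def test_table_concentrations_preserved(self):
        """The printed plasma values are used verbatim for the major ions
        (Na 145, K 5, Cl 105, X 80 intra)."""
        ions = plasma_ions()
        by = {ion.name: ion for ion in ions}
        assert by["Na"].c_in == 145.0 and by["K"].c_in == 5.0
        assert by["Cl"].c_in == 105.0 and by["X"].c_in == 80.0
        c_in, c_out = balanced_concentrations(ions)
        z = np.array([0 if i.tracer else i.z for i in ions], float)
        assert abs(z @ c_in) < 1e-12
        assert abs(z @ c_out) < 1e-12

    def test_identical_profiles_identical_state(self, hex7_world):
        s = bv.initial_state(hex7_world)
        assert np.allclose(s.c_cells, s.c_cells[:, :1])

    def test_profiles_must_cover_cells(self, hex7_world):
        from biovolt.state import Profile, membrane_diffusivity_base
        bad = [Profile("A", np.arange(3), {"Na": 1e-10})]
        with pytest.raises(ValueError, match="cover"):
            membrane_diffusivity_base(hex7_world.cell_grid,
                                      hex7_world.ions, bad,
                                      hex7_world.params)


class TestInterventions:
    def _schedule(self):
        return InterventionSchedule([
            Intervention(1.0, 3.0, "scale_permeability", ion="Na",
                         factor=25.0),
            Intervention(5.0, 6.0, "block_pump"),
            Intervention(7.0, 8.0, "set_boundary_concentration", ion="K",
                         value=40.0),
        ])

    def test_inactive_schedule_leaves_state_alone(self, hex7_world):
        s = bv.initial_state(hex7_world)
        apply_interventions(s, self._schedule(), 0.5, hex7_world.ions)
        assert np.allclose(s.perm_scale, 1.0)
        assert not s.pump_blocked and not s.boundary_conc

    def test_events_apply_and_revert(self, hex7_world):
        s = bv.initial_state(hex7_world)
        ions = hex7_world.ions
        iNa = hex7_world.ion_index["Na"]
        apply_interventions(s, self._schedule(), 2.0, ions)
        assert np.allclose(s.perm_scale[iNa], 25.0)
        apply_interventions(s, self._schedule(), 3.0, ions)
        assert np.allclose(s.perm_scale, 1.0)  # exact reversal at t_end
        apply_interventions(s, self._schedule(), 5.5, ions)
        assert s.pump_blocked
        apply_interventions(s, self._schedule(), 7.5, ions)
        assert s.boundary_conc == {hex7_world.ion_index["K"]: 40.0}
        assert not s.pump_blocked

    def test_contradictory_overlap_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            InterventionSchedule([
                Intervention(1.0, 5.0, "scale_permeability", ion="Na",
                             factor=25.0),
                Intervention(3.0, 6.0, "scale_permeability", ion="Na",
                             factor=2.0),
            ])

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError, match="t_start"):
            InterventionSchedule([Intervention(3.0, 1.0, "block_pump")])
        with pytest.raises(ValueError, match="unknown"):
            InterventionSchedule([Intervention(0.0, 1.0, "explode")])

    def test_state_copy_roundtrip(self, hex7_world):
        s = bv.initial_state(hex7_world)
        s2 = s.copy()
        s2.c_cells[0, 0] += 1.0
        assert s.c_cells[0, 0] != s2.c_cells[0, 0]


class TestConfig:
    def test_minimal_config_builds(self):
        cfg = {
            "world": {"shape": "square", "side": 2e-5,
                      "cell_radius": 2e-5, "mask_pixels": 40,
                      "env_nodes": 8},
            "ions": "plasma",
            "profiles": [{"label": "B", "cells": "all",
                          "P_mem": {"K": 1e-9}}],
            "solver": {"t_end": 1.0},
        }
        world, kwargs = build_from_config(cfg)
        assert world.cell_grid.n_cells == 1
        assert kwargs["t_end"] == 1.0

    def test_unknown_key_rejected_with_path(self):
        cfg = {"wrld": {}}
        with pytest.raises(ValueError, match="wrld"):
            build_from_config(cfg)

    def test_negative_permeability_rejected(self):
        cfg = {
            "world": {"shape": "square", "side": 2e-5,
                      "cell_radius": 2e-5, "mask_pixels": 40},
            "ions": "plasma",
            "profiles": [{"label": "B", "cells": "all",
                          "P_mem": {"K": -1e-9}}],
        }
        with pytest.raises(ValueError, match="negative permeability"):
            build_from_config(cfg)

    def test_unknown_ion_in_profile_rejected(self):
        cfg = {
            "world": {"shape": "square", "side": 2e-5,
                      "cell_radius": 2e-5, "mask_pixels": 40},
            "ions": "plasma",
            "profiles": [{"label": "B", "cells": "all",
                          "P_mem": {"Xx": 1e-9}}],
        }
        with pytest.raises(ValueError, match="unknown ion"):
            build_from_config(cfg)

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_presets_validate(self, name):
        cfg = preset(name)
        if name in ("sim4a", "sim4b", "sim4c"):
            # tuning inside the build is exercised elsewhere; keep this a
            # schema check by replacing the tuned leak with a fixed value
            cfg["profiles"][0]["tune_K_to_vmem"] = None
            cfg["profiles"][0]["P_mem"]["K"] = 1e-9
        if name == "sim7":
            cfg["world"]["diameter"] = 70e-6  # schema check at small size
        world, kwargs = build_from_config(cfg)
        assert world.cell_grid.n_cells >= 1


class TestFixtures:
    def test_fixture_determinism_and_kinds(self):
        w1, c1 = bv.generate_fixture("two_profile_disc", 3)
        w2, c2 = bv.generate_fixture("two_profile_disc", 3)
        assert np.array_equal(w1.cell_grid.cell_centers,
                              w2.cell_grid.cell_centers)
        assert c1 == c2
        with pytest.raises(KeyError):
            bv.generate_fixture("nonsense", 0)

    def test_two_profile_disc_covers_all_cells(self):
        world, _ = bv.generate_fixture("two_profile_disc", 1)
        covered = np.concatenate([p.cells for p in world.profiles])
        assert sorted(covered) == list(range(world.cell_grid.n_cells))
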