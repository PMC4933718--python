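"""Configuration parsing and validation.

A configuration is a YAML document (or equivalent dict) with sections

* ``world`` — cluster shape (disc / square / inline mask raster), target
  cell radius, RNG seed, raster and environment-grid resolution;
* ``ions`` — a named physiological set ("plasma", "ringer",
  "plasma+ligand") or an explicit list of ion specs;
* ``profiles`` — membrane permeability profiles with cell-selection
  rules, pump scaling and channel declarations;
* ``solver`` — time step, end time, simulation mode and any physical
  parameter overrides (all `ParameterSet` fields are accepted);
* ``interventions`` — timed perturbations;
* ``wound`` — an optional mid-run wound event.

``build_from_config`` returns ``(world, run_kwargs)`` ready for
``engine.run``.  Validation errors name the offending field path.
"""

from __future__ import annotations

import numpy as np
import yaml

from .engine import World, build_world
from .geometry import (RegionMask, build_cell_grid, build_env_grid,
                       cell_grid_from_seeds, disc_mask, square_mask)
from .params import ParameterSet
from .state import Intervention, InterventionSchedule, IonSpec, Profile

__all__ = ["load_config", "build_from_config", "config_from_yaml"]

_TOP_KEYS = {"world", "ions", "profiles", "solver", "interventions",
             "wound", "outputs", "name"}
_WORLD_KEYS = {"shape", "diameter", "side", "cell_radius", "seed",
               "mask_pixels", "env_nodes", "hex7", "mask", "mask_file",
               "extent"}
_PROFILE_KEYS = {"label", "cells", "P_mem", "pump_scale", "channels",
                 "tune_K_to_vmem"}
_RUN_KEYS = {"t_end", "dt", "record_dt", "snapshot_dt", "init_phase",
             "init_dt", "start_at_rest"}


def _check_keys(d: dict, allowed: set, path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} "
                         f"at {path}")


def config_from_yaml(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} is not a mapping")
    return cfg


def _build_mask(w: dict) -> RegionMask:
    shape = w.get("shape", "disc")
    n_px = int(w.get("mask_pixels", 120))
    if shape == "disc":
        return disc_mask(float(w["diameter"]), n_pixels=n_px)
    if shape == "square":
        return square_mask(float(w["side"]), n_pixels=n_px)
    if shape == "mask":
        if "mask_file" in w:
            # binary image (PNG/BMP): white = included; image row 0 is the
            # top, so flip to the bottom-origin world convention
            from imageio.v3 import imread
            img = np.asarray(imread(w["mask_file"]))
            if img.ndim == 3:
                img = img[..., :3].mean(axis=-1)
            pixels = img[::-1] > img.max() / 2.0
        else:
            pixels = np.asarray(w["mask"], dtype=bool)
        return RegionMask(pixels, tuple(w["extent"]))
    raise ValueError(f"world.shape: unknown shape {shape!r}")


def _hex7_grid(mask: RegionMask, radius: float, h: float, d_gj: float):
    wx, wy = mask.extent
    c = np.array([wx / 2, wy / 2])
    a = radius * np.sqrt(2 * np.pi / np.sqrt(3.0))
    ang = np.arange(6) * np.pi / 3.0
    seeds = np.vstack([c, c + a * np.column_stack([np.cos(ang),
                                                   np.sin(ang)])])
    return cell_grid_from_seeds(seeds, mask, h=h, d_gj=d_gj)


def _resolve_cells(spec, grid, claimed: np.ndarray, n_bands: int,
                   path: str) -> np.ndarray:
    wx, wy = grid.world_extent
    if isinstance(spec, str):
        if spec == "all":
            return np.arange(grid.n_cells)
        if spec == "rest":
            return np.flatnonzero(~claimed)
        raise ValueError(f"{path}: unknown cell selector {spec!r}")
    if isinstance(spec, dict):
        if "disc_frac" in spec:
            cx, cy, r = spec["disc_frac"]
            d = grid.cell_centers - np.array([cx * wx, cy * wy])
            return np.flatnonzero(np.hypot(d[:, 0], d[:, 1])
                                  <= r * max(wx, wy))
        if "band" in spec:
            k = int(spec["band"])
            x = grid.cell_centers[:, 0]
            edges = np.quantile(x, np.linspace(0, 1, n_bands + 1))
            lo, hi = edges[k], edges[k + 1]
            sel = (x >= lo) & (x <= hi if k == n_bands - 1 else x < hi)
            return np.flatnonzero(sel)
        raise ValueError(f"{path}: unknown cell selector {spec}")
    return np.asarray(spec, dtype=int)


def _ion_set(spec) -> list[IonSpec]:
    from .presets import ION_SETS, plasma_ions
    if isinstance(spec, str):
        if spec == "plasma+ligand":
            ions = plasma_ions()
            ions.append(IonSpec("L", 1, c_in=1e-3, c_out=1e-3,
                                tracer=True))
            return ions
        if spec in ION_SETS:
            return ION_SETS[spec]()
        raise ValueError(f"ions: unknown ion set {spec!r}")
    return [IonSpec(**d) for d in spec]


def build_from_config(cfg: dict):
    """Validate a configuration and build ``(world, run_kwargs)``."""
    from .presets import resting_state, tune_k_leak

    _check_keys(cfg, _TOP_KEYS, "top level")
    w = dict(cfg.get("world", {}))
    _check_keys(w, _WORLD_KEYS, "world")
    solver = dict(cfg.get("solver", {}))
    run_kwargs = {k: solver.pop(k) for k in list(solver)
                  if k in _RUN_KEYS}
    start_at_rest = bool(run_kwargs.pop("start_at_rest", False))
    try:
        params = ParameterSet(**{**solver,
                                 "t_end": run_kwargs.get("t_end", 60.0)})
    except TypeError as e:
        raise ValueError(f"solver: {e}") from None
    run_kwargs.setdefault("t_end", params.t_end)

    mask = _build_mask(w)
    radius = float(w.get("cell_radius", 5e-6))
    if radius <= 0:
        raise ValueError("world.cell_radius must be positive")
    if w.get("hex7"):
        grid = _hex7_grid(mask, radius, params.h, params.d_gj)
    else:
        grid = build_cell_grid(mask, radius, int(w.get("seed", 0)),
                               h=params.h, d_gj=params.d_gj)
    env_grid = build_env_grid(mask.extent, int(w.get("env_nodes", 30)),
                              grid)

    ions = _ion_set(cfg.get("ions", "plasma"))
    ion_names = {ion.name for ion in ions}

    profs_cfg = cfg.get("profiles")
    if not profs_cfg:
        raise ValueError("profiles: at least one profile required")
    n_bands = sum(1 for p in profs_cfg
                  if isinstance(p.get("cells"), dict)
                  and "band" in p["cells"])
    profiles = []
    claimed = np.zeros(grid.n_cells, dtype=bool)
    # resolve explicit selectors first so "rest" can fill the remainder
    order = sorted(range(len(profs_cfg)),
                   key=lambda i: profs_cfg[i].get("cells") == "rest")
    resolved: dict[int, np.ndarray] = {}
    for i in order:
        p = profs_cfg[i]
        _check_keys(p, _PROFILE_KEYS, f"profiles[{i}]")
        cells = _resolve_cells(p.get("cells", "all"), grid, claimed,
                               max(n_bands, 1), f"profiles[{i}].cells")
        cells = cells[~claimed[cells]]
        claimed[cells] = True
        resolved[i] = cells
    for i, p in enumerate(profs_cfg):
        P_mem = {k: v for k, v in dict(p.get("P_mem", {})).items()
                 if v is not None}
        for name, val in P_mem.items():
            if name not in ion_names:
                raise ValueError(f"profiles[{i}].P_mem: unknown ion {name}")
            if val < 0:
                raise ValueError(
                    f"profiles[{i}].P_mem.{name}: negative permeability")
        if p.get("tune_K_to_vmem") is not None:
            fit = tune_k_leak(float(p["tune_K_to_vmem"]), P_mem, ions,
                              params, p.get("pump_scale", 1.0))
            P_mem["K"] = fit["P_K"]
        profiles.append(Profile(label=p.get("label", str(i)),
                                cells=resolved[i], P_mem=P_mem,
                                pump_scale=float(p.get("pump_scale", 1.0)),
                                channels=list(p.get("channels", []))))

    if start_at_rest:
        if len(profiles) != 1:
            raise ValueError("solver.start_at_rest requires one profile")
        rest = resting_state(profiles[0].P_mem, ions, params,
                             profiles[0].pump_scale)
        new_ions = []
        for ion in ions:
            if ion.name in rest["c_in"]:
                from dataclasses import replace
                ion = replace(ion, c_in=rest["c_in"][ion.name])
            new_ions.append(ion)
        ions = new_ions

    events = []
    for j, ev in enumerate(cfg.get("interventions", [])):
        ev = dict(ev)
        cells = ev.pop("cells", None)
        if cells is not None and not isinstance(cells, (list, np.ndarray)):
            cells = _resolve_cells(cells, grid, np.zeros(grid.n_cells,
                                                         bool),
                                   1, f"interventions[{j}].cells")
        if ev.get("ion") is not None and ev["ion"] not in ion_names:
            raise ValueError(f"interventions[{j}].ion: unknown ion "
                             f"{ev['ion']}")
        events.append(Intervention(cells=None if cells is None
                                   else np.asarray(cells, int), **ev))
    schedule = InterventionSchedule(events)

    world = build_world(grid, ions, profiles, params, schedule=schedule,
                        env_grid=env_grid)

    wound_cfg = cfg.get("wound")
    if wound_cfg:
        cx, cy, r = wound_cfg["disc_frac"]
        wx, wy = mask.extent
        # build the wound raster directly on the world extent
        n_px = int(w.get("mask_pixels", 120))
        pxs = wx / n_px
        cgrid = (np.arange(n_px) + 0.5) * pxs
        xx, yy = np.meshgrid(cgrid, cgrid)
        pix = ((xx - cx * wx) ** 2 + (yy - cy * wy) ** 2
               <= (r * max(wx, wy)) ** 2)
        run_kwargs["wound_at"] = (float(wound_cfg["t"]),
                                  RegionMask(pix, (wx, wy), role="wound"))

    run_kwargs["config_echo"] = cfg
    return world, run_kwargs


def load_config(path_or_dict) -> tuple:
    """Load and validate a YAML configuration file (or dict)."""
    cfg = (config_from_yaml(path_or_dict)
           if not isinstance(path_or_dict, dict) else path_or_dict)
    return build_from_config(cfg)
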