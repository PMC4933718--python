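"""Result serialization: CSV time series, HDF5 full state, legacy VTK.

CSV columns follow the field's reading conventions — voltages in mV,
concentrations in mmol/L (numerically equal to mol/m^3) — while HDF5
stores the raw SI arrays losslessly.  The VTK writer emits ASCII legacy
unstructured-grid files of the cell polygons with per-cell V_mem data,
viewable in ParaView.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .engine import SimResult, World
from .state import TissueState

__all__ = ["result_frame", "write_result", "save_result_h5",
           "load_result_h5", "save_state_h5", "load_state_h5",
           "write_vtk_cells"]


def result_frame(result: SimResult) -> pd.DataFrame:
    """Time-series DataFrame: per-cell V_mem (mV) and mean concentrations."""
    cols = {"t_s": result.times}
    if result.V_mem.size:
        for c in range(result.V_mem.shape[1]):
            cols[f"Vmem_mV_cell{c}"] = result.V_mem[:, c] * 1e3
        cols["Venv_internal_mV"] = result.V_env_internal * 1e3
        for i, name in enumerate(result.ion_names):
            cols[f"c_{name}_mM_mean"] = np.nanmean(
                result.c_cells[:, i, :], axis=1)
    return pd.DataFrame(cols)


def write_result(result: SimResult, path, fmt: str = "csv",
                 world: World | None = None) -> None:
    """Write a SimResult as csv, hdf5 or vtk (vtk needs the world)."""
    if fmt == "csv":
        result_frame(result).to_csv(path, index=False)
    elif fmt in ("hdf5", "h5"):
        save_result_h5(result, path)
    elif fmt == "vtk":
        if world is None:
            raise ValueError("vtk export requires the world geometry")
        vm = result.V_mem[-1] if result.V_mem.size else None
        write_vtk_cells(world.cell_grid, path, cell_data={"Vmem_mV":
                        vm * 1e3} if vm is not None else None)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def save_result_h5(result: SimResult, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=result.times)
        f.create_dataset("V_mem", data=result.V_mem)
        f.create_dataset("V_cell", data=result.V_cell)
        f.create_dataset("V_env_internal", data=result.V_env_internal)
        f.create_dataset("c_cells", data=result.c_cells)
        f.attrs["ion_names"] = json.dumps(result.ion_names)
        f.attrs["events"] = json.dumps(
            [(float(t), str(m)) for t, m in result.events])
        f.attrs["config"] = json.dumps(result.config, default=str)
        if result.final_state is not None:
            _state_to_group(f.create_group("final_state"),
                            result.final_state)


def load_result_h5(path) -> SimResult:
    with h5py.File(path, "r") as f:
        final = (_state_from_group(f["final_state"])
                 if "final_state" in f else None)
        return SimResult(
            times=f["times"][...],
            V_mem=f["V_mem"][...],
            V_cell=f["V_cell"][...],
            V_env_internal=f["V_env_internal"][...],
            c_cells=f["c_cells"][...],
            ion_names=json.loads(f.attrs["ion_names"]),
            events=[tuple(e) for e in json.loads(f.attrs["events"])],
            config=json.loads(f.attrs["config"]),
            final_state=final,
        )


def _state_to_group(g, s: TissueState) -> None:
    g.attrs["t"] = s.t
    for name in ("c_cells", "c_env", "V_cell", "V_env", "V_mem"):
        g.create_dataset(name, data=getattr(s, name))
    if s.beta_gj is not None:
        g.create_dataset("beta_gj", data=s.beta_gj)
    if s.perm_scale is not None:
        g.create_dataset("perm_scale", data=s.perm_scale)
    gg = g.create_group("gates")
    for ch, gates in s.gates.items():
        cg = gg.create_group(ch)
        for gate, arr in gates.items():
            cg.create_dataset(gate, data=arr)


def _state_from_group(g) -> TissueState:
    s = TissueState(
        t=float(g.attrs["t"]),
        c_cells=g["c_cells"][...],
        c_env=g["c_env"][...],
        V_cell=g["V_cell"][...],
        V_env=g["V_env"][...],
        V_mem=g["V_mem"][...],
        beta_gj=g["beta_gj"][...] if "beta_gj" in g else None,
        perm_scale=g["perm_scale"][...] if "perm_scale" in g else None,
    )
    if "gates" in g:
        for ch in g["gates"]:
            s.gates[ch] = {gate: g["gates"][ch][gate][...]
                           for gate in g["gates"][ch]}
    return s


def save_state_h5(s: TissueState, path) -> None:
    """Lossless HDF5 round-trip of a tissue state."""
    with h5py.File(path, "w") as f:
        _state_to_group(f, s)


def load_state_h5(path) -> TissueState:
    with h5py.File(path, "r") as f:
        return _state_from_group(f)


def write_vtk_cells(cell_grid, path, cell_data: dict | None = None) -> None:
    """ASCII legacy-VTK unstructured grid of the cell polygons."""
    polys = cell_grid.cell_polys
    points = np.vstack(polys)
    offsets = np.cumsum([0] + [len(p) for p in polys])
    lines = ["# vtk DataFile Version 3.0", "biovolt cell grid", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(points)} double"]
    for p in points:
        lines.append(f"{p[0]:.9e} {p[1]:.9e} 0.0")
    ncell = len(polys)
    size = sum(len(p) + 1 for p in polys)
    lines.append(f"CELLS {ncell} {size}")
    for k, p in enumerate(polys):
        ids = " ".join(str(i) for i in range(offsets[k], offsets[k + 1]))
        lines.append(f"{len(p)} {ids}")
    lines.append(f"CELL_TYPES {ncell}")
    lines.extend(["7"] * ncell)  # VTK_POLYGON
    if cell_data:
        lines.append(f"CELL_DATA {ncell}")
        for name, arr in cell_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9e}" for v in np.asarray(arr, dtype=float))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
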