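"""Configuration files, result files and plots.

Configuration schema (YAML, all keys optional except ``seed``; bench units,
converted to SI on read)::

    seed: 1                     # mandatory integer
    extents_mm: [30, 20, 12]    # construct dimensions, millimetres
    element_size_mm: 1.0
    elastic_modulus_kpa: 100.0
    poisson_ratio: 0.45
    density_kg_m3: 1100.0
    total_cells: 6000000        # XOR seeding_density_per_cm3
    seeding_density_per_cm3: 5000000   # alternative cell-count input
    cells_per_agent: 100
    force_per_cell_nn: 1.0      # nanonewtons
    timestep_s: 3600
    duration_days: 7
    geometry_update: true
    snapshot_days: [0, 1, 4, 7]
    guidance_mode: tensile      # or "magnitude"
    load_mode: element          # or "dipole" (per-agent endpoint forces)

``total_cells`` and ``seeding_density_per_cm3`` are mutually exclusive ways
of stating the cell load (the reference construct is quoted both as six
million cells total and as 5e6 cells/cm3, which disagree by a factor of six;
both are exposed and neither is silently preferred).

Outputs written by :func:`write_outputs`:

- ``metrics.csv`` — one row per metric record; columns ``time_s``,
  ``projected_area_mm2``, ``area_change_percent``, ``order_parameter``,
  ``max_principal_strain``, ``mean_principal_strain``.
- ``manifest.json`` — the exact SI configuration and seed of the run;
  :func:`read_manifest` reconstructs the identical ``SimulationConfig``.
- ``mesh_day{D}.vtk`` — legacy ASCII VTK unstructured grid per snapshot:
  deformed geometry, point displacement vectors, cell-wise principal-strain
  magnitude and guidance direction.
- ``agents_day{D}.csv`` / ``agents_day{D}.vtk`` — agent point cloud
  (id, x, y, z, ox, oy, oz) and the same as VTK polydata with orientation
  vectors.
- optional ``area_timecourse.png`` — footprint area versus day.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coupling import DAY, SimulationConfig, SimulationState
from .fem import MaterialModel, principal_guidance

__all__ = [
    "load_config",
    "config_from_dict",
    "write_outputs",
    "read_manifest",
    "write_mesh_vtk",
    "write_agents_vtk",
    "plot_area_history",
]


def load_config(path) -> SimulationConfig:
    """Read a YAML configuration file (schema above) into SI units."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a bench-unit dictionary."""
    raw = dict(raw)
    if "seed" not in raw:
        raise ValueError("configuration must provide a seed")
    extents_mm = raw.pop("extents_mm", (30.0, 20.0, 12.0))
    if "total_cells" in raw and "seeding_density_per_cm3" in raw:
        raise ValueError(
            "give either total_cells or seeding_density_per_cm3, not both"
        )
    extents = tuple(float(v) * 1e-3 for v in extents_mm)
    if "seeding_density_per_cm3" in raw:
        volume_cm3 = np.prod(extents) * 1e6
        total_cells = int(round(raw.pop("seeding_density_per_cm3") * volume_cm3))
    else:
        total_cells = int(raw.pop("total_cells", 6_000_000))
    material = MaterialModel(
        elastic_modulus=float(raw.pop("elastic_modulus_kpa", 100.0)) * 1e3,
        poisson_ratio=float(raw.pop("poisson_ratio", 0.45)),
        density=float(raw.pop("density_kg_m3", 1100.0)),
    )
    known = {
        "seed": int(raw.pop("seed")),
        "extents": extents,
        "element_size": float(raw.pop("element_size_mm", 1.0)) * 1e-3,
        "material": material,
        "total_cells": total_cells,
        "cells_per_agent": int(raw.pop("cells_per_agent", 100)),
        "force_per_cell": float(raw.pop("force_per_cell_nn", 1.0)) * 1e-9,
        "timestep": float(raw.pop("timestep_s", 3600.0)),
        "duration": float(raw.pop("duration_days", 7.0)) * DAY,
        "geometry_update": bool(raw.pop("geometry_update", True)),
        "snapshot_days": tuple(float(d) for d in raw.pop("snapshot_days", (0, 1, 4, 7))),
        "guidance_mode": str(raw.pop("guidance_mode", "tensile")),
        "load_mode": str(raw.pop("load_mode", "element")),
    }
    if "reassembly_drift" in raw:
        known["reassembly_drift"] = float(raw.pop("reassembly_drift"))
    if raw:
        raise ValueError(f"unknown configuration keys: {sorted(raw)}")
    return SimulationConfig(**known)


def _config_to_manifest(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["material"] = dataclasses.asdict(config.material)
    return d


def read_manifest(path) -> SimulationConfig:
    """Reconstruct the exact SI configuration a run was executed with."""
    with open(path) as fh:
        d = json.load(fh)["config"]
    d["material"] = MaterialModel(**d["material"])
    d["extents"] = tuple(d["extents"])
    d["snapshot_days"] = tuple(d["snapshot_days"])
    return SimulationConfig(**d)


def write_outputs(
    state: SimulationState,
    out_dir,
    config: SimulationConfig | None = None,
    *,
    plot: bool = False,
) -> dict:
    """Write metrics CSV, run manifest, snapshot series and optional plot.

    Returns a dict of the paths written.  I/O failures propagate with the
    offending path in the exception.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    df = pd.DataFrame(
        {
            "time_s": [r.time for r in state.history],
            "projected_area_mm2": [r.projected_area * 1e6 for r in state.history],
            "area_change_percent": [r.area_change_percent for r in state.history],
            "order_parameter": [r.order_parameter for r in state.history],
            "max_principal_strain": [r.max_principal_strain for r in state.history],
            "mean_principal_strain": [r.mean_principal_strain for r in state.history],
        }
    )
    paths["metrics"] = out / "metrics.csv"
    df.to_csv(paths["metrics"], index=False, float_format="%.17g")

    if config is not None:
        paths["manifest"] = out / "manifest.json"
        with open(paths["manifest"], "w") as fh:
            json.dump({"config": _config_to_manifest(config)}, fh, indent=2)

    for t, snap in state.snapshots.items():
        day = t / DAY
        tag = f"day{day:g}"
        mesh_path = out / f"mesh_{tag}.vtk"
        write_mesh_vtk(mesh_path, state, snap)
        paths[f"mesh_{tag}"] = mesh_path
        apath = out / f"agents_{tag}.csv"
        _write_agents_csv(apath, snap)
        paths[f"agents_{tag}"] = apath
        vpath = out / f"agents_{tag}.vtk"
        write_agents_vtk(vpath, snap)
        paths[f"agents_vtk_{tag}"] = vpath

    if plot:
        paths["plot"] = out / "area_timecourse.png"
        plot_area_history(state.history, paths["plot"])
    return paths


def _write_agents_csv(path, snap) -> None:
    pos = snap["agent_positions"]
    ori = snap["agent_orientations"]
    df = pd.DataFrame(
        {
            "id": np.arange(pos.shape[0]),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "ox": ori[:, 0] if len(ori) else [],
            "oy": ori[:, 1] if len(ori) else [],
            "oz": ori[:, 2] if len(ori) else [],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def _vtk_header(fh, title: str, dataset: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(title + "\n")
    fh.write("ASCII\n")
    fh.write(f"DATASET {dataset}\n")


def _write_array(fh, arr: np.ndarray) -> None:
    np.savetxt(fh, np.atleast_2d(arr), fmt="%.17g")


def write_mesh_vtk(path, state: SimulationState, snap: dict) -> None:
    """Legacy ASCII VTK unstructured grid of a geometry snapshot.

    Points are the deformed node positions; point data holds the total
    displacement from the reference geometry; cell data holds the
    largest-magnitude principal value of the snapshot's incremental strain
    field and the corresponding guidance direction (zero where degenerate).
    """
    mesh = state.mesh
    coords = snap["node_coords"]
    disp = coords - mesh.node_coords
    strain = snap["strain"]
    with open(path, "w") as fh:
        _vtk_header(fh, "constructsim geometry snapshot", "UNSTRUCTURED_GRID")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        _write_array(fh, coords)
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {9 * ne}\n")
        cells = np.column_stack([np.full(ne, 8, dtype=np.intp), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {ne}\n")
        np.savetxt(fh, np.full(ne, 12, dtype=np.intp), fmt="%d")  # VTK_HEXAHEDRON
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        fh.write("VECTORS displacement double\n")
        _write_array(fh, disp)
        fh.write(f"CELL_DATA {ne}\n")
        fh.write("SCALARS principal_strain_magnitude double 1\n")
        fh.write("LOOKUP_TABLE default\n")
        if strain is None:
            mags = np.zeros(ne)
            dirs = np.zeros((ne, 3))
        else:
            mags = strain.max_abs
            dirs, degen = principal_guidance(strain)
            dirs = np.where(degen[:, None], 0.0, dirs)
        _write_array(fh, mags[:, None])
        fh.write("VECTORS principal_direction double\n")
        _write_array(fh, dirs)


def write_agents_vtk(path, snap: dict) -> None:
    """Agent point cloud with orientation vectors as legacy VTK polydata."""
    pos = snap["agent_positions"]
    ori = snap["agent_orientations"]
    n = pos.shape[0]
    with open(path, "w") as fh:
        _vtk_header(fh, "constructsim agent snapshot", "POLYDATA")
        fh.write(f"POINTS {n} double\n")
        if n:
            _write_array(fh, pos)
        fh.write(f"VERTICES {n} {2 * n}\n")
        if n:
            np.savetxt(
                fh,
                np.column_stack([np.ones(n, dtype=np.intp), np.arange(n)]),
                fmt="%d",
            )
        fh.write(f"POINT_DATA {n}\n")
        fh.write("VECTORS orientation double\n")
        if n:
            _write_array(fh, ori)


def plot_area_history(history, path) -> None:
    """Footprint area versus day, mirroring the experimental time course."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.array([r.time for r in history]) / DAY
    a = np.array([r.projected_area for r in history]) * 1e6
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(t, a, lw=1.5)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("top-view area (mm$^2$)")
    ax.set_title("Construct footprint over culture time")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
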