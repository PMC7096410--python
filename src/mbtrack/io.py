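"""File output, legacy-VTK mesh/field serialization, and test fixtures.

Outputs of a run:

* ``metrics.json``  -- scalar metrics, conservation ledger, the fully
  resolved config, its hash and the seed (deterministic key ordering, so two
  runs with equal config + seed are byte-identical);
* ``sdm.csv``       -- per-boundary-element SDM table (RFC-4180);
* ``sdm.vtk``       -- the boundary mesh with SDM as cell data, legacy VTK
  ASCII (loadable by ParaView and similar viewers);
* ``events.csv``    -- optional per-event log;
* ``trajectories.csv`` -- optional strided particle positions.

The legacy VTK ASCII format is written and read directly (it is a simple
text format); :func:`write_field_vtk` / :mod:`mbtrack.external_field` use it
to round-trip velocity-field time series.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig


def metrics_payload(result) -> dict:
    cfg = result.config
    return {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "metrics": result.metrics.to_dict(),
        "adhesion_Ka0_m2": cfg.adhesion_params().K_a0,
    }


def write_outputs(result, outdir: str | Path) -> dict[str, Path]:
    """Write metrics JSON, SDM CSV + VTK and optional logs; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    payload = metrics_payload(result)
    paths["metrics"] = outdir / "metrics.json"
    with open(paths["metrics"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    mesh = result.sdm_field.mesh
    df = pd.DataFrame({
        "element_id": np.arange(mesh.n_elements),
        "centroid_x_m": mesh.centroids[:, 0],
        "centroid_y_m": mesh.centroids[:, 1],
        "centroid_z_m": mesh.centroids[:, 2],
        "area_m2": mesh.areas,
        "region": mesh.tags,
        "adhered_count": result.sdm_field.counts,
        "sdm_per_m2": result.sdm_field.sdm,
    })
    paths["sdm_csv"] = outdir / "sdm.csv"
    df.to_csv(paths["sdm_csv"], index=False, lineterminator="\r\n")

    paths["sdm_vtk"] = outdir / "sdm.vtk"
    write_surface_vtk(paths["sdm_vtk"], mesh,
                      cell_data={"sdm_per_m2": result.sdm_field.sdm,
                                 "adhered_count":
                                 result.sdm_field.counts.astype(float)})

    if result.events:
        paths["events"] = outdir / "events.csv"
        pd.DataFrame(result.events).to_csv(paths["events"], index=False,
                                           lineterminator="\r\n")
    if result.trajectories is not None:
        rows = []
        for t, pos, status in zip(result.trajectories["t"],
                                  result.trajectories["position"],
                                  result.trajectories["status"]):
            for pid in range(len(pos)):
                rows.append((t, pid, *pos[pid], status[pid]))
        paths["trajectories"] = outdir / "trajectories.csv"
        pd.DataFrame(rows, columns=["t_s", "particle", "x_m", "y_m", "z_m",
                                    "status"]).to_csv(
            paths["trajectories"], index=False, lineterminator="\r\n")
    return paths


# -- legacy VTK ASCII -------------------------------------------------------

def write_surface_vtk(path, mesh, cell_data: dict | None = None) -> None:
    """Boundary surface as legacy VTK POLYDATA with optional cell data."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmbtrack boundary mesh\n"
                 "ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        ne = len(mesh.triangles)
        fh.write(f"POLYGONS {ne} {4 * ne}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if cell_data:
            fh.write(f"CELL_DATA {ne}\n")
            for name, values in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in values:
                    fh.write(f"{v:.9e}\n")


def write_field_vtk(path, points: np.ndarray, cells: np.ndarray,
                    velocity: np.ndarray) -> None:
    """Point cloud + tetrahedral connectivity + nodal velocity as legacy VTK
    UNSTRUCTURED_GRID (cell type 10 = tetrahedron)."""
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    velocity = np.asarray(velocity, dtype=float)
    if velocity.shape != points.shape:
        raise ValueError("velocity must be per-node, shape (n_points, 3)")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmbtrack velocity field\n"
                 "ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        fh.write(f"CELLS {len(cells)} {5 * len(cells)}\n")
        for c in cells:
            fh.write(f"4 {c[0]} {c[1]} {c[2]} {c[3]}\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        fh.writelines("10\n" for _ in cells)
        fh.write(f"POINT_DATA {len(points)}\nVECTORS velocity double\n")
        for v in velocity:
            fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")


def read_field_vtk(path):
    """Read a legacy VTK ASCII unstructured grid written by
    :func:`write_field_vtk`; returns (points, cells, velocity)."""
    path = Path(path)
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "vtk" not in lines[0]:
        raise ValueError(f"{path}: not a legacy VTK file")
    i = 0
    points = cells = velocity = None
    n = len(lines)
    while i < n:
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            cnt = int(parts[1])
            flat = " ".join(lines[i + 1:]).split()
            vals = np.array(flat[:3 * cnt], dtype=float)
            points = vals.reshape(cnt, 3)
            i += 1 + cnt
        elif key == "CELLS":
            cnt = int(parts[1])
            rows = []
            for j in range(cnt):
                row = lines[i + 1 + j].split()
                if int(row[0]) != 4:
                    raise ValueError(
                        f"{path}: only tetrahedral cells supported")
                rows.append([int(v) for v in row[1:5]])
            cells = np.array(rows, dtype=np.int64)
            i += 1 + cnt
        elif key == "VECTORS":
            # preceded by POINT_DATA <cnt>
            cnt = len(points)
            flat = " ".join(lines[i + 1: i + 1 + cnt]).split()
            velocity = np.array(flat, dtype=float).reshape(cnt, 3)
            i += 1 + cnt
        else:
            i += 1
    if points is None or velocity is None:
        raise ValueError(f"{path}: missing POINTS or velocity VECTORS")
    return points, cells, velocity


def write_waveform_csv(path, waveform, n: int = 256) -> None:
    """One period of the inlet waveform as CSV (t_s, v_m_s)."""
    t = np.linspace(0.0, waveform.period, n, endpoint=False)
    pd.DataFrame({"t_s": t, "v_m_s": waveform(t)}).to_csv(
        path, index=False, lineterminator="\r\n")


# -- fixtures ---------------------------------------------------------------

def make_fixture(kind: str) -> tuple[RunConfig, dict]:
    """Tiny deterministic scenarios for the test suite.

    ``straight_tube``: near-cylindrical domain for Poiseuille checks
    (expected wall shear rate 4 v_in / R0 at the inlet radius).
    ``small_aaa``: 50-particle smoke run over half a cycle.
    ``two_particle``: LJ pair geometry at the potential minimum.
    """
    if kind == "straight_tube":
        cfg = RunConfig.model_validate({
            "geometry": {"max_aneurysm_diameter_mm": 22.0,
                         "mesh_n_z": 20, "mesh_n_theta": 16},
            "injection": {"count_per_injection": 10, "times_s": [0.0]},
            "numerics": {"dt_s": 1e-3, "t_end_s": 0.2},
            "physics": {"brownian": False, "interaction": False},
            "seed": 7,
        })
        r0 = float(np.sqrt(cfg.geometry.inlet_area_mm2 * 1e-6 / np.pi))
        expected = {
            "wall_shear_rate_coeff": 4.0 / r0,  # times v_in(t) at the inlet
            "inlet_radius_m": r0,
        }
        return cfg, expected
    if kind == "small_aaa":
        cfg = RunConfig.model_validate({
            "geometry": {"mesh_n_z": 24, "mesh_n_theta": 16},
            "injection": {"count_per_injection": 50, "times_s": [0.0]},
            "numerics": {"dt_s": 1e-3, "t_end_s": 0.5},
            "seed": 11,
        })
        return cfg, {"total_particles": 50}
    if kind == "two_particle":
        d_p = 1.1e-6
        sigma = 0.89 * d_p
        cfg = RunConfig.model_validate({"seed": 3})
        expected = {
            "diameter_m": d_p,
            "sigma_m": sigma,
            "r_min_m": 2.0 ** (1.0 / 6.0) * sigma,
        }
        return cfg, expected
    raise ValueError(f"unknown fixture kind {kind!r}")
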