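"""Export of meshes and fields: VTK legacy ASCII and CSV.

The surface is written as POLYDATA (rings of quads), the volume as an
UNSTRUCTURED_GRID point cloud; nodal fields ride along as POINT_DATA scalars
("pressure_Pa" on the volume, "wss_Pa" on the surface).  Legacy ASCII keeps
the exports dependency-free and readable by ParaView/VTK/meshio.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import VesselGeometry
from .solver import FlowSolution

__all__ = [
    "write_surface_vtk",
    "write_volume_vtk",
    "write_radius_csv",
    "write_field_csv",
    "export_solution",
]


def _header(fh, title: str, dataset: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\n")
    fh.write(f"DATASET {dataset}\n")


def _points(fh, pts: np.ndarray) -> None:
    fh.write(f"POINTS {len(pts)} float\n")
    np.savetxt(fh, pts, fmt="%.9g")


def _point_data(fh, name: str, values: np.ndarray) -> None:
    fh.write(f"POINT_DATA {len(values)}\n")
    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
    np.savetxt(fh, values, fmt="%.9g")


def write_surface_vtk(
    path: str | Path, geom: VesselGeometry, wss: np.ndarray | None = None
) -> Path:
    """Write the wall surface as legacy POLYDATA with quad cells; optional WSS."""
    res = geom.resolution
    nax, nc = res.n_axial, res.n_circ
    path = Path(path)
    with path.open("w") as fh:
        _header(fh, f"vesselrom surface {geom.id}", "POLYDATA")
        _points(fh, geom.surface_nodes)
        nquads = (nax - 1) * nc
        fh.write(f"POLYGONS {nquads} {5 * nquads}\n")
        for i in range(nax - 1):
            for k in range(nc):
                a = i * nc + k
                b = i * nc + (k + 1) % nc
                fh.write(f"4 {a} {b} {b + nc} {a + nc}\n")
        if wss is not None:
            _point_data(fh, "wss_Pa", np.asarray(wss))
    return path


def write_volume_vtk(
    path: str | Path, geom: VesselGeometry, pressure: np.ndarray | None = None
) -> Path:
    """Write the volume nodes as a legacy UNSTRUCTURED_GRID vertex cloud."""
    path = Path(path)
    pts = geom.volume_nodes
    n = len(pts)
    with path.open("w") as fh:
        _header(fh, f"vesselrom volume {geom.id}", "UNSTRUCTURED_GRID")
        _points(fh, pts)
        fh.write(f"CELLS {n} {2 * n}\n")
        for i in range(n):
            fh.write(f"1 {i}\n")
        fh.write(f"CELL_TYPES {n}\n")
        fh.write("\n".join(["1"] * n) + "\n")
        if pressure is not None:
            _point_data(fh, "pressure_Pa", np.asarray(pressure))
    return path


def write_radius_csv(path: str | Path, geom: VesselGeometry) -> Path:
    """Radius profile as CSV (station_index, s_mm, r_mm)."""
    path = Path(path)
    pd.DataFrame(
        {
            "station_index": np.arange(geom.stations.size),
            "s_mm": geom.stations,
            "r_mm": geom.radius,
        }
    ).to_csv(path, index=False)
    return path


def write_field_csv(path: str | Path, values: np.ndarray) -> Path:
    """Nodal field as CSV (node_id, value)."""
    path = Path(path)
    values = np.asarray(values)
    pd.DataFrame({"node_id": np.arange(values.size), "value": values}).to_csv(
        path, index=False
    )
    return path


def export_solution(outdir: str | Path, geom: VesselGeometry, sol: FlowSolution) -> None:
    """Write surface+volume VTK and per-field CSVs for one solved mesh."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_surface_vtk(outdir / f"{geom.id}_surface.vtk", geom, sol.wss)
    write_volume_vtk(outdir / f"{geom.id}_volume.vtk", geom, sol.pressure)
    write_field_csv(outdir / f"{geom.id}_pressure.csv", sol.pressure)
    write_field_csv(outdir / f"{geom.id}_wss.csv", sol.wss)
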