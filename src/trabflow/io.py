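"""File I/O: legacy ASCII VTK polydata, STL surfaces, CSV tables.

Boundary time series are written one file per frame with zero-padded
frame indices; node identity is preserved as VTK point data and as a
sidecar CSV of frame-invariant labels. Extruded 3D surfaces go to STL
(binary via trimesh, or ASCII).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import MovingBoundary
from .metrics import extrude_boundary

__all__ = ["write_mesh_series", "write_labels_csv", "write_wss_csv",
           "read_vtk_polyline", "write_vtk_polyline"]


def write_vtk_polyline(path, coords: np.ndarray,
                       point_data: dict[str, np.ndarray] | None = None,
                       comment: str = "trabflow boundary") -> Path:
    """Write a closed 2D polyline as legacy ASCII VTK polydata (z = 0)."""
    path = Path(path)
    n = coords.shape[0]
    lines = [
        "# vtk DataFile Version 3.0",
        comment,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    for x, y in coords:
        lines.append(f"{x:.8g} {y:.8g} 0")
    lines.append(f"LINES 1 {n + 2}")
    lines.append(" ".join([str(n + 1)] + [str(i) for i in range(n)] + ["0"]))
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.8g}" for v in arr.astype(float))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_polyline(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read back a polyline written by :func:`write_vtk_polyline`."""
    tokens = Path(path).read_text().splitlines()
    it = iter(tokens)
    pts = None
    data: dict[str, np.ndarray] = {}
    for line in it:
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            pts = np.array([next(it).split() for _ in range(n)], dtype=float)
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            next(it)  # LOOKUP_TABLE
            data[name] = np.array([next(it) for _ in range(pts.shape[0])],
                                  dtype=float)
    if pts is None:
        raise ValueError(f"no POINTS section in {path}")
    return pts[:, :2], data


def write_mesh_series(mb: MovingBoundary, directory,
                      fmt: str = "vtk-legacy",
                      height: float | None = None,
                      ascii_stl: bool = False) -> list[Path]:
    """Write one file per frame of a moving boundary.

    ``vtk-legacy``: closed polyline with node_id point data; ``stl``: the
    out-of-plane extrusion as a triangulated surface with outward facet
    normals. Frame indices are zero-padded.
    """
    if mb.n_frames == 0:
        raise ValueError("empty frame list")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(mb.n_frames - 1)))
    paths = []
    for f in range(mb.n_frames):
        stem = f"boundary_{f:0{width}d}"
        if fmt == "vtk-legacy":
            p = write_vtk_polyline(
                directory / f"{stem}.vtk", mb.coords[f],
                point_data={"node_id": np.arange(mb.n_nodes)})
        elif fmt == "stl":
            vertices, faces = extrude_boundary(mb, f, height=height)
            mesh = trimesh.Trimesh(vertices=vertices, faces=faces,
                                   process=False)
            trimesh.repair.fix_normals(mesh)
            p = directory / f"{stem}.stl"
            mesh.export(p, file_type="stl_ascii" if ascii_stl else "stl")
        else:
            raise ValueError(f"unknown format '{fmt}'")
        paths.append(p)
    write_labels_csv(mb, directory / "node_labels.csv")
    return paths


def write_labels_csv(mb: MovingBoundary, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"node_id": np.arange(mb.n_nodes),
                       "label": mb.labels.astype(str),
                       "groove_id": mb.groove_ids})
    df.to_csv(path, index=False)
    return path


def write_wss_csv(gamma: np.ndarray, path, viscosity: float | None = None,
                  tangents: np.ndarray | None = None) -> Path:
    """Wall shear rate / stress series as tidy CSV: one row per
    (frame, node) with gamma (1/s) and, when a viscosity is given, the
    tangential WSS and its in-plane components (Pa)."""
    path = Path(path)
    nf, nn = gamma.shape
    frames = np.repeat(np.arange(nf), nn)
    nodes = np.tile(np.arange(nn), nf)
    cols = {"frame": frames, "node_id": nodes, "gamma": gamma.ravel()}
    if viscosity is not None:
        tau = viscosity * gamma
        cols["tau_t"] = tau.ravel()
        if tangents is not None:
            cols["tau_x"] = (tau[..., None] * tangents)[..., 0].ravel()
            cols["tau_y"] = (tau[..., None] * tangents)[..., 1].ravel()
    pd.DataFrame(cols).to_csv(path, index=False)
    return path
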