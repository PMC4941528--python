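"""Reading and writing the canonical footprint table and surface files.

Tables are UTF-8 CSV with a fixed column vocabulary (units in the names);
unknown columns are preserved but ignored.  Surfaces travel as an ASCII grid
container (header + elevation matrix + margin-mask matrix) with a landmark
sidecar CSV, or as ASCII PLY meshes via trimesh.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import FootprintSurface
from .schema import (
    DEPTH_COLUMNS,
    DEPTH_LANDMARKS,
    MEASUREMENT_COLUMNS,
    REQUIRED_COLUMNS,
)

__all__ = [
    "SchemaError",
    "read_footprint_table",
    "write_footprint_table",
    "read_surface_xyz",
    "write_surface_xyz",
    "surface_to_mesh",
    "write_surface_ply",
    "read_mesh_ply",
    "read_landmarks",
    "write_landmarks",
]

#: Columns that must parse as numbers when present.
_NUMERIC_COLUMNS = MEASUREMENT_COLUMNS + DEPTH_COLUMNS + ("body_mass_kg",)


class SchemaError(ValueError):
    """A footprint table violates the canonical schema."""


def read_footprint_table(path) -> pd.DataFrame:
    """Read and validate a footprint CSV.

    Raises :class:`SchemaError` naming any missing required column, or naming
    the row and column of the first non-numeric measurement.  Row numbers
    (1-based, excluding the header) are retained in the index for error
    reporting downstream.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")
    for col in _NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based + header line
            raise SchemaError(
                f"{path.name}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        df[col] = converted
    df.index = pd.RangeIndex(2, len(df) + 2, name="line")
    return df


def write_footprint_table(records: pd.DataFrame, path) -> None:
    """Write a footprint table as canonical CSV (stable column order)."""
    ordered = [c for c in REQUIRED_COLUMNS + ("body_mass_kg",) + DEPTH_COLUMNS
               if c in records.columns]
    extras = [c for c in records.columns if c not in ordered]
    records[ordered + extras].to_csv(path, index=False)


_SURFACE_MAGIC = "# ichnostats surface v1"


def write_surface_xyz(surface: FootprintSurface, path) -> None:
    """Write a surface as the ASCII grid container (elevations + margin mask).

    Landmarks are embedded as a trailing block so a single file round-trips a
    complete surface.
    """
    ny, nx = surface.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_SURFACE_MAGIC + "\n")
        fh.write(f"origin {surface.origin[0]!r} {surface.origin[1]!r}\n")
        fh.write(f"spacing {surface.spacing!r}\n")
        fh.write(f"shape {ny} {nx}\n")
        fh.write("elevations_cm\n")
        np.savetxt(fh, surface.elevations, fmt="%.10g")
        fh.write("margin_mask\n")
        np.savetxt(fh, surface.margin_mask.astype(int), fmt="%d")
        fh.write("landmarks\n")
        for name in DEPTH_LANDMARKS:
            x, y = surface.landmarks[name]
            fh.write(f"{name} {x!r} {y!r}\n")


def read_surface_xyz(path) -> FootprintSurface:
    """Read a surface written by :func:`write_surface_xyz`."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _SURFACE_MAGIC:
        raise ValueError(f"{path}: not an ichnostats ASCII surface file")
    origin = tuple(float(v) for v in lines[1].split()[1:3])
    spacing = float(lines[2].split()[1])
    ny, nx = (int(v) for v in lines[3].split()[1:3])
    assert lines[4] == "elevations_cm"
    z = np.loadtxt(lines[5 : 5 + ny], ndmin=2)
    assert lines[5 + ny] == "margin_mask"
    mask = np.loadtxt(lines[6 + ny : 6 + 2 * ny], ndmin=2).astype(bool)
    assert lines[6 + 2 * ny] == "landmarks"
    landmarks = {}
    for line in lines[7 + 2 * ny : 7 + 2 * ny + len(DEPTH_LANDMARKS)]:
        name, x, y = line.split()
        landmarks[name] = (float(x), float(y))
    return FootprintSurface(
        origin=origin, spacing=spacing, elevations=z, margin_mask=mask,
        landmarks=landmarks,
    )


def surface_to_mesh(surface: FootprintSurface) -> trimesh.Trimesh:
    """Triangulate the elevation grid into a mesh (two triangles per cell)."""
    gx, gy = surface.grid_coords()
    xx, yy = np.meshgrid(gx, gy)
    ny, nx = surface.shape
    vertices = np.column_stack(
        [xx.ravel(), yy.ravel(), surface.elevations.ravel()]
    )
    idx = np.arange(ny * nx).reshape(ny, nx)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, c]), np.column_stack([b, d, c])]
    )
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def write_surface_ply(surface: FootprintSurface, path) -> None:
    """Export the surface as an ASCII PLY mesh (landmarks need a sidecar)."""
    mesh = surface_to_mesh(surface)
    Path(path).write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))


def read_mesh_ply(path) -> np.ndarray:
    """Vertex array (n, 3) of a PLY mesh, for nearest-vertex depth sampling."""
    mesh = trimesh.load(str(path), file_type="ply", process=False)
    return np.asarray(mesh.vertices, dtype=float)


def write_landmarks(landmarks: dict[str, tuple[float, float]], path) -> None:
    pd.DataFrame(
        [(name, *landmarks[name]) for name in DEPTH_LANDMARKS],
        columns=["landmark", "x_cm", "y_cm"],
    ).to_csv(path, index=False)


def read_landmarks(path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path)
    return {
        str(row.landmark): (float(row.x_cm), float(row.y_cm))
        for row in df.itertuples()
    }
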