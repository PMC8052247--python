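"""Minimal legacy-ASCII VTK writers for streamlines and point clouds.

Only the small subset of the legacy VTK polydata format needed to inspect
results in ParaView is emitted (POINTS, LINES/VERTICES, POINT_DATA with
scalar arrays).  Written by hand because no VTK binding is a dependency.
"""

from __future__ import annotations

import numpy as np

from .streamlines import Streamline

__all__ = ["write_polylines", "write_points"]


def _header(fh, title: str, n_points: int) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET POLYDATA\n")
    fh.write(f"POINTS {n_points} double\n")


def write_polylines(path: str, lines: list[Streamline]) -> None:
    """Streamlines as VTK polylines with arc length and pressure point data."""
    pts = np.concatenate([ln.vertices for ln in lines]) if lines else np.empty((0, 3))
    with open(path, "w") as fh:
        _header(fh, "rhinoflow streamlines", len(pts))
        for p in pts:
            fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
        sizes = [len(ln.vertices) for ln in lines]
        total = sum(s + 1 for s in sizes)
        fh.write(f"LINES {len(lines)} {total}\n")
        offset = 0
        for s in sizes:
            ids = " ".join(str(offset + k) for k in range(s))
            fh.write(f"{s} {ids}\n")
            offset += s
        fh.write(f"POINT_DATA {len(pts)}\n")
        fh.write("SCALARS arc_length_mm double 1\nLOOKUP_TABLE default\n")
        for ln in lines:
            for v in ln.arc_length:
                fh.write(f"{v:.8g}\n")
        if all(ln.pressure is not None for ln in lines):
            fh.write("SCALARS pressure_pa double 1\nLOOKUP_TABLE default\n")
            for ln in lines:
                for v in ln.pressure:  # type: ignore[union-attr]
                    fh.write(f"{v:.8g}\n")


def write_points(path: str, points: np.ndarray, scalars: dict[str, np.ndarray] | None = None) -> None:
    """Point cloud (e.g. HPGR positions) with optional scalar arrays."""
    points = np.atleast_2d(points)
    with open(path, "w") as fh:
        _header(fh, "rhinoflow points", len(points))
        for p in points:
            fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
        fh.write(f"VERTICES {len(points)} {2 * len(points)}\n")
        for i in range(len(points)):
            fh.write(f"1 {i}\n")
        if scalars:
            fh.write(f"POINT_DATA {len(points)}\n")
            for name, arr in scalars.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in np.asarray(arr):
                    fh.write(f"{v:.8g}\n")
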