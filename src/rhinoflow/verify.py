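"""Grid-convergence (GCI) analysis and clinical outcome metrics.

Richardson extrapolation on three systematically refined grids yields the
observed order of convergence p, the zero-spacing estimate f0 and Roache's
grid convergence index; a mesh-independence ratio MI ~ 1 certifies that the
solutions are in the asymptotic range.

Outcome metrics compare pre-surgery, virtual-surgery and post-surgery
states: the pressure-drop ratio

    delta_pi = (dp_pre - dp_virtual) / (dp_pre - dp_post)

equals 1 when the virtual plan exactly reproduces the achieved surgical
pressure change, and the cross-section ratio delta_a = A_virtual / A_post is
evaluated at an investigation plane along the airway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GCIReport",
    "gci",
    "surface_avg_pressure",
    "delta_pi",
    "area_profile",
    "delta_a",
]


@dataclass(frozen=True)
class GCIReport:
    """Three-grid convergence study: f1 fine, f2 medium, f3 coarse."""

    f1: float
    f2: float
    f3: float
    r: float
    p_order: float
    f0: float
    gci12: float
    gci23: float
    mi: float


def gci(f1: float, f2: float, f3: float, r: float, safety_factor: float = 1.25) -> GCIReport:
    """Observed order, Richardson extrapolate and grid convergence indices.

    ``r`` is the (constant) refinement ratio between successive grids.  The
    safety factor 1.25 is Roache's recommendation for three-grid studies.
    Relative errors use the finer grid of each pair as denominator.

    Raises on oscillatory (non-monotone) convergence, i.e. when
    ``(f3 - f2) / (f2 - f1) <= 0``.
    """
    if r <= 1:
        raise ValueError("refinement ratio r must be > 1")
    if f2 == f1:
        raise ValueError("f1 == f2: order of convergence is undefined")
    ratio = (f3 - f2) / (f2 - f1)
    if ratio <= 0:
        raise ValueError(f"non-monotone (oscillatory) convergence: (f3-f2)/(f2-f1) = {ratio:.3g}")
    p = math.log(ratio) / math.log(r)
    rp = r**p
    f0 = f1 + (f1 - f2) / (rp - 1.0)
    gci12 = safety_factor * abs((f2 - f1) / f1) / (rp - 1.0)
    gci23 = safety_factor * abs((f3 - f2) / f2) / (rp - 1.0)
    mi = gci23 / (rp * gci12)
    return GCIReport(f1=f1, f2=f2, f3=f3, r=r, p_order=p, f0=f0, gci12=gci12, gci23=gci23, mi=mi)


def surface_avg_pressure(pressure: np.ndarray, plane_mask: np.ndarray) -> float:
    """Area-weighted mean pressure over the fluid voxels of a plane mask."""
    if plane_mask.shape != pressure.shape:
        raise ValueError("plane mask and pressure field must share shape")
    n = int(plane_mask.sum())
    if n == 0:
        raise ValueError("plane mask is empty")
    return float(pressure[plane_mask.astype(bool)].mean())


def delta_pi(dp_pre: float, dp_virtual: float, dp_post: float) -> float:
    """Pressure-drop ratio (pre - virtual) / (pre - post), signed.

    Invariant under adding a constant to all three pressures and under
    multiplication by a positive constant; undefined when pre == post.
    """
    denom = dp_pre - dp_post
    if denom == 0:
        raise ValueError("delta_pi undefined: dp_pre == dp_post")
    return (dp_pre - dp_virtual) / denom


def area_profile(
    fluid_mask: np.ndarray,
    spacing: float,
    axis: int = 0,
    exclusions: tuple[np.ndarray, ...] = (),
) -> pd.DataFrame:
    """Cross-sectional area A(d) per slice along ``axis`` (d in mm).

    ``exclusions`` are masks of regions not counted (e.g. the inlet sphere,
    the outlet cuboid, sinuses).  Columns: ``d_mm``, ``area_mm2``.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    mask = fluid_mask.astype(bool).copy()
    for excl in exclusions:
        if excl.shape != fluid_mask.shape:
            raise ValueError("exclusion mask shape mismatch")
        mask &= ~excl.astype(bool)
    other = tuple(a for a in range(3) if a != axis)
    counts = mask.sum(axis=other)
    d = np.arange(fluid_mask.shape[axis]) * spacing
    return pd.DataFrame({"d_mm": d, "area_mm2": counts * spacing**2})


def delta_a(area_virtual: float, area_post: float) -> float:
    """Cross-section ratio virtual surgery / post surgery at a plane."""
    if area_post <= 0:
        raise ValueError("area_post must be positive")
    return area_virtual / area_post
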