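"""Streamline seeding, adaptive RK45 integration and pressure sampling.

Streamlines are integrated in arc-length parameterization, dx/ds = v/|v|,
with trilinear interpolation of the velocity field, so the sampled pressure
gradient dp/dl along a line is directly in Pa/mm.  Seeds are drawn uniformly
from the inlet sphere; integration direction "both" concatenates a backward
branch (reversed) and a forward branch through the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import RegularGridInterpolator

__all__ = ["Streamline", "Termination", "seed_in_sphere", "StreamlineTracer", "trace", "trace_many", "sample_pressure"]


class Termination(str, Enum):
    MAX_LENGTH = "max_length"
    LEFT_DOMAIN = "left_domain"
    STAGNATION = "stagnation"
    MAX_STEPS = "max_steps"


@dataclass(frozen=True)
class Streamline:
    """Ordered polyline with cumulative arc length (mm) and sampled pressure (Pa)."""

    vertices: np.ndarray  # (m, 3) mm
    arc_length: np.ndarray  # (m,) cumulative, non-decreasing
    pressure: np.ndarray | None  # (m,) Pa, filled by sample_pressure
    termination_reason: Termination
    seed: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arc_length) < -1e-9):
            raise ValueError("arc_length must be non-decreasing")


def seed_in_sphere(
    n: int,
    center,
    diameter: float,
    rng_seed: int,
    fluid_mask: np.ndarray | None = None,
    spacing: float | None = None,
) -> np.ndarray:
    """``n`` points uniform in the ball, reproducible from ``rng_seed``.

    If a fluid mask is given, points whose containing voxel is not fluid are
    rejected and resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    center = np.asarray(center, dtype=float)
    radius = diameter / 2.0
    rng = np.random.default_rng(rng_seed)

    def accept(pts: np.ndarray) -> np.ndarray:
        if fluid_mask is None:
            return np.ones(len(pts), dtype=bool)
        idx = np.rint(pts / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(fluid_mask.shape)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if ok.any():
            ii = idx[ok]
            out[ok] = fluid_mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    if fluid_mask is not None:
        if spacing is None:
            raise ValueError("spacing is required with a fluid mask")
        probe = _ball(rng, max(4 * n, 1000), center, radius)
        if not accept(probe).any():
            raise ValueError("inlet sphere contains no fluid voxels")

    points: list[np.ndarray] = []
    for _ in range(1000):
        batch = _ball(rng, max(n, 64), center, radius)
        batch = batch[accept(batch)]
        points.append(batch)
        if sum(len(p) for p in points) >= n:
            break
    pts = np.concatenate(points)[:n]
    if len(pts) < n:
        raise ValueError("could not place the requested number of seeds inside the fluid")
    return pts


def _ball(rng: np.random.Generator, m: int, center: np.ndarray, radius: float) -> np.ndarray:
    v = rng.standard_normal((m, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(m) ** (1.0 / 3.0)
    return center + v * r[:, None]


class StreamlineTracer:
    """Reusable tracer bound to one velocity field (m/s) on a voxel grid."""

    def __init__(
        self,
        velocity: np.ndarray,
        spacing: float,
        fluid_mask: np.ndarray | None = None,
        stagnation_floor: float = 1e-6,
        rtol: float = 1e-4,
        max_step_mm: float | None = None,
    ):
        if velocity.ndim != 4 or velocity.shape[-1] != 3:
            raise ValueError("velocity must have shape (n0, n1, n2, 3)")
        self.spacing = float(spacing)
        self.shape = velocity.shape[:3]
        axes = [np.arange(n) * self.spacing for n in self.shape]
        self._v = RegularGridInterpolator(axes, velocity, bounds_error=False, fill_value=0.0)
        self._fluid = None
        if fluid_mask is not None:
            self._fluid = RegularGridInterpolator(
                axes, fluid_mask.astype(float), bounds_error=False, fill_value=0.0
            )
        self.floor = float(stagnation_floor)
        self.rtol = float(rtol)
        self.max_step = max_step_mm if max_step_mm is not None else 5.0 * self.spacing
        self._hi = np.array([(n - 1) * self.spacing for n in self.shape])

    def _speed(self, x: np.ndarray) -> float:
        return float(np.linalg.norm(self._v(x[None])[0]))

    def _branch(self, seed: np.ndarray, sign: float, max_length: float, dl: float):
        def rhs(_s, x):
            v = self._v(x[None])[0]
            sp = np.linalg.norm(v)
            if sp < self.floor:
                return np.zeros(3)
            return sign * v / sp

        def ev_stagnation(_s, x):
            return self._speed(x) - self.floor

        ev_stagnation.terminal = True

        def ev_exit(_s, x):
            m = np.minimum(x, self._hi - x).min()
            if self._fluid is not None:
                m = min(m, float(self._fluid(np.clip(x, 0, self._hi)[None])[0]) - 0.5)
            return m

        ev_exit.terminal = True

        sol = solve_ivp(
            rhs,
            (0.0, max_length),
            seed,
            method="RK45",
            rtol=self.rtol,
            atol=1e-3,
            max_step=self.max_step,
            events=[ev_stagnation, ev_exit],
            dense_output=True,
        )
        s_end = float(sol.t[-1])
        if s_end <= 0:
            return np.empty((0, 3)), np.empty(0), Termination.STAGNATION
        grid = np.arange(0.0, s_end, dl)
        grid = np.append(grid, s_end)
        verts = sol.sol(grid).T
        # event location can overshoot the grid by a fraction of a step
        verts = np.clip(verts, 0.0, self._hi)
        if sol.status == 1:  # an event fired
            reason = Termination.STAGNATION if len(sol.t_events[0]) else Termination.LEFT_DOMAIN
        elif sol.status == 0:
            reason = Termination.MAX_LENGTH
        else:
            reason = Termination.MAX_STEPS
        return verts, grid, reason

    def trace(
        self,
        seed,
        direction: str = "both",
        max_length_mm: float = 300.0,
        dl_mm: float | None = None,
    ) -> Streamline:
        """Integrate one streamline; vertices are spaced ``dl_mm`` apart
        (default: half a voxel) along the arc."""
        # voxel-centre grids span [0, (n-1)*spacing]; a seed in the outer
        # half-voxel is clamped onto that range
        seed = np.clip(np.asarray(seed, dtype=float), 0.0, self._hi)
        if self._fluid is not None:
            # membership by containing voxel, consistent with seed_in_sphere
            idx = tuple(np.rint(seed / self.spacing).astype(int).clip(0, np.array(self.shape) - 1))
            if self._fluid.values[idx] < 0.5:
                raise ValueError(f"seed {seed} is outside the fluid domain")
        dl = dl_mm if dl_mm is not None else self.spacing / 2.0

        if self._speed(seed) < self.floor:
            one = seed[None, :]
            return Streamline(one, np.zeros(1), None, Termination.STAGNATION, seed)

        if direction == "forward":
            verts, arcs, reason = self._branch(seed, +1.0, max_length_mm, dl)
        elif direction == "backward":
            verts, arcs, reason = self._branch(seed, -1.0, max_length_mm, dl)
        elif direction == "both":
            half = max_length_mm / 2.0
            vb, ab, rb = self._branch(seed, -1.0, half, dl)
            vf, af, rf = self._branch(seed, +1.0, half, dl)
            verts = np.concatenate([vb[::-1][:-1], vf]) if len(vb) > 1 else vf
            base = ab[-1] if len(ab) else 0.0
            arcs = np.concatenate([(base - ab[::-1])[:-1], base + af]) if len(ab) else af
            reason = rf
        else:
            raise ValueError("direction must be forward, backward or both")

        if len(verts) == 0:
            verts = seed[None, :]
            arcs = np.zeros(1)
        return Streamline(verts, np.asarray(arcs), None, reason, seed)


def trace(
    velocity: np.ndarray,
    spacing: float,
    seed,
    direction: str = "both",
    max_length_mm: float = 300.0,
    fluid_mask: np.ndarray | None = None,
    **kwargs,
) -> Streamline:
    """One-shot tracing convenience wrapper around :class:`StreamlineTracer`."""
    tracer = StreamlineTracer(velocity, spacing, fluid_mask=fluid_mask, **kwargs)
    return tracer.trace(seed, direction=direction, max_length_mm=max_length_mm)


def trace_many(
    velocity: np.ndarray,
    spacing: float,
    seeds: np.ndarray,
    direction: str = "both",
    max_length_mm: float = 300.0,
    fluid_mask: np.ndarray | None = None,
    **kwargs,
) -> list[Streamline]:
    tracer = StreamlineTracer(velocity, spacing, fluid_mask=fluid_mask, **kwargs)
    return [tracer.trace(s, direction=direction, max_length_mm=max_length_mm) for s in seeds]


def sample_pressure(line: Streamline, pressure: np.ndarray, spacing: float) -> Streamline:
    """Attach trilinearly interpolated pressure (Pa) to each vertex."""
    axes = [np.arange(n) * spacing for n in pressure.shape]
    interp = RegularGridInterpolator(axes, pressure, bounds_error=True)
    try:
        p = interp(line.vertices)
    except ValueError as exc:
        bad = line.vertices[
            np.any((line.vertices < 0) | (line.vertices > [(n - 1) * spacing for n in pressure.shape]), axis=1)
        ]
        raise ValueError(f"streamline vertex outside the pressure field: {bad[:1]}") from exc
    return replace(line, pressure=np.asarray(p))
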