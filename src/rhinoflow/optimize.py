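"""Iterative virtual surgery: widen the airway at high-pressure-gradient
regions until the obstruction criterion clears, and report the resection.

Each selected HPGR founds a region of interest (ROI) and an optimization
cube (OC, fixed 10 mm side, centred on the HPGR; initially the ROI
coincides with the OC).  One iteration:

1. inside every ROI, move the airway wall outward by one voxel layer
   (Laplacian edge detection on the fluid mask selects the solid voxels on
   the fluid-solid interface; only voxels on the far side of the airway
   relative to the OC centre are converted, emulating a move in surface
   normal direction);
2. grow every ROI by 0.234 mm per face (0.468 mm per axis);
3. re-run the flow for a short duration, warm-started from the *initial*
   solution with new fluid voxels at rest;
4. re-trace streamlines, re-detect HPGRs, keep those inside ROIs; a new
   HPGR inside a ROI founds an additional OC/ROI pair (the original is
   kept).

The loop stops when fewer than ``stop_count`` HPGRs remain inside all ROIs.
The resection volume is the Boolean difference between the final and the
initial fluid mask times the voxel volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from . import hpgr as hpgr_mod
from .hpgr import HPGR, detect
from .imaging import FlowDomain
from .lbm import LatticeState, LBMSolver, SolverConfig
from .streamlines import StreamlineTracer, sample_pressure, seed_in_sphere

__all__ = ["OptimizerConfig", "OptimizationState", "ResectionReport", "init_rois", "move_wall", "iterate", "optimize"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimizerConfig:
    """Knobs of the virtual-surgery loop (lengths in mm)."""

    oc_side_mm: float = 10.0
    roi_growth_mm_per_axis: float = 0.468  # 0.234 per face
    stop_count: int = 5
    max_iterations: int = 30
    wall_mode: str = "normal"  # or "dilate": all-edge dilation fallback
    warm_start: str = "initial"  # or "previous": restart each LB run from the last iterate
    n_seeds: int = 532
    rng_seed: int = 0
    max_length_mm: float = 300.0
    critical_gradient: float = hpgr_mod.CRITICAL_GRADIENT
    min_count: int = hpgr_mod.MIN_COUNT
    bin_size_mm: float | None = None  # default: 2 x lattice spacing
    boundary_margin_mm: float = 2.0  # HPGR exclusion zone around inlet/outlet bodies


@dataclass
class Box:
    """Axis-aligned box in mm, half-open on nothing (voxel-centre inclusive)."""

    lo: np.ndarray
    hi: np.ndarray

    def grow(self, per_face_mm: float) -> "Box":
        return Box(self.lo - per_face_mm, self.hi + per_face_mm)

    def clipped(self, shape, spacing) -> "Box":
        hi_mm = (np.asarray(shape) - 1) * spacing
        return Box(np.clip(self.lo, 0, hi_mm), np.clip(self.hi, 0, hi_mm))

    def voxel_slices(self, spacing: float, shape) -> tuple[slice, slice, slice]:
        lo = np.maximum(np.ceil(self.lo / spacing - 1e-9).astype(int), 0)
        hi = np.minimum(np.floor(self.hi / spacing + 1e-9).astype(int), np.asarray(shape) - 1)
        return tuple(slice(l, h + 1) for l, h in zip(lo, hi))

    def mask(self, spacing: float, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        sl = self.voxel_slices(spacing, shape)
        if all(s.stop > s.start for s in sl):
            out[sl] = True
        return out

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lo + self.hi)


@dataclass
class OptimizationState:
    """Mutable record of one virtual-surgery run."""

    iteration: int
    fluid_mask: np.ndarray
    initial_fluid_mask: np.ndarray
    rois: list[Box]
    ocs: list[Box]
    spacing: float
    active_hpgrs: list[HPGR] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)
    founding_bins: set = field(default_factory=set)

    @property
    def resection_mask(self) -> np.ndarray:
        return self.fluid_mask & ~self.initial_fluid_mask

    def roi_union_mask(self) -> np.ndarray:
        out = np.zeros(self.fluid_mask.shape, dtype=bool)
        for roi in self.rois:
            out |= roi.mask(self.spacing, self.fluid_mask.shape)
        return out


@dataclass(frozen=True)
class ResectionReport:
    """Outcome of a virtual-surgery run."""

    volume_mm3: float
    mask: np.ndarray
    per_roi_voxels: list[int]
    iterations: int
    converged: bool
    history: list[dict]


def init_rois(
    selected: list[HPGR],
    fluid_mask: np.ndarray,
    spacing: float,
    oc_side_mm: float = 10.0,
) -> OptimizationState:
    """One ROI/OC pair per selected HPGR, HPGR at the cube centre.

    Cubes reaching past the volume are clipped with a logged warning.  Two
    coincident HPGRs yield two ROIs; deduplication is the caller's choice.
    """
    if not selected:
        raise ValueError("empty HPGR selection")
    shape = fluid_mask.shape
    rois, ocs = [], []
    half = oc_side_mm / 2.0
    hi_mm = (np.asarray(shape) - 1) * spacing
    for h in selected:
        box = Box(np.asarray(h.position) - half, np.asarray(h.position) + half)
        if np.any(box.lo < 0) or np.any(box.hi > hi_mm):
            log.warning("OC at %s clipped to volume bounds", np.round(h.position, 2))
            box = box.clipped(shape, spacing)
        rois.append(Box(box.lo.copy(), box.hi.copy()))
        ocs.append(box)
    return OptimizationState(
        iteration=0,
        fluid_mask=fluid_mask.copy(),
        initial_fluid_mask=fluid_mask.copy(),
        rois=rois,
        ocs=ocs,
        spacing=spacing,
        active_hpgrs=list(selected),
        founding_bins={h.voxel_bin for h in selected},
    )


def move_wall(
    state: OptimizationState,
    roi_index: int,
    mode: str = "normal",
    forbidden: np.ndarray | None = None,
) -> OptimizationState:
    """Convert one layer of wall voxels to fluid inside one ROI (in place).

    The discrete Laplacian of the fluid mask is non-zero exactly on the
    fluid-solid interface; solid voxels on that edge are candidates.  In
    ``normal`` mode only candidates whose supporting fluid neighbour lies on
    the OC-centre side are converted (outward growth); ``dilate`` converts
    every edge voxel in the ROI.  A ROI without wall voxels is a no-op.
    """
    roi = state.rois[roi_index]
    center = state.ocs[roi_index].center
    shape = state.fluid_mask.shape
    sp = state.spacing
    sl = roi.voxel_slices(sp, shape)
    if any(s.stop <= s.start for s in sl):
        return state
    # pad by one voxel for a correct Laplacian at the ROI border
    psl = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, n)) for s, n in zip(sl, shape))
    fluid_sub = state.fluid_mask[psl]
    lap = ndi.laplace(fluid_sub.astype(np.int8))
    edge_solid = ~fluid_sub & (lap != 0)

    if mode == "normal":
        keep = np.zeros_like(edge_solid)
        offs = np.array([s.start for s in psl])
        for a in range(3):
            for sgn in (1, -1):
                # fluid neighbour at v - sgn*e_a, growth direction +sgn*e_a
                nb_fluid = _shift(fluid_sub, a, sgn)
                idx = np.arange(fluid_sub.shape[a]) + offs[a]
                pos_mm = idx * sp
                outward = pos_mm * sgn > center[a] * sgn  # voxel beyond the OC centre
                shp = [1, 1, 1]
                shp[a] = -1
                keep |= edge_solid & nb_fluid & outward.reshape(shp)
        convert = keep
    elif mode == "dilate":
        convert = edge_solid
    else:
        raise ValueError("mode must be 'normal' or 'dilate'")

    # restrict to the ROI proper (strip the pad)
    roi_box = np.zeros_like(convert)
    inner = tuple(
        slice(s.start - p.start, s.stop - p.start) for s, p in zip(sl, psl)
    )
    roi_box[inner] = True
    convert &= roi_box
    if forbidden is not None:
        convert &= ~forbidden[psl]
    if not convert.any():
        log.info("ROI %d: no wall voxels to move (grown past the anatomy)", roi_index)
        return state
    state.fluid_mask[psl] |= convert
    return state


def _shift(mask: np.ndarray, axis: int, sgn: int) -> np.ndarray:
    """mask shifted so out[v] = mask[v - sgn*e_axis], zero-filled."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if sgn == 1:
        dst[axis], src[axis] = slice(1, None), slice(None, -1)
    else:
        dst[axis], src[axis] = slice(None, -1), slice(1, None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _boundary_forbidden(domain: FlowDomain, margin_mm: float) -> np.ndarray:
    """Voxels that may never be resected: solid near inlet/outlet bodies."""
    body = domain.sphere_mask() | domain.cuboid_mask()
    it = max(1, int(np.ceil(margin_mm / domain.spacing)))
    return ndi.binary_dilation(body, iterations=it)


def _exclude_mask(domain: FlowDomain, margin_mm: float) -> np.ndarray:
    """HPGR exclusion zone: inside (a dilation of) the boundary bodies."""
    return _boundary_forbidden(domain, margin_mm)


def _detect_in_rois(
    state: OptimizationState,
    solution: LatticeState,
    domain: FlowDomain,
    ocfg: OptimizerConfig,
) -> list[HPGR]:
    sp = domain.spacing
    vel = solution.velocity_field()
    pres = solution.pressure_field()
    seeds = seed_in_sphere(
        ocfg.n_seeds,
        domain.sphere_center,
        domain.sphere_diameter,
        ocfg.rng_seed,
        fluid_mask=domain.fluid_mask,
        spacing=sp,
    )
    tracer = StreamlineTracer(vel, sp, fluid_mask=domain.fluid_mask)
    lines = [
        sample_pressure(tracer.trace(s, max_length_mm=ocfg.max_length_mm), pres, sp) for s in seeds
    ]
    bin_size = ocfg.bin_size_mm if ocfg.bin_size_mm is not None else 2.0 * sp
    hits = detect(
        lines,
        ocfg.critical_gradient,
        bin_size,
        exclude_mask=_exclude_mask(domain, ocfg.boundary_margin_mm),
        spacing=sp,
    )
    roi_union = state.roi_union_mask()
    in_roi = []
    for h in hits:
        idx = np.clip(np.rint(h.position / sp).astype(int), 0, np.asarray(roi_union.shape) - 1)
        if roi_union[tuple(idx)]:
            in_roi.append(h)
    return in_roi


def iterate(
    state: OptimizationState,
    domain: FlowDomain,
    cfg: SolverConfig,
    initial_solution: LatticeState,
    ocfg: OptimizerConfig = OptimizerConfig(),
) -> tuple[OptimizationState, LatticeState, FlowDomain]:
    """One optimization iteration; returns (state, new flow solution, new domain)."""
    forbidden = _boundary_forbidden(domain, ocfg.boundary_margin_mm)
    for i in range(len(state.rois)):
        move_wall(state, i, mode=ocfg.wall_mode, forbidden=forbidden)
    per_face = ocfg.roi_growth_mm_per_axis / 2.0
    state.rois = [
        r.grow(per_face).clipped(state.fluid_mask.shape, state.spacing) for r in state.rois
    ]
    state.iteration += 1

    new_domain = domain.with_fluid(state.fluid_mask)
    solver = LBMSolver(new_domain, cfg)
    solution = solver.run(cfg.optimization_duration_s, initial=initial_solution)

    in_roi = _detect_in_rois(state, solution, new_domain, ocfg)
    state.active_hpgrs = in_roi

    # a new HPGR inside a ROI founds an additional OC/ROI (originals persist)
    oc_union = np.zeros(state.fluid_mask.shape, dtype=bool)
    for oc in state.ocs:
        oc_union |= oc.mask(state.spacing, state.fluid_mask.shape)
    for h in in_roi:
        idx = np.clip(
            np.rint(h.position / state.spacing).astype(int),
            0,
            np.asarray(state.fluid_mask.shape) - 1,
        )
        if h.voxel_bin not in state.founding_bins and not oc_union[tuple(idx)]:
            half = ocfg.oc_side_mm / 2.0
            box = Box(np.asarray(h.position) - half, np.asarray(h.position) + half).clipped(
                state.fluid_mask.shape, state.spacing
            )
            state.ocs.append(box)
            state.rois.append(Box(box.lo.copy(), box.hi.copy()))
            state.founding_bins.add(h.voxel_bin)
            oc_union |= box.mask(state.spacing, state.fluid_mask.shape)

    dp = float(solution.dp_trace_pa[-1]) if solution.dp_trace_pa.size else float("nan")
    state.history.append(
        {"iteration": state.iteration, "hpgr_in_roi": len(in_roi), "dp_pa": dp}
    )
    return state, solution, new_domain


def optimize(
    domain: FlowDomain,
    cfg: SolverConfig,
    selected: list[HPGR],
    ocfg: OptimizerConfig = OptimizerConfig(),
    initial_solution: LatticeState | None = None,
) -> tuple[ResectionReport, OptimizationState, LatticeState]:
    """Full virtual-surgery loop from an initial flow solution.

    Returns the resection report, the final optimizer state and the last
    flow solution.  ROIs founded on HPGRs inside the inlet/outlet exclusion
    zone are rejected (flow near the artificial bodies diverges).
    """
    if not selected:
        raise ValueError("empty HPGR selection")
    sp = domain.spacing
    excl = _exclude_mask(domain, ocfg.boundary_margin_mm)
    for h in selected:
        idx = np.clip(np.rint(np.asarray(h.position) / sp).astype(int), 0, np.asarray(excl.shape) - 1)
        if excl[tuple(idx)]:
            raise ValueError(
                f"selected HPGR at {np.round(h.position, 2)} lies in the inlet/outlet "
                "exclusion zone; optimization there is unstable"
            )
    if initial_solution is None:
        initial_solution = LBMSolver(domain, cfg).run(cfg.physical_duration_s)

    state = init_rois(selected, domain.fluid_mask, sp, oc_side_mm=ocfg.oc_side_mm)
    solution = initial_solution
    cur_domain = domain

    in_roi = _detect_in_rois(state, solution, cur_domain, ocfg)
    state.active_hpgrs = in_roi
    dp0 = float(solution.dp_trace_pa[-1]) if solution.dp_trace_pa.size else float("nan")
    state.history.append({"iteration": 0, "hpgr_in_roi": len(in_roi), "dp_pa": dp0})
    converged = len(in_roi) < ocfg.stop_count

    while not converged and state.iteration < ocfg.max_iterations:
        warm = initial_solution if ocfg.warm_start == "initial" else solution
        state, solution, cur_domain = iterate(state, cur_domain, cfg, warm, ocfg)
        log.info(
            "iteration %d: %d HPGRs in ROIs, dp = %.2f Pa",
            state.iteration,
            len(state.active_hpgrs),
            state.history[-1]["dp_pa"],
        )
        converged = len(state.active_hpgrs) < ocfg.stop_count

    resection = state.resection_mask
    per_roi = [
        int((resection & roi.mask(sp, resection.shape)).sum()) for roi in state.rois
    ]
    report = ResectionReport(
        volume_mm3=float(resection.sum()) * sp**3,
        mask=resection,
        per_roi_voxels=per_roi,
        iterations=state.iteration,
        converged=converged,
        history=list(state.history),
    )
    return report, state, solution
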