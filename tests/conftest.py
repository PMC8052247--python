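"""Shared fixtures: phantom geometries and the desk-scale study run.

The desk run (flow solution + streamlines + HPGRs + virtual surgery on the
shipped constricted phantom) is expensive, so it is computed once per
session and shared by all end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import rhinoflow as rf
from rhinoflow.config import desk_phantom_config
from rhinoflow.hpgr import detect, surgery_criterion, sweep
from rhinoflow.lbm import LBMSolver
from rhinoflow.optimize import OptimizerConfig, _exclude_mask, optimize
from rhinoflow.streamlines import StreamlineTracer, sample_pressure, seed_in_sphere


@pytest.fixture(scope="session")
def desk_config():
    return desk_phantom_config()


@pytest.fixture(scope="session")
def desk_domain(desk_config):
    vol = rf.make_channel_phantom(desk_config.phantom)
    below = np.argwhere(vol.data < desk_config.hu_threshold)
    seed = tuple(int(v) for v in below[len(below) // 2])
    air = rf.segment_air(vol, desk_config.hu_threshold, seed)
    return rf.build_boundaries(
        air,
        vol.spacing[0],
        sphere_diameter=desk_config.sphere_diameter_mm,
        cuboid_dims=desk_config.cuboid_dims_mm,
    )


@pytest.fixture(scope="session")
def desk_run(desk_config, desk_domain):
    """Full desk-scale study: initial solution, streamlines, HPGRs, surgery."""
    cfg = desk_config.solver
    sp = desk_domain.spacing
    solver = LBMSolver(desk_domain, cfg)
    initial = solver.run(cfg.physical_duration_s)

    vel = initial.velocity_field()
    pres = initial.pressure_field()
    seeds = seed_in_sphere(
        desk_config.n_streamlines,
        desk_domain.sphere_center,
        desk_domain.sphere_diameter,
        desk_config.rng_seed,
        fluid_mask=desk_domain.fluid_mask,
        spacing=sp,
    )
    tracer = StreamlineTracer(vel, sp, fluid_mask=desk_domain.fluid_mask)
    lines = [
        sample_pressure(tracer.trace(s, max_length_mm=desk_config.max_length_mm), pres, sp)
        for s in seeds
    ]
    excl = _exclude_mask(desk_domain, desk_config.optimizer.boundary_margin_mm)
    bin_size = desk_config.bin_size_mm
    hits = detect(lines, desk_config.critical_gradient, bin_size, exclude_mask=excl, spacing=sp)
    curve = sweep(lines, bin_size, exclude_mask=excl, spacing=sp)
    fire, count = surgery_criterion(curve, desk_config.critical_gradient, desk_config.min_count)

    ocfg = OptimizerConfig(bin_size_mm=bin_size, rng_seed=desk_config.rng_seed)
    report, state, last = optimize(
        desk_domain, cfg, hits, ocfg, initial_solution=initial
    )
    return {
        "config": desk_config,
        "domain": desk_domain,
        "initial": initial,
        "velocity": vel,
        "pressure": pres,
        "lines": lines,
        "hpgrs": hits,
        "curve": curve,
        "criterion_met": fire,
        "criterion_count": count,
        "report": report,
        "state": state,
        "last_solution": last,
        "exclude_mask": excl,
    }


@pytest.fixture()
def straight_spec():
    return rf.PhantomSpec(constriction_factor=1.0)


@pytest.fixture()
def constricted_spec():
    return rf.PhantomSpec(constriction_factor=0.5)
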