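"""Pipeline orchestration: segment -> simulate -> trace -> detect -> select
-> optimize -> report, with reproducible artifacts in a run directory.

Every stage writes plain-text (CSV/JSON) or NIfTI artifacts; numeric outputs
are byte-identical across runs of the same configuration.  A provenance
record (config hash, seeds, library versions, unit mapping) and a checksum
manifest accompany each run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import vtkio
from .config import RunConfig
from .hpgr import HPGR, detect, surgery_criterion, sweep
from .imaging import HUVolume, build_boundaries, resample_isotropic, save_mask, segment_air
from .lbm import LBMSolver
from .optimize import _exclude_mask, optimize
from .streamlines import StreamlineTracer, sample_pressure, seed_in_sphere
from .verify import area_profile

__all__ = ["run_pipeline", "select_hpgrs"]

log = logging.getLogger(__name__)


def _write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _streamlines_to_csv(lines, path: str) -> None:
    rows = []
    for sid, ln in enumerate(lines):
        p = ln.pressure if ln.pressure is not None else np.full(len(ln.vertices), np.nan)
        for k, (v, l, pp) in enumerate(zip(ln.vertices, ln.arc_length, p)):
            rows.append((sid, k, v[0], v[1], v[2], l, pp))
    pd.DataFrame(
        rows, columns=["streamline_id", "vertex_id", "x_mm", "y_mm", "z_mm", "l_mm", "p_pa"]
    ).to_csv(path, index=False)


def _hpgrs_to_csv(hits: list[HPGR], path: str) -> None:
    rows = [
        (i, h.position[0], h.position[1], h.position[2], h.gradient, h.streamline_id,
         h.voxel_bin[0], h.voxel_bin[1], h.voxel_bin[2])
        for i, h in enumerate(hits)
    ]
    pd.DataFrame(
        rows,
        columns=["id", "x_mm", "y_mm", "z_mm", "gradient_pa_per_mm", "streamline_id",
                 "bin0", "bin1", "bin2"],
    ).to_csv(path, index=False)


def _load_hpgrs(path: str) -> list[HPGR]:
    df = pd.read_csv(path)
    return [
        HPGR(
            position=np.array([r.x_mm, r.y_mm, r.z_mm]),
            gradient=float(r.gradient_pa_per_mm),
            streamline_id=int(r.streamline_id),
            voxel_bin=(int(r.bin0), int(r.bin1), int(r.bin2)),
        )
        for r in df.itertuples()
    ]


def select_hpgrs(run_dir: str, indices) -> str:
    """Write the HPGR selection consumed by the optimize stage.

    ``indices`` is a list of row ids of ``hpgrs.csv`` or the string "all".
    Duplicates are dropped with a warning; out-of-range ids raise.
    """
    path = os.path.join(run_dir, "hpgrs.csv")
    if not os.path.exists(path):
        raise FileNotFoundError("no detection output in run directory; run detect first")
    n = len(pd.read_csv(path))
    if indices == "all":
        chosen = list(range(n))
    else:
        chosen = [int(i) for i in indices]
        if not chosen:
            raise ValueError("empty HPGR selection")
        if len(set(chosen)) != len(chosen):
            log.warning("duplicate HPGR indices deduplicated")
            chosen = sorted(set(chosen))
        bad = [i for i in chosen if not (0 <= i < n)]
        if bad:
            raise ValueError(f"HPGR indices out of range: {bad} (have {n})")
    out = os.path.join(run_dir, "selection.json")
    _write_json(out, {"indices": chosen})
    return out


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Execute the full planning pipeline; returns a summary dictionary.

    Artifacts are written to ``out_dir``; numeric outputs are deterministic
    functions of the configuration (including its RNG seed).
    """
    os.makedirs(out_dir, exist_ok=True)
    j = lambda name: os.path.join(out_dir, name)  # noqa: E731
    with open(j("config.json"), "w") as fh:
        fh.write(config.to_json())

    # --- stage 1: volume -------------------------------------------------
    if config.phantom is not None:
        from .phantoms import make_channel_phantom

        vol = make_channel_phantom(config.phantom)
    else:
        vol = HUVolume.load(config.input_volume)
    if config.resample_spacing_mm is not None:
        vol = resample_isotropic(vol, config.resample_spacing_mm)
    if len(set(vol.spacing)) != 1:
        raise ValueError("volume must be isotropic before simulation; set resample_spacing_mm")
    sp = vol.spacing[0]
    vol.save(j("volume.nii"))

    # --- stage 2: segmentation -------------------------------------------
    seed_voxel = config.seed_voxel
    if seed_voxel is None:
        below = np.argwhere(vol.data < config.hu_threshold)
        if len(below) == 0:
            raise ValueError("no voxel below the HU threshold; cannot auto-place the seed")
        seed_voxel = tuple(int(v) for v in below[len(below) // 2])
    air = segment_air(vol, config.hu_threshold, seed_voxel)
    save_mask(air, sp, j("air_mask.nii"))

    domain = build_boundaries(
        air,
        sp,
        sphere_center=config.sphere_center_mm,
        sphere_diameter=config.sphere_diameter_mm,
        cuboid_dims=config.cuboid_dims_mm,
    )
    save_mask(domain.labels, sp, j("labels.nii"))

    # --- stage 3: initial flow solution ----------------------------------
    solver = LBMSolver(domain, config.solver)
    mapping = solver.mapping
    _write_json(
        j("unit_mapping.json"),
        {
            "dx_m": mapping.dx_m,
            "dt_s": mapping.dt_s,
            "tau0": mapping.tau0,
            "nu_lat": mapping.nu_lat,
            "steps_initial": mapping.steps_for(config.solver.physical_duration_s),
            "flow_rate_ml_s": config.solver.flow_rate_ml_s,
        },
    )
    initial = solver.run(config.solver.physical_duration_s)
    pd.DataFrame(
        {"step": np.arange(1, initial.dp_trace_pa.size + 1), "dp_pa": initial.dp_trace_pa}
    ).to_csv(j("dp_trace.csv"), index=False)
    vel = initial.velocity_field()
    pres = initial.pressure_field()
    np.save(j("velocity.npy"), vel)
    HUVolume(pres, (sp,) * 3).save(j("pressure.nii"))
    dp_pre = float(initial.dp_trace_pa[-1])

    # --- stage 4: streamlines --------------------------------------------
    seeds = seed_in_sphere(
        config.n_streamlines,
        domain.sphere_center,
        domain.sphere_diameter,
        config.rng_seed,
        fluid_mask=domain.fluid_mask,
        spacing=sp,
    )
    tracer = StreamlineTracer(vel, sp, fluid_mask=domain.fluid_mask)
    lines = [
        sample_pressure(tracer.trace(s, max_length_mm=config.max_length_mm), pres, sp)
        for s in seeds
    ]
    _streamlines_to_csv(lines, j("streamlines.csv"))
    vtkio.write_polylines(j("streamlines.vtk"), lines)

    # --- stage 5: HPGR detection + criterion ------------------------------
    bin_size = config.bin_size_mm if config.bin_size_mm is not None else 2.0 * sp
    excl = _exclude_mask(domain, config.optimizer.boundary_margin_mm)
    hits = detect(lines, config.critical_gradient, bin_size, exclude_mask=excl, spacing=sp)
    _hpgrs_to_csv(hits, j("hpgrs.csv"))
    if hits:
        vtkio.write_points(
            j("hpgrs.vtk"),
            np.array([h.position for h in hits]),
            {"gradient_pa_per_mm": np.array([h.gradient for h in hits])},
        )
    curve = sweep(lines, bin_size, exclude_mask=excl, spacing=sp)
    pd.DataFrame({"threshold_pa_per_mm": curve.thresholds, "count": curve.counts}).to_csv(
        j("sweep.csv"), index=False
    )
    fire, count = surgery_criterion(curve, config.critical_gradient, config.min_count)
    _write_json(
        j("criterion.json"),
        {
            "critical_gradient_pa_per_mm": config.critical_gradient,
            "min_count": config.min_count,
            "count": count,
            "criterion_met": bool(fire),
        },
    )

    summary = {
        "criterion_met": bool(fire),
        "hpgr_count": count,
        "dp_pre_pa": dp_pre,
        "developed": bool(initial.developed),
    }

    ocfg = dataclasses.replace(
        config.optimizer,
        n_seeds=config.n_streamlines,
        rng_seed=config.rng_seed,
        max_length_mm=config.max_length_mm,
        critical_gradient=config.critical_gradient,
        min_count=config.min_count,
        bin_size_mm=bin_size,
    )

    # --- stage 6: selection + optimization --------------------------------
    if not fire or not hits:
        _write_json(
            j("resection.json"),
            {
                "criterion_met": bool(fire),
                "volume_mm3": 0.0,
                "iterations": 0,
                "converged": True,
                "note": "surgery criterion not met; nothing to optimize",
            },
        )
        summary.update(resection_volume_mm3=0.0, iterations=0, converged=True)
    else:
        select_hpgrs(out_dir, config.selection)
        with open(j("selection.json")) as fh:
            chosen = json.load(fh)["indices"]
        selected = [hits[i] for i in chosen]
        report, state, last = optimize(
            domain, config.solver, selected, ocfg, initial_solution=initial
        )
        save_mask(report.mask, sp, j("resection_mask.nii"))
        if report.mask.any():
            vtkio.write_points(j("resection.vtk"), np.argwhere(report.mask) * sp)
        pd.DataFrame(report.history).to_csv(j("history.csv"), index=False)
        dp_virtual = report.history[-1]["dp_pa"]
        _write_json(
            j("resection.json"),
            {
                "criterion_met": True,
                "volume_mm3": report.volume_mm3,
                "iterations": report.iterations,
                "converged": bool(report.converged),
                "dp_pre_pa": dp_pre,
                "dp_virtual_pa": dp_virtual,
                "final_hpgr_in_roi": report.history[-1]["hpgr_in_roi"],
            },
        )
        prof_pre = area_profile(
            domain.fluid_mask, sp, axis=0, exclusions=(domain.sphere_mask(), domain.cuboid_mask())
        )
        prof_virt = area_profile(
            domain.fluid_mask | report.mask,
            sp,
            axis=0,
            exclusions=(domain.sphere_mask(), domain.cuboid_mask()),
        )
        prof = prof_pre.rename(columns={"area_mm2": "area_pre_mm2"})
        prof["area_virtual_mm2"] = prof_virt["area_mm2"]
        prof.to_csv(j("area_profile.csv"), index=False)
        summary.update(
            resection_volume_mm3=report.volume_mm3,
            iterations=report.iterations,
            converged=bool(report.converged),
            dp_virtual_pa=dp_virtual,
        )

    # --- stage 7: provenance + manifest -----------------------------------
    import scipy

    from . import __version__

    _write_json(
        j("provenance.json"),
        {
            "config_sha256": config.sha256(),
            "rng_seed": config.rng_seed,
            "rhinoflow": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "unit_mapping": {"dx_m": mapping.dx_m, "dt_s": mapping.dt_s, "tau0": mapping.tau0},
        },
    )
    names = sorted(
        f for f in os.listdir(out_dir) if f not in ("manifest.json",) and os.path.isfile(j(f))
    )
    _write_json(j("manifest.json"), {f: _sha256(j(f)) for f in names})
    _write_json(j("summary.json"), summary)
    return summary
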