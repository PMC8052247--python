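"""Run configuration: schema, defaults and (de)serialization.

The clinical-scale defaults are the standard operating point of the method
(-300 HU threshold, 600 ml/s, cs = 0.14, 0.0125/0.00625 s, 532 seeds,
0.3 m maximum streamline length, -1.1 Pa/mm with 25 HPGRs, 10 mm cube,
0.468 mm ROI growth per axis, stop below 5 HPGRs).  ``desk_phantom_config``
returns the shipped desk-scale phantom study: same analysis constants on a
96 x 64 x 64 phantom at 0.5 mm with proportionally smaller boundary bodies
and a laminar-regime flow rate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .lbm import SolverConfig
from .optimize import OptimizerConfig
from .phantoms import PhantomSpec

__all__ = ["RunConfig", "desk_phantom_config", "tiny_phantom_config"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    phantom: PhantomSpec | None = None
    input_volume: str | None = None  # NIfTI path, alternative to a phantom
    resample_spacing_mm: float | None = None
    hu_threshold: float = -300.0
    seed_voxel: tuple[int, int, int] | None = None  # None = first sub-threshold voxel
    sphere_center_mm: tuple[float, float, float] | None = None
    sphere_diameter_mm: float = 70.0
    cuboid_dims_mm: tuple[float, float, float] = (60.0, 40.0, 30.0)
    solver: SolverConfig = field(default_factory=SolverConfig)
    n_streamlines: int = 532
    rng_seed: int = 0
    max_length_mm: float = 300.0
    critical_gradient: float = -1.1
    min_count: int = 25
    bin_size_mm: float | None = None  # None = 2 x spacing
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    selection: str | tuple[int, ...] = "all"

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.input_volume is None):
            raise ValueError("exactly one of phantom / input_volume must be set")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if self.critical_gradient >= 0:
            raise ValueError("critical_gradient must be negative")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if d.get("phantom") is not None:
            ph = dict(d["phantom"])
            ph["shape"] = tuple(ph["shape"])
            d["phantom"] = PhantomSpec(**ph)
        if d.get("solver") is not None:
            sv = dict(d["solver"])
            if sv.get("body_force_lat") is not None:
                sv["body_force_lat"] = tuple(sv["body_force_lat"])
            d["solver"] = SolverConfig(**sv)
        if d.get("optimizer") is not None:
            d["optimizer"] = OptimizerConfig(**d["optimizer"])
        for key in ("seed_voxel", "sphere_center_mm", "cuboid_dims_mm"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if isinstance(d.get("selection"), list):
            d["selection"] = tuple(d["selection"])
        return cls(**d)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            if path.endswith((".yaml", ".yml")):
                return cls.from_dict(yaml.safe_load(fh))
            return cls.from_dict(json.load(fh))


def desk_phantom_config(constriction_factor: float = 0.5) -> RunConfig:
    """The shipped desk-scale constricted-phantom study.

    A 48 mm channel (radius 6 mm) with a raised-cosine constriction, a
    20 mm inlet sphere over the top face and a 10 x 16 x 16 mm outlet
    cuboid.  The flow rate of 60 ml/s keeps the constriction Reynolds
    number near 850, inside the steady laminar regime that a 0.5 mm lattice
    can resolve; analysis constants (criterion, seeds, cube sizes) are the
    clinical values.
    """
    return RunConfig(
        phantom=PhantomSpec(constriction_factor=constriction_factor),
        sphere_diameter_mm=20.0,
        cuboid_dims_mm=(10.0, 16.0, 16.0),
        solver=SolverConfig(flow_rate_ml_s=60.0, spacing_mm=0.5),
        bin_size_mm=1.0,
    )


def tiny_phantom_config() -> RunConfig:
    """A minutes-scale miniature of the desk study for smoke tests and
    determinism checks: coarser grid, fewer streamlines, same physics."""
    return RunConfig(
        phantom=PhantomSpec(
            shape=(48, 28, 28),
            spacing=1.0,
            channel_radius=5.0,
            constriction_factor=0.5,
            constriction_center=24.0,
            constriction_width=12.0,
        ),
        sphere_diameter_mm=16.0,
        cuboid_dims_mm=(8.0, 14.0, 14.0),
        solver=SolverConfig(flow_rate_ml_s=60.0, spacing_mm=1.0),
        n_streamlines=96,
        bin_size_mm=2.0,
    )
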