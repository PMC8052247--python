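"""Synthetic CT-like phantoms with known air-channel geometry.

Real nasal CT series are rarely shareable, so every downstream stage
(segmentation, flow simulation, streamline analysis, virtual surgery) is
exercised on generated Hounsfield-unit volumes: one or two air channels
(HU ~ -1000) embedded in soft tissue (HU ~ +40), optionally with a smooth
constriction (a "stenosis") and a septum-like lateral deviation.  Voxel
membership is decided by voxel-center inclusion, with no anti-aliasing, so
the air mask is exactly countable and segmentation targets are bit-exact.

Axis convention follows :mod:`rhinoflow.imaging`: axis 0 is the axial stack
(index 0 = most inferior slice, where the outlet sits; the top slice is the
"nostril" end), axes 1-2 are in-plane.  World mm = index * spacing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .imaging import HUVolume

__all__ = ["PhantomSpec", "GeometryError", "make_channel_phantom", "make_paired_phantoms"]


class GeometryError(ValueError):
    """Raised when the requested channel does not fit inside the volume."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a channel phantom.

    Lengths are millimetres.  ``constriction_factor`` multiplies the channel
    radius at the narrowest point (1.0 = no constriction); the radius profile
    is a raised-cosine bump of full width ``constriction_width`` centred at
    ``constriction_center`` along axis 0.  ``septum_deviation`` bows the
    channel centreline laterally (axis 2) by up to that many mm at
    mid-length.  With ``n_channels=2`` two parallel "nostril" channels run
    from the top and merge into a single duct toward the bottom
    ("nasopharynx") via overlapping cylinders.
    """

    shape: tuple[int, int, int] = (96, 64, 64)
    spacing: float = 0.5
    channel_radius: float = 6.0
    channel_length: float | None = None  # None = full axis-0 extent
    constriction_factor: float = 1.0
    constriction_center: float = 24.0
    constriction_width: float = 12.0
    septum_deviation: float = 0.0
    hu_air: float = -1000.0
    hu_tissue: float = 40.0
    n_channels: int = 1
    channel_separation: float = 14.0  # centre-to-centre at the nostril end
    merge_start: float | None = None  # axial mm where the two channels begin converging
    merge_blend: float = 10.0  # axial mm over which they converge

    def __post_init__(self) -> None:
        if not (0.0 < self.constriction_factor <= 1.0):
            raise ValueError("constriction_factor must be in (0, 1]")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.channel_radius <= 0:
            raise ValueError("channel_radius must be positive")
        if self.n_channels not in (1, 2):
            raise ValueError("n_channels must be 1 or 2")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["shape"] = tuple(d["shape"])
        return cls(**d)


def _radius_profile(spec: PhantomSpec, z: np.ndarray) -> np.ndarray:
    """Channel radius (mm) vs axial position z (mm): raised-cosine stenosis."""
    r = np.full_like(z, spec.channel_radius, dtype=float)
    if spec.constriction_factor < 1.0 and spec.constriction_width > 0:
        xi = (z - spec.constriction_center) / (spec.constriction_width / 2.0)
        bump = np.where(np.abs(xi) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * xi)), 0.0)
        r *= 1.0 - (1.0 - spec.constriction_factor) * bump
    return r


def _deviation_profile(spec: PhantomSpec, z: np.ndarray, length: float) -> np.ndarray:
    """Lateral (axis-2) centreline offset: half-sine bow, zero at both ends."""
    if spec.septum_deviation == 0.0:
        return np.zeros_like(z)
    return spec.septum_deviation * np.sin(np.pi * np.clip(z / length, 0.0, 1.0))


def _separation_profile(spec: PhantomSpec, z: np.ndarray, length: float) -> np.ndarray:
    """Half-distance between the two channel centres as a function of z."""
    merge_start = spec.merge_start if spec.merge_start is not None else 0.55 * length
    lo = merge_start - spec.merge_blend
    t = np.clip((z - lo) / max(spec.merge_blend, 1e-9), 0.0, 1.0)
    return 0.5 * spec.channel_separation * t


def make_channel_phantom(spec: PhantomSpec) -> HUVolume:
    """Rasterize the phantom into an HU volume.

    A voxel is air iff its centre lies inside one of the (possibly
    constricted, possibly deviated) tubes.  Deterministic: no RNG.

    Raises
    ------
    GeometryError
        If the air channel would touch the lateral faces of the volume
        (less than two voxels of tissue margin).
    """
    n0, n1, n2 = spec.shape
    sp = spec.spacing
    length = spec.channel_length if spec.channel_length is not None else (n0 - 1) * sp

    z = np.arange(n0) * sp  # axial position of each slice
    in_axis = z <= length + 1e-9
    r = _radius_profile(spec, z)
    dev = _deviation_profile(spec, z, length)

    c1 = (n1 - 1) / 2.0 * sp
    c2 = (n2 - 1) / 2.0 * sp

    y = np.arange(n1)[None, :, None] * sp
    x = np.arange(n2)[None, None, :] * sp

    rz = r[:, None, None]
    dy2 = (y - c1) ** 2

    if spec.n_channels == 1:
        cx = (c2 + dev)[:, None, None]
        air = dy2 + (x - cx) ** 2 <= rz**2
    else:
        sep = _separation_profile(spec, z, length)
        cx_l = (c2 - sep + dev)[:, None, None]
        cx_r = (c2 + sep + dev)[:, None, None]
        air = (dy2 + (x - cx_l) ** 2 <= rz**2) | (dy2 + (x - cx_r) ** 2 <= rz**2)

    air &= in_axis[:, None, None]

    # >=2 voxels of tissue margin on the lateral faces
    if air[:, :2, :].any() or air[:, -2:, :].any() or air[:, :, :2].any() or air[:, :, -2:].any():
        raise GeometryError("channel does not fit: less than 2 voxels of lateral tissue margin")
    if not air.any():
        raise GeometryError("phantom contains no air voxels")

    data = np.where(air, spec.hu_air, spec.hu_tissue).astype(np.float64)
    return HUVolume(data=data, spacing=(sp, sp, sp))


def make_paired_phantoms(spec: PhantomSpec) -> tuple[HUVolume, HUVolume]:
    """Pre/post surgery pair: the "pre" volume carries the constriction, the
    "post" volume is the same geometry with ``constriction_factor=1``.

    The post air mask is a strict superset of the pre air mask (the radius
    profile only grows), emulating a resected airway.
    """
    if spec.constriction_factor >= 1.0:
        raise ValueError("paired phantoms need constriction_factor < 1 (no pathology to remove)")
    pre = make_channel_phantom(spec)
    post = make_channel_phantom(dataclasses.replace(spec, constriction_factor=1.0))
    return pre, post
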