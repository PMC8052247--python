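"""Volume I/O, isotropic resampling, airway segmentation and boundary label maps.

The segmentation stage follows standard clinical practice for upper-airway
CT: resample to an isotropic grid, threshold at -300 HU (air vs soft
tissue), then region-grow from a seed placed inside the airway.  The flow
domain adds two artificial boundary bodies: a sphere over the nostrils
(pressure inlet, ambient air reservoir) and a cuboid at the nasopharynx
(velocity outlet, where the inhaled flow is drawn out).

Conventions
-----------
* axis 0 = axial stack, index 0 = most inferior slice (outlet side);
* world coordinates in mm = voxel index * spacing, 0-based, voxel centres;
* label coding: 0 solid, 1 interior fluid, 2 wall, 3 inlet (sphere
  surface), 4 outlet (cuboid surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "HUVolume",
    "FlowDomain",
    "SOLID",
    "INTERIOR",
    "WALL",
    "INLET",
    "OUTLET",
    "resample_isotropic",
    "segment_air",
    "build_boundaries",
    "domain_from_mask",
]

SOLID, INTERIOR, WALL, INLET, OUTLET = 0, 1, 2, 3, 4

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class HUVolume:
    """A 3-D scalar field in Hounsfield units with per-axis voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("HUVolume.data must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def save(self, path: str) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine), path)

    @classmethod
    def load(cls, path: str) -> "HUVolume":
        img = nib.load(path)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=np.asarray(img.dataobj, dtype=np.float64), spacing=spacing)


def save_mask(mask: np.ndarray, spacing: float | tuple[float, float, float], path: str) -> None:
    """Write a binary or label mask as NIfTI (uint8)."""
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3  # type: ignore[assignment]
    affine = np.diag([*spacing, 1.0])  # type: ignore[misc]
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), path)


def load_mask(path: str) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj, dtype=np.uint8)


def resample_isotropic(vol: HUVolume, target_spacing: float, order: int = 3) -> HUVolume:
    """Resample to an isotropic grid by spline interpolation.

    ``order=3`` (cubic) is the default, matching the behaviour of
    ``scipy.ndimage.zoom`` commonly used for CT preprocessing; ``order=1``
    gives trilinear, ``order=0`` nearest-neighbour.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if not np.isfinite(vol.data).all():
        raise ValueError("input volume contains non-finite values")
    factors = tuple(s / target_spacing for s in vol.spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return HUVolume(vol.data.copy(), (target_spacing,) * 3)
    out = ndi.zoom(vol.data, zoom=factors, order=order)
    return HUVolume(out, (target_spacing,) * 3)


def segment_air(
    vol: HUVolume, hu_threshold: float = -300.0, seed: tuple[int, int, int] = (0, 0, 0)
) -> np.ndarray:
    """26-connected region growing of the sub-threshold (air) set from a seed.

    Returns the boolean mask of the connected component of
    ``{HU < hu_threshold}`` containing ``seed``.
    """
    seed = tuple(int(s) for s in seed)
    if vol.data[seed] >= hu_threshold:
        raise ValueError(
            f"seed voxel {seed} has HU {vol.data[seed]:.1f} >= threshold {hu_threshold}; "
            "place the seed inside the airway"
        )
    below = vol.data < hu_threshold
    labels, _ = ndi.label(below, structure=_CONN26)
    return labels == labels[seed]


def _surface_of(body: np.ndarray) -> np.ndarray:
    """Voxels of ``body`` with a 6-neighbour outside the body (incl. array faces)."""
    eroded = ndi.binary_erosion(body, structure=ndi.generate_binary_structure(3, 1), border_value=0)
    return body & ~eroded


def _wall_of(fluid: np.ndarray) -> np.ndarray:
    """Fluid voxels with a 6-neighbour that is solid (array faces count as solid)."""
    return _surface_of(fluid)


@dataclass(frozen=True)
class FlowDomain:
    """Binary fluid mask + boundary label map on an isotropic grid.

    ``sphere_*`` / ``cuboid_*`` record the inlet/outlet body geometry in mm
    so labels can be rebuilt after the fluid mask changes (virtual surgery).
    Domains built directly from a mask (no bodies) have those fields None.
    """

    fluid_mask: np.ndarray
    labels: np.ndarray
    spacing: float
    sphere_center: tuple[float, float, float] | None = None
    sphere_diameter: float | None = None
    cuboid_center: tuple[float, float, float] | None = None
    cuboid_dims: tuple[float, float, float] | None = None
    periodic_axes: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.fluid_mask.shape != self.labels.shape:
            raise ValueError("fluid mask and label map must share shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fluid_mask.shape  # type: ignore[return-value]

    # -- geometric masks ---------------------------------------------------
    def _coords_mm(self):
        n0, n1, n2 = self.shape
        sp = self.spacing
        return (
            np.arange(n0)[:, None, None] * sp,
            np.arange(n1)[None, :, None] * sp,
            np.arange(n2)[None, None, :] * sp,
        )

    def sphere_mask(self) -> np.ndarray:
        if self.sphere_center is None:
            return np.zeros(self.shape, dtype=bool)
        z, y, x = self._coords_mm()
        c = self.sphere_center
        r = self.sphere_diameter / 2.0
        return (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= r**2

    def cuboid_mask(self) -> np.ndarray:
        if self.cuboid_center is None:
            return np.zeros(self.shape, dtype=bool)
        z, y, x = self._coords_mm()
        c, d = self.cuboid_center, self.cuboid_dims
        return (
            (np.abs(z - c[0]) <= d[0] / 2.0)
            & (np.abs(y - c[1]) <= d[1] / 2.0)
            & (np.abs(x - c[2]) <= d[2] / 2.0)
        )

    def airway_mask(self) -> np.ndarray:
        """Fluid voxels outside the artificial inlet/outlet bodies."""
        return self.fluid_mask & ~self.sphere_mask() & ~self.cuboid_mask()

    def min_airway_area_mm2(self, axis: int = 0) -> float:
        """Smallest cross-sectional airway area along ``axis`` (mm^2).

        Only slices where the airway (fluid excluding the boundary bodies)
        is present are considered; used to size the lattice time step from
        the peak expected velocity.
        """
        air = self.airway_mask()
        other = tuple(a for a in range(3) if a != axis)
        counts = air.sum(axis=other)
        # slices clipped by a boundary body under-count the true cross-section
        body = self.sphere_mask() | self.cuboid_mask()
        clean = body.sum(axis=other) == 0
        counts = counts[(counts > 0) & clean] if (clean & (counts > 0)).any() else counts[counts > 0]
        if counts.size == 0:
            raise ValueError("domain has no airway voxels outside the boundary bodies")
        return float(counts.min()) * self.spacing**2

    def with_fluid(self, new_fluid: np.ndarray) -> "FlowDomain":
        """Rebuild labels for a modified fluid mask, same body geometry."""
        labels = _label_domain(new_fluid, self.sphere_mask(), self.cuboid_mask())
        return replace(self, fluid_mask=new_fluid, labels=labels)


def _label_domain(fluid: np.ndarray, sphere: np.ndarray, cuboid: np.ndarray) -> np.ndarray:
    labels = np.zeros(fluid.shape, dtype=np.uint8)
    labels[fluid] = INTERIOR
    labels[_wall_of(fluid)] = WALL
    labels[fluid & _surface_of(sphere)] = INLET
    labels[fluid & _surface_of(cuboid)] = OUTLET
    return labels


def build_boundaries(
    air: np.ndarray,
    spacing: float,
    sphere_center: tuple[float, float, float] | None = None,
    sphere_diameter: float = 70.0,
    cuboid_dims: tuple[float, float, float] = (60.0, 40.0, 30.0),
    cuboid_center: tuple[float, float, float] | None = None,
) -> FlowDomain:
    """Attach the inlet sphere and outlet cuboid to a segmented airway.

    By default the cuboid midpoint is the centroid of the air voxels in the
    most inferior axial slice (index 0 along axis 0) that contains air, and
    the sphere is centred over the superior ("nostril") end of the airway.
    The clinical-scale defaults (70 mm sphere, 60x40x30 mm cuboid) suit
    patient CT; desk-scale phantoms pass proportionally smaller bodies.
    """
    air = air.astype(bool)
    if not air.any():
        raise ValueError("air mask is empty")
    sp = float(spacing)
    n0 = air.shape[0]

    if cuboid_center is None:
        ax_counts = air.sum(axis=(1, 2))
        i_low = int(np.nonzero(ax_counts)[0][0])
        idx = np.argwhere(air[i_low])
        c_in_plane = idx.mean(axis=0) * sp
        cuboid_center = (i_low * sp, float(c_in_plane[0]), float(c_in_plane[1]))

    if sphere_center is None:
        ax_counts = air.sum(axis=(1, 2))
        i_high = int(np.nonzero(ax_counts)[0][-1])
        idx = np.argwhere(air[i_high])
        c_in_plane = idx.mean(axis=0) * sp
        sphere_center = (i_high * sp, float(c_in_plane[0]), float(c_in_plane[1]))

    shell = FlowDomain(
        fluid_mask=air,
        labels=np.zeros(air.shape, dtype=np.uint8),
        spacing=sp,
        sphere_center=tuple(float(v) for v in sphere_center),
        sphere_diameter=float(sphere_diameter),
        cuboid_center=tuple(float(v) for v in cuboid_center),
        cuboid_dims=tuple(float(v) for v in cuboid_dims),
    )
    sphere = shell.sphere_mask()
    cuboid = shell.cuboid_mask()
    if not (sphere & air).any():
        raise ValueError("inlet sphere does not overlap the airway")
    if not (cuboid & air).any():
        raise ValueError("outlet cuboid does not overlap the airway")

    fluid = air | sphere | cuboid
    labels = _label_domain(fluid, sphere, cuboid)
    return replace(shell, fluid_mask=fluid, labels=labels)


def domain_from_mask(
    fluid: np.ndarray, spacing: float, periodic_axes: tuple[int, ...] = ()
) -> FlowDomain:
    """Wall/interior-only domain from a raw fluid mask (no inlet/outlet bodies).

    Used for closed boxes and duct benchmarks; ``periodic_axes`` lists axes
    whose array faces wrap around instead of acting as solid walls.
    """
    fluid = fluid.astype(bool)
    labels = np.zeros(fluid.shape, dtype=np.uint8)
    labels[fluid] = INTERIOR
    wall = _wall_of(fluid)
    # faces on periodic axes are not walls
    if periodic_axes:
        interior6 = ndi.binary_erosion(
            _pad_periodic(fluid, periodic_axes), structure=ndi.generate_binary_structure(3, 1)
        )
        interior6 = _unpad(interior6, periodic_axes)
        wall = fluid & ~interior6
    labels[wall] = WALL
    return FlowDomain(
        fluid_mask=fluid, labels=labels, spacing=float(spacing), periodic_axes=tuple(periodic_axes)
    )


def _pad_periodic(mask: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    pad = [(1, 1) if a in axes else (0, 0) for a in range(3)]
    return np.pad(mask, pad, mode="wrap")


def _unpad(mask: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    sl = tuple(slice(1, -1) if a in axes else slice(None) for a in range(3))
    return mask[sl]
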