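"""Voxelized digital thorax phantom.

Three water-equivalent cuboid targets (mimicking lung lesions) sit in a
lung-equivalent foam slab, which is sandwiched between water-equivalent
slabs.  Axes: z = superior–inferior (the rotation/motion axis), x = lateral,
y = anterior–posterior (the slab stacking direction).  All coordinates are
in mm in the phantom frame, whose origin is the scanner isocenter.

Voxelization is by center sampling: a voxel takes the attenuation of the
innermost region containing its center (target > foam > slab > air), which
keeps the construction deterministic; an optional supersampling factor
averages sub-voxel samples for smoother boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TargetSpec",
    "PhantomConfig",
    "VoxelVolume",
    "build_phantom",
    "target_axial_profile",
    "default_config",
]

Box = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class TargetSpec:
    """A cuboid target; the z extent is the stationary length L0 (mm)."""

    name: str
    extents: tuple[float, float, float]   # (x, y, z) lengths, mm
    center: tuple[float, float, float]    # (x, y, z) position, mm
    mu: float = 0.020                     # linear attenuation, 1/mm

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extents):
            raise ValueError(f"target {self.name!r}: extents must be > 0")
        if self.mu <= 0:
            raise ValueError(f"target {self.name!r}: mu must be > 0")

    @property
    def L0(self) -> float:
        """Stationary length along the motion axis, mm."""
        return self.extents[2]

    @property
    def bounds(self) -> Box:
        return tuple(
            (c - e / 2.0, c + e / 2.0) for c, e in zip(self.center, self.extents)
        )


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 2.0                  # isotropic voxel pitch, mm
    mu_foam: float = 0.005                # lung-equivalent foam, 1/mm
    mu_water: float = 0.020               # solid-water slabs, 1/mm
    mu_air: float = 0.0
    slab_region: Box = ((-80.0, 80.0), (-70.0, 70.0), (-96.0, 96.0))
    foam_region: Box = ((-80.0, 80.0), (-40.0, 40.0), (-96.0, 96.0))
    targets: tuple[TargetSpec, ...] = ()
    supersample: int = 1                  # sub-samples per axis per voxel

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(n < 1 for n in self.shape):
            raise ValueError("shape must be positive")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        for ax in range(3):
            lo_f, hi_f = self.foam_region[ax]
            lo_s, hi_s = self.slab_region[ax]
            if not (lo_s <= lo_f < hi_f <= hi_s):
                raise ValueError("foam region must lie inside the slab region")
        self._validate_targets()

    def _validate_targets(self) -> None:
        for t in self.targets:
            for ax in range(3):
                lo, hi = t.bounds[ax]
                flo, fhi = self.foam_region[ax]
                if not (flo <= lo and hi <= fhi):
                    raise ValueError(
                        f"target {t.name!r} extends outside the foam region on axis {ax}"
                    )
        for i, a in enumerate(self.targets):
            for b in self.targets[i + 1:]:
                if all(
                    a.bounds[ax][0] < b.bounds[ax][1] and b.bounds[ax][0] < a.bounds[ax][1]
                    for ax in range(3)
                ):
                    raise ValueError(f"targets {a.name!r} and {b.name!r} overlap")

    @property
    def origin(self) -> tuple[float, float, float]:
        """Center of voxel (0,0,0), grid centered on the isocenter."""
        return tuple(-(n - 1) / 2.0 * self.spacing for n in self.shape)

    def target(self, name: str) -> TargetSpec:
        for t in self.targets:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class VoxelVolume:
    """3-D linear-attenuation map (1/mm) with grid metadata."""

    values: np.ndarray                    # (nx, ny, nz)
    spacing: float                        # mm, isotropic
    origin: tuple[float, float, float]    # mm, center of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D")
        if not np.isfinite(self.values).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)

    def index_of(self, position: Sequence[float]) -> tuple[int, int, int]:
        """Voxel index whose center is nearest to a physical position."""
        idx = []
        for ax, p in enumerate(position):
            i = int(round((p - self.origin[ax]) / self.spacing))
            if not (0 <= i < self.shape[ax]):
                raise ValueError(f"position {position} outside the grid on axis {ax}")
            idx.append(i)
        return tuple(idx)

    def copy_with(self, values: np.ndarray) -> "VoxelVolume":
        return VoxelVolume(values=values, spacing=self.spacing, origin=self.origin)


def default_config(**overrides) -> PhantomConfig:
    """The three-target thorax phantom.

    Stationary lengths along z: small 10 mm, medium 20 mm, large 40 mm
    (cuboids 50 x 30 mm in-plane).  Targets sit on the right side of the
    foam slab — small superior, medium inferior, large medial — laterally
    offset from the rotation axis so all three stay inside both fan
    geometries at the largest range of motion, and offset from one another
    so each target's measurement column crosses no other target even when
    maximally blurred.  The slab/foam stack spans the whole grid along z
    (a long object, as real anatomy extends beyond the axial field of
    view), so axial profiles have a uniform foam baseline.
    """
    targets = (
        TargetSpec("small", (50.0, 30.0, 10.0), (50.0, 12.0, 50.0)),
        TargetSpec("medium", (50.0, 30.0, 20.0), (50.0, -12.0, -50.0)),
        TargetSpec("large", (50.0, 30.0, 40.0), (-45.0, 0.0, 0.0)),
    )
    return PhantomConfig(targets=targets, **overrides)


def _region_mask(bounds: Box, xs, ys, zs) -> np.ndarray:
    """Half-open [lo, hi) membership of voxel centers in an axis-aligned box."""
    mx = (xs >= bounds[0][0]) & (xs < bounds[0][1])
    my = (ys >= bounds[1][0]) & (ys < bounds[1][1])
    mz = (zs >= bounds[2][0]) & (zs < bounds[2][1])
    return mx[:, None, None] & my[None, :, None] & mz[None, None, :]


def build_phantom(config: PhantomConfig) -> VoxelVolume:
    """Rasterize the phantom onto its voxel grid.

    Each voxel takes the attenuation of the innermost enclosing region
    (target > foam > slab > air) at its center; with ``supersample > 1`` the
    voxel value is the mean over a regular sub-grid of sample points.
    """
    nx, ny, nz = config.shape
    sp = config.spacing
    origin = config.origin
    ss = config.supersample

    acc = np.zeros(config.shape, dtype=np.float64)
    # sub-sample offsets within a voxel, centered
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    for ox in offs:
        for oy in offs:
            for oz in offs:
                xs = origin[0] + sp * (np.arange(nx) + ox)
                ys = origin[1] + sp * (np.arange(ny) + oy)
                zs = origin[2] + sp * (np.arange(nz) + oz)
                vol = np.full(config.shape, config.mu_air, dtype=np.float64)
                vol[_region_mask(config.slab_region, xs, ys, zs)] = config.mu_water
                vol[_region_mask(config.foam_region, xs, ys, zs)] = config.mu_foam
                for t in config.targets:
                    vol[_region_mask(t.bounds, xs, ys, zs)] = t.mu
                acc += vol
    acc /= ss ** 3
    return VoxelVolume(values=acc, spacing=sp, origin=origin)


def target_axial_profile(volume: VoxelVolume, target: TargetSpec):
    """Attenuation along z at the (x, y) column nearest the target center.

    Returns ``(z_mm, values)`` — the ground-truth line through the target
    centroid, parallel to the motion axis.
    """
    ix, iy, _ = volume.index_of(target.center)
    return volume.axis_coords(2), volume.values[ix, iy, :].copy()
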