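"""Time-resolved cone-beam projection acquisition of the moving phantom.

Two protocols mirror a linac on-board imager: *half-fan* laterally offsets
the flat panel and scans a full circle (enlarged field of view, ~1 min);
*full-fan* centers the panel and scans a short arc (~half a minute).  The
kVp/mAs technique factors are carried as metadata only — projections are
ideal monochromatic line integrals; optional Poisson noise can be added in
the transmission domain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._kernels import forward_project_kernel
from .motion import MotionPattern
from .phantom import VoxelVolume

__all__ = ["ScanProtocol", "ProjectionSet", "angle_schedule", "forward_project", "add_noise"]


@dataclass(frozen=True)
class ScanProtocol:
    """Gantry arc, timing and flat-panel geometry for one CBCT scan."""

    mode: str                       # "half_fan" | "full_fan"
    arc_deg: float
    duration_s: float
    n_projections: int
    sad: float = 1000.0             # source-axis distance, mm
    sdd: float = 1500.0             # source-detector distance, mm
    nu: int = 128                   # detector columns (lateral)
    nv: int = 128                   # detector rows (axial)
    pitch: float = 3.0              # detector pixel pitch, mm
    lateral_offset_mm: float = 0.0  # panel shift along u (half-fan only)
    kvp: float = 0.0                # metadata only
    mas: float = 0.0                # metadata only

    def __post_init__(self) -> None:
        if self.mode not in ("half_fan", "full_fan"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if not (0 < self.arc_deg <= 360):
            raise ValueError("arc must be in (0, 360] degrees")
        if self.n_projections < 2:
            raise ValueError("need at least 2 projections")
        if not (self.sdd > self.sad > 0):
            raise ValueError("require SDD > SAD > 0")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.mode == "full_fan" and self.lateral_offset_mm != 0:
            raise ValueError("full-fan protocol must have zero lateral offset")

    @property
    def panel_half_width(self) -> float:
        return self.nu * self.pitch / 2.0

    @property
    def fan_half_angle(self) -> float:
        """Half fan angle (rad) of the detector around the piercing point."""
        reach = self.panel_half_width + abs(self.lateral_offset_mm)
        return math.atan2(reach, self.sdd)

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    @property
    def fov_radius(self) -> float:
        """Radius (mm) of the fully sampled field of view at the isocenter."""
        far = (self.panel_half_width + abs(self.lateral_offset_mm)) / self.magnification
        if self.lateral_offset_mm == 0:
            return far
        # displaced detector: full circle fills in the short side
        return far

    @classmethod
    def full_fan(cls, desk_scale: bool = False, **kw) -> "ScanProtocol":
        """Short-scan centered-panel protocol (head technique analogue)."""
        p = cls(
            mode="full_fan", arc_deg=200.0, duration_s=30.0,
            n_projections=200, kvp=100.0, mas=146.0, **kw,
        )
        return p.desk_scale() if desk_scale else p

    @classmethod
    def half_fan(cls, desk_scale: bool = False, **kw) -> "ScanProtocol":
        """Full-circle displaced-panel protocol (standard thorax analogue)."""
        kw.setdefault("lateral_offset_mm", 143.0)
        p = cls(
            mode="half_fan", arc_deg=360.0, duration_s=60.0,
            n_projections=360, kvp=125.0, mas=264.0, **kw,
        )
        return p.desk_scale() if desk_scale else p

    def desk_scale(self) -> "ScanProtocol":
        """Halve the projection count for quick desk-scale runs."""
        return replace(self, n_projections=max(2, self.n_projections // 2))


@dataclass
class ProjectionSet:
    """Stack of line-integral projections with angles and timestamps."""

    data: np.ndarray          # (n, nv, nu), dimensionless line integrals
    angles_rad: np.ndarray    # (n,)
    times_s: np.ndarray       # (n,), strictly increasing over [0, duration]
    protocol: ScanProtocol

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.angles_rad = np.asarray(self.angles_rad, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        n = self.data.shape[0]
        if self.angles_rad.shape != (n,) or self.times_s.shape != (n,):
            raise ValueError("angles/timestamps must match the projection count")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.isfinite(self.data).all():
            raise ValueError("projections contain non-finite values")

    @property
    def n(self) -> int:
        return self.data.shape[0]


def angle_schedule(protocol: ScanProtocol):
    """Uniform gantry angles over the arc and timestamps over the duration.

    Returns ``(angles_rad, times_s)``, both of length ``n_projections`` and
    including both endpoints (a 360-degree arc therefore samples the closing
    direction twice; the reconstruction weights account for this).
    """
    angles = np.deg2rad(np.linspace(0.0, protocol.arc_deg, protocol.n_projections))
    times = np.linspace(0.0, protocol.duration_s, protocol.n_projections)
    return angles, times


def _check_in_view(volume: VoxelVolume, pattern: MotionPattern, protocol: ScanProtocol) -> None:
    """Warn when phantom content can leave the imaged field of view."""
    xs = volume.axis_coords(0)
    ys = volume.axis_coords(1)
    nonzero = np.argwhere(volume.values != 0)
    if nonzero.size == 0:
        return
    rx = max(abs(xs[nonzero[:, 0].min()]), abs(xs[nonzero[:, 0].max()]))
    ry = max(abs(ys[nonzero[:, 1].min()]), abs(ys[nonzero[:, 1].max()]))
    if math.hypot(rx, ry) > protocol.fov_radius:
        warnings.warn(
            "phantom content extends beyond the lateral field of view; "
            "apparent lengths near the edge are unreliable",
            stacklevel=3,
        )
    # axial coverage at the worst displacement
    zs = volume.axis_coords(2)
    z_lo = zs[nonzero[:, 2].min()]
    z_hi = zs[nonzero[:, 2].max()]
    t = np.linspace(0.0, protocol.duration_s, 512)
    dz = np.atleast_1d(pattern.displacement(t))
    z_reach = max(abs(z_lo + dz.min()), abs(z_hi + dz.max()))
    v_cov = protocol.nv * protocol.pitch / 2.0 / protocol.magnification
    if z_reach > v_cov:
        warnings.warn(
            "phantom moves partially out of the axial field of view during the scan",
            stacklevel=3,
        )


def forward_project(
    volume: VoxelVolume,
    pattern: MotionPattern,
    protocol: ScanProtocol,
    step: float | None = None,
) -> ProjectionSet:
    """Simulate the time-resolved cone-beam acquisition of a moving phantom.

    For each (angle, timestamp) pair the phantom is rigidly displaced along
    z by ``pattern.displacement(t)`` (implemented as shifted sampling, exact
    for rigid 1-D motion) and line integrals source->pixel are computed by
    ray marching with trilinear interpolation.

    Parameters
    ----------
    step : float, optional
        Ray-march step in mm; defaults to half the voxel spacing.
    """
    if not np.isfinite(volume.values).all():
        raise ValueError("volume contains NaN/Inf")
    _check_in_view(volume, pattern, protocol)
    angles, times = angle_schedule(protocol)
    dzs = np.atleast_1d(np.asarray(pattern.displacement(times), dtype=np.float64))
    if step is None:
        step = volume.spacing / 2.0
    data = forward_project_kernel(
        np.ascontiguousarray(volume.values, dtype=np.float64),
        float(volume.spacing),
        float(volume.origin[0]), float(volume.origin[1]), float(volume.origin[2]),
        angles, dzs,
        float(protocol.sad), float(protocol.sdd),
        protocol.nu, protocol.nv, float(protocol.pitch),
        float(protocol.lateral_offset_mm), float(step),
    )
    return ProjectionSet(data=data, angles_rad=angles, times_s=times, protocol=protocol)


def add_noise(projections: ProjectionSet, photons_per_ray: float, seed: int) -> ProjectionSet:
    """Poisson noise in the transmission domain, re-logged to line integrals.

    Each ray's expected photon count is ``N0 * exp(-p)``; a Poisson draw is
    re-logged as ``-log(max(count, 0.5)/N0)``.  Seeded and reproducible.
    Disabled by default in the pipeline — the elongation analysis is
    geometric, not dosimetric.
    """
    if photons_per_ray <= 0:
        raise ValueError("photons_per_ray must be > 0")
    rng = np.random.default_rng(seed)
    transmitted = photons_per_ray * np.exp(-projections.data)
    counts = rng.poisson(transmitted).astype(np.float64)
    noisy = -np.log(np.maximum(counts, 0.5) / photons_per_ray)
    return ProjectionSet(
        data=noisy,
        angles_rad=projections.angles_rad.copy(),
        times_s=projections.times_s.copy(),
        protocol=projections.protocol,
    )
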