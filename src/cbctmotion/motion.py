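"""Rigid one-dimensional phantom trajectories along the superior–inferior (z) axis.

The moving platform carries the whole phantom, so every voxel shares one
trajectory.  Two motion families are supported:

* sinusoidal respiration surrogate  ``Z(t) = Zo + A·sin(2πf·t + φ)``
* constant speed                    ``Z(t) = Zo + Vp·t``

plus the degenerate static case.  The peak-to-peak excursion (range of
motion) is ``ROM = 2A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MotionPattern", "sinusoidal", "constant_speed", "static"]


@dataclass(frozen=True)
class MotionPattern:
    """One-dimensional rigid trajectory of the phantom along z.

    Parameters
    ----------
    kind : {"sinusoidal", "constant", "static"}
    A : float
        Amplitude in mm (sinusoidal); ROM = 2A.
    f : float
        Frequency in Hz; omega = 2*pi*f.
    phi : float
        Phase in radians at t = 0.
    Vp : float
        Speed in mm/s (constant mode).
    Zo : float
        Reference offset in mm.
    """

    kind: str = "static"
    A: float = 0.0
    f: float = 0.25
    phi: float = 0.0
    Vp: float = 0.0
    Zo: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoidal", "constant", "static"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.A < 0:
            raise ValueError("amplitude A must be >= 0")
        if self.kind == "sinusoidal" and self.f <= 0:
            raise ValueError("sinusoidal motion needs f > 0")
        if self.kind == "static" and (self.A != 0 or self.Vp != 0):
            raise ValueError("static pattern must have A = 0 and Vp = 0")

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi*f in rad/s."""
        return 2.0 * math.pi * self.f

    @property
    def rom(self) -> float:
        """Range of motion (peak to peak), 2A, in mm."""
        return 2.0 * self.A

    @property
    def period(self) -> float:
        """Motion period 1/f in seconds."""
        if self.f <= 0:
            raise ValueError("period undefined for f <= 0")
        return 1.0 / self.f

    # -- kinematics ---------------------------------------------------------

    def displacement(self, t):
        """Position Z(t) in mm; `t` may be scalar or array, in seconds."""
        t = np.asarray(t, dtype=float)
        if self.kind == "sinusoidal":
            out = self.Zo + self.A * np.sin(self.omega * t + self.phi)
        elif self.kind == "constant":
            out = self.Zo + self.Vp * t
        else:
            out = np.full_like(t, self.Zo)
        return out if out.ndim else float(out)

    def velocity(self, t):
        """Speed dZ/dt in mm/s; peak sinusoidal speed is omega*A."""
        t = np.asarray(t, dtype=float)
        if self.kind == "sinusoidal":
            out = self.omega * self.A * np.cos(self.omega * t + self.phi)
        elif self.kind == "constant":
            out = np.full_like(t, self.Vp)
        else:
            out = np.zeros_like(t)
        return out if out.ndim else float(out)

    # -- dwell (time-occupancy) density -------------------------------------

    def dwell_density(self, z_spacing: float):
        """Time-occupancy density of the sinusoid over >= 1 full period.

        A point following ``A·sin(ωt+φ)`` spends a fraction of time at
        displacement ``u`` given by the arcsine law ``p(u) = 1/(π·√(A²−u²))``
        on (−A, A), independent of f and φ.  The density is discretized on a
        z grid of pitch `z_spacing` by integrating the exact CDF over each
        voxel-wide bin, so it sums to 1 and its support is exactly [−A, A].

        Returns
        -------
        offsets : ndarray
            Bin-center offsets in mm, symmetric about 0.
        weights : ndarray
            Bin masses, summing to 1.
        """
        if self.kind not in ("sinusoidal", "static"):
            raise ValueError("dwell density is defined for sinusoidal/static motion")
        if z_spacing <= 0:
            raise ValueError("z_spacing must be > 0")
        if self.A == 0:
            return np.array([0.0]), np.array([1.0])
        # outermost bin whose [k*dz - dz/2, k*dz + dz/2] overlaps (-A, A)
        k_max = int(math.floor(self.A / z_spacing + 0.5))
        if self.A / z_spacing + 0.5 == k_max and k_max > 0:
            k_max -= 1  # bin only touches the support endpoint
        k = np.arange(-k_max, k_max + 1)
        lo = np.clip(k * z_spacing - z_spacing / 2.0, -self.A, self.A)
        hi = np.clip(k * z_spacing + z_spacing / 2.0, -self.A, self.A)
        cdf = lambda u: 0.5 + np.arcsin(u / self.A) / math.pi
        weights = cdf(hi) - cdf(lo)
        weights /= weights.sum()
        return k.astype(float) * z_spacing, weights


def sinusoidal(A: float, f: float = 0.25, phi: float = 0.0, Zo: float = 0.0) -> MotionPattern:
    """Sinusoidal respiration surrogate; A in mm, f in Hz, phi in rad."""
    if A == 0:
        return static(Zo)
    return MotionPattern(kind="sinusoidal", A=A, f=f, phi=phi, Zo=Zo)


def constant_speed(Vp: float, Zo: float = 0.0) -> MotionPattern:
    """Constant-speed drift at Vp mm/s."""
    if Vp == 0:
        return static(Zo)
    return MotionPattern(kind="constant", Vp=Vp, Zo=Zo)


def static(Zo: float = 0.0) -> MotionPattern:
    return MotionPattern(kind="static", Zo=Zo)
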