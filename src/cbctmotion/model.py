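"""Closed-form predictions of mobile-target elongation in cone-beam CT.

With a stationary couch, a target drifting at constant speed Vp that stays
in the imaging view for time T appears elongated to

    L = L0 + Vp*T .

For cyclic (sinusoidal) motion of amplitude A whose period is shorter than
the scan, every target voxel sweeps the full excursion (-A, A) during
acquisition, so the maximal apparent length is

    L_max = L0 + 2A = L0 + ROM ,

independent of frequency and phase.  The instantaneous form
``L(t) = L0 + [wA cos(wt+phi)]*t`` is exposed verbatim for plotting; it is
unbounded in t and the pipeline anchors its comparisons on L_max (cyclic)
and on the constant-speed law.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .motion import MotionPattern

__all__ = [
    "length_constant_speed",
    "length_instantaneous",
    "length_max_cyclic",
    "motion_period",
    "ModelPrediction",
    "predict",
]


def length_constant_speed(L0, Vp, T):
    """Apparent length L0 + Vp*T of a target drifting at constant speed.

    Parameters are the stationary length L0 (mm), speed Vp (mm/s, >= 0) and
    the in-view time T (s).  Broadcasts over array inputs.
    """
    L0, Vp, T = np.asarray(L0, float), np.asarray(Vp, float), np.asarray(T, float)
    if np.any(L0 <= 0):
        raise ValueError("L0 must be > 0")
    if np.any(Vp < 0) or np.any(T < 0):
        raise ValueError("Vp and T must be >= 0")
    out = L0 + Vp * T
    return out if out.ndim else float(out)


def length_instantaneous(L0: float, A: float, f: float, phi: float, t):
    """Instantaneous apparent length L0 + 2*pi*f*A*cos(2*pi*f*t + phi)*t.

    Implemented exactly as written, without clamping: for large t the value
    may fall below L0 (or 0).  Intended for inspection/plotting only.
    """
    if L0 <= 0:
        raise ValueError("L0 must be > 0")
    if A < 0:
        raise ValueError("A must be >= 0")
    if f <= 0:
        raise ValueError("f must be > 0")
    t = np.asarray(t, float)
    w = 2.0 * math.pi * f
    out = L0 + (w * A * np.cos(w * t + phi)) * t
    return out if out.ndim else float(out)


def length_max_cyclic(L0, A, scan_duration: float | None = None, f: float | None = None):
    """Maximal apparent length L0 + 2A of a cyclically moving target.

    Valid when the scan lasts at least one motion period, so the target
    sweeps its full excursion during acquisition; independent of frequency
    and phase.  If `scan_duration` and `f` are given and the scan is shorter
    than one period, a warning is raised (the value is still returned).
    """
    L0, A = np.asarray(L0, float), np.asarray(A, float)
    if np.any(L0 <= 0):
        raise ValueError("L0 must be > 0")
    if np.any(A < 0):
        raise ValueError("A must be >= 0")
    if scan_duration is not None and f is not None and scan_duration < 1.0 / f:
        warnings.warn(
            "scan shorter than one motion period: the full-excursion "
            "elongation L0 + 2A may not be reached",
            stacklevel=2,
        )
    out = L0 + 2.0 * A
    return out if out.ndim else float(out)


def motion_period(f: float) -> float:
    """Period 1/f in seconds (15 cycles/min -> 4 s)."""
    if f <= 0:
        raise ValueError("frequency must be > 0")
    return 1.0 / f


@dataclass(frozen=True)
class ModelPrediction:
    """Bundle of the model's predictions for one target and motion pattern."""

    L0: float
    pattern: MotionPattern
    T: float                      # in-view scan time, s

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise ValueError("L0 must be > 0")
        if self.T < 0:
            raise ValueError("T must be >= 0")

    @property
    def L_constant(self) -> float:
        """Constant-speed prediction L0 + Vp*T (Vp = 0 unless constant kind)."""
        vp = self.pattern.Vp if self.pattern.kind == "constant" else 0.0
        return length_constant_speed(self.L0, vp, self.T)

    @property
    def L_max(self) -> float:
        """Cyclic-motion maximal length L0 + 2A."""
        return length_max_cyclic(self.L0, self.pattern.A)

    def L_of_t(self, t):
        """Instantaneous length for sinusoidal patterns (plotting aid)."""
        if self.pattern.kind != "sinusoidal":
            raise ValueError("L_of_t is defined for sinusoidal motion")
        return length_instantaneous(
            self.L0, self.pattern.A, self.pattern.f, self.pattern.phi, t
        )


def predict(L0: float, pattern: MotionPattern, T: float) -> ModelPrediction:
    return ModelPrediction(L0=L0, pattern=pattern, T=T)
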