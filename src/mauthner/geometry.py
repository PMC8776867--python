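"""Looming-stimulus geometry and contrast.

An expanding dark disk on a screen stands in for an object on collision
course.  Two idealizations coexist and are kept distinct: the on-screen disk
grows *exponentially* in diameter (what the projector showed), while the
conventional L/V summary assumes a *constant-velocity* approach of an object
of size L at speed V, for which the subtended angle is
theta(t) = 2*atan(L / (2*V*(t_c - t))).  Angles are degrees at the interface,
radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "LoomSpec",
    "ContrastSpec",
    "MICHELSON_LABELS",
    "subtended_angle",
    "viewing_distance_from_angle",
    "loom_diameter",
    "loom_angle",
    "l_over_v",
    "michelson_index",
]

#: The six visual contrasts used in the study (Michelson index magnitudes).
MICHELSON_LABELS = (0.03, 0.07, 0.12, 0.21, 0.33, 0.49)


@dataclass
class LoomSpec:
    """On-screen loom: exponential diameter growth over a fixed duration."""

    d_start: float = 0.27       # cm
    d_end: float = 18.15        # cm
    duration: float = 5.3       # s
    theta_start: float = 2.06   # degrees
    theta_end: float = 100.84   # degrees
    viewing_distance: Optional[float] = None  # cm; derived if unset

    def __post_init__(self) -> None:
        if not 0 < self.d_start < self.d_end:
            raise ValueError("require 0 < d_start < d_end")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.theta_end > self.theta_start:
            raise ValueError("theta_end must exceed theta_start")
        if self.viewing_distance is None:
            # anchor on the initial (least rounded) angle
            self.viewing_distance = viewing_distance_from_angle(
                self.d_start, self.theta_start
            )


@dataclass
class ContrastSpec:
    """Disk/background irradiance pair with its Michelson index."""

    i_disk: float
    i_background: float

    def __post_init__(self) -> None:
        if self.i_disk < 0 or self.i_background < 0:
            raise ValueError("irradiances must be non-negative")

    @property
    def michelson(self) -> float:
        return michelson_index(self.i_disk, self.i_background)

    @property
    def michelson_magnitude(self) -> float:
        """|MI|; the convention used to label dark-on-light looms."""
        return abs(self.michelson)


def subtended_angle(diameter: float, viewing_distance: float) -> float:
    """Angle (degrees) subtended by a disk of ``diameter`` at ``viewing_distance`` (cm)."""
    if viewing_distance <= 0:
        raise ValueError("viewing_distance must be positive")
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    return math.degrees(2.0 * math.atan(diameter / (2.0 * viewing_distance)))


def viewing_distance_from_angle(diameter: float, theta: float) -> float:
    """Distance (cm) at which ``diameter`` subtends ``theta`` degrees."""
    if not 0 < theta < 180:
        raise ValueError("theta must lie in (0, 180) degrees")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return diameter / (2.0 * math.tan(math.radians(theta) / 2.0))


def loom_diameter(t: float, spec: LoomSpec) -> float:
    """On-screen diameter (cm) at time ``t`` (s) into the exponential expansion."""
    if not 0 <= t <= spec.duration:
        raise ValueError("t outside the stimulus")
    return spec.d_start * (spec.d_end / spec.d_start) ** (t / spec.duration)


def loom_angle(t: float, spec: LoomSpec) -> float:
    """Subtended angle (degrees) of the on-screen loom at time ``t`` (s)."""
    return subtended_angle(loom_diameter(t, spec), spec.viewing_distance)


def l_over_v(theta_start: float, theta_end: float, duration: float) -> float:
    """Size-to-speed ratio (s) of the constant-velocity approach spanning the
    given initial and final subtended angles (degrees) in ``duration`` seconds.

    L/V = 2 * duration / (cot(theta_start/2) - cot(theta_end/2)).
    """
    if not 0 < theta_start < theta_end < 180:
        raise ValueError("require 0 < theta_start < theta_end < 180 degrees")
    if duration <= 0:
        raise ValueError("duration must be positive")
    cot0 = 1.0 / math.tan(math.radians(theta_start) / 2.0)
    cot1 = 1.0 / math.tan(math.radians(theta_end) / 2.0)
    denom = cot0 - cot1
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("degenerate angle pair")
    return 2.0 * duration / denom


def michelson_index(i_disk: float, i_background: float) -> float:
    """Michelson contrast (I_disk - I_background) / (I_disk + I_background)."""
    if i_disk < 0 or i_background < 0:
        raise ValueError("irradiances must be non-negative")
    total = i_disk + i_background
    if total == 0:
        raise ValueError("both irradiances are zero; contrast undefined")
    return (i_disk - i_background) / total
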