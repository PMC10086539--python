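"""Strike-aligned coordinate frame.

The strike direction is the overall direction of head travel over the first
10 video frames of the strike. Both the force-sensor axes and the
digitization axes are rotated by the same angle theta so that the strike
direction maps to +x' (the fore-aft axis), the horizontal perpendicular to
+y' (lateral), and the vertical channel passes through unchanged:

    x' =  x cos(theta) + y sin(theta)
    y' = -x sin(theta) + y cos(theta)

Forces rotate as free vectors; positions rotate about the head position at
strike onset.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .io import ForceTrace, KinematicTrace

__all__ = ["StrikeFrameSpec", "compute_strike_direction", "rotate_to_strike_frame"]


class StrikeFrameError(ValueError):
    pass


@dataclass(frozen=True)
class StrikeFrameSpec:
    """Planar rotation taking lab/sensor axes into the strike frame.

    ``theta`` is the angle from the original +x axis to the strike direction,
    in (-pi, pi]; ``origin`` is the head position at onset (rotation center
    for positions).
    """

    theta: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not (-math.pi < self.theta <= math.pi):
            raise StrikeFrameError(f"theta must be in (-pi, pi], got {self.theta}")

    def apply(self, x: np.ndarray, y: np.ndarray, *, about_origin: bool = False):
        """Rotate planar samples into the strike frame (strike axis -> +x')."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        if about_origin:
            x = x - self.origin[0]
            y = y - self.origin[1]
        return x * c + y * s, -x * s + y * c

    def invert(self, xp: np.ndarray, yp: np.ndarray, *, about_origin: bool = False):
        c, s = math.cos(self.theta), math.sin(self.theta)
        x, y = xp * c - yp * s, xp * s + yp * c
        if about_origin:
            x = x + self.origin[0]
            y = y + self.origin[1]
        return x, y


def compute_strike_direction(
    kin: KinematicTrace, t_onset: float, n_frames: int = 10
) -> StrikeFrameSpec:
    """Strike direction from head displacement over ``n_frames`` video frames.

    The direction is taken from the head position at the onset frame to the
    position ``n_frames`` frames later; theta = atan2(dy, dx).
    """
    # first frame at or after onset (tolerant of float fuzz on the grid)
    i0 = int(np.searchsorted(kin.time, t_onset - 0.5 / kin.rate))
    i1 = i0 + n_frames
    if i1 >= len(kin):
        raise StrikeFrameError(
            f"need {n_frames} frames after onset; only {len(kin) - 1 - i0} available"
        )
    dx = kin.head_x[i1] - kin.head_x[i0]
    dy = kin.head_y[i1] - kin.head_y[i0]
    if math.hypot(dx, dy) == 0.0:
        raise StrikeFrameError("zero head displacement over direction window")
    return StrikeFrameSpec(
        theta=math.atan2(dy, dx),
        origin=(float(kin.head_x[i0]), float(kin.head_y[i0])),
    )


def rotate_to_strike_frame(trace, spec: StrikeFrameSpec):
    """Rotate a ForceTrace or KinematicTrace into the strike frame.

    Returns a trace of the same type: for forces, (fx, fy) become
    (fore-aft, lateral) and fz passes through; for kinematics, head and tail
    positions are rotated about the onset origin so +x' is the strike axis.
    """
    if isinstance(trace, ForceTrace):
        fa, lat = spec.apply(trace.fx, trace.fy)
        return dataclasses.replace(trace, fx=fa, fy=lat)
    if isinstance(trace, KinematicTrace):
        hx, hy = spec.apply(trace.head_x, trace.head_y, about_origin=True)
        tx, ty = spec.apply(trace.tail_x, trace.tail_y, about_origin=True)
        return dataclasses.replace(trace, head_x=hx, head_y=hy, tail_x=tx, tail_y=ty)
    raise TypeError(f"cannot rotate object of type {type(trace).__name__}")
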