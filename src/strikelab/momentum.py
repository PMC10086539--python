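"""Impulse-momentum accounting for the strike.

To accelerate its head forward a snake must impart equal and opposite
momentum to the ground, to its own posterior body and tail, or to both. The
force plate sees only the ground share, so ground impulse alone understates
the head's momentum change whenever the tail recoils rearward (the
"inertial appendage" strategy). This module formalizes that argument with a
two-point-mass abstraction of the continuous body: a declared head/tail
mass split, momentum changes of each mass along the strike axis, the
fore-aft ground impulse, and the bookkeeping residual

    residual = m_h dv_h + m_t dv_t - ground impulse,

which is reported, never dropped — it is the model error of the two-mass
reduction. By default the budget is taken over the momentum-delivery phase
(onset to peak head fore-aft velocity): over the full strike window the
head returns to rest and the budget degenerates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .smooth import SmoothedSignal

__all__ = ["MomentumBudget", "compute_budget", "classify_strategy", "delivery_window"]


@dataclass(frozen=True)
class MomentumBudget:
    """Strike-axis momentum budget over one time window."""

    head_momentum_change: float  # kg m/s, m_h * dv_h
    tail_momentum_change: float  # kg m/s, m_t * dv_t
    ground_fa_impulse: float  # N*s
    residual: float  # N*s, head + tail - ground
    head_mass: float  # kg
    tail_mass: float  # kg
    window: tuple[float, float]

    @property
    def relative_residual(self) -> float:
        scale = max(abs(self.head_momentum_change), abs(self.ground_fa_impulse))
        return abs(self.residual) / scale if scale > 0 else 0.0

    @property
    def tail_fraction(self) -> float:
        """Fraction of head momentum balanced by tail counter-momentum."""
        if self.head_momentum_change == 0.0:
            return 0.0
        return -self.tail_momentum_change / self.head_momentum_change


def delivery_window(
    head_vel: Callable, t_onset: float, t_end: float
) -> tuple[float, float]:
    """Onset to the time of peak fore-aft head velocity (momentum delivery)."""
    grid = np.linspace(t_onset, t_end, 2001)
    v = head_vel(grid)
    return t_onset, float(grid[int(np.argmax(v))])


def compute_budget(
    head_vel: Callable,
    tail_vel: Callable,
    f_fa: SmoothedSignal,
    window: tuple[float, float],
    mass: float,
    head_fraction: float,
    tail_fraction: float | None = None,
) -> MomentumBudget:
    """Two-mass momentum budget on the strike axis over ``window``.

    ``head_vel`` and ``tail_vel`` are callables returning the smoothed
    strike-axis velocity at a time t; ``f_fa`` is the smoothed fore-aft
    ground force, integrated exactly over the window. The head/tail mass
    fractions must sum to 1.
    """
    if tail_fraction is None:
        tail_fraction = 1.0 - head_fraction
    if abs(head_fraction + tail_fraction - 1.0) > 1e-9:
        raise ValueError(
            f"mass split fractions must sum to 1, got "
            f"{head_fraction} + {tail_fraction}"
        )
    if not 0 < head_fraction <= 1:
        raise ValueError("head fraction must be in (0, 1]")
    a, b = window
    if not a < b:
        raise ValueError(f"empty budget window {window}")
    m_h = head_fraction * mass
    m_t = tail_fraction * mass
    dp_head = m_h * float(head_vel(b) - head_vel(a))
    dp_tail = m_t * float(tail_vel(b) - tail_vel(a))
    impulse = f_fa.integrate(a, b)
    return MomentumBudget(
        head_momentum_change=dp_head,
        tail_momentum_change=dp_tail,
        ground_fa_impulse=impulse,
        residual=dp_head + dp_tail - impulse,
        head_mass=m_h,
        tail_mass=m_t,
        window=(float(a), float(b)),
    )


def classify_strategy(
    budget: MomentumBudget, low: float = 0.25, high: float = 0.75
) -> str:
    """Label the strike by how much head momentum the tail balances.

    tail fraction < ``low``  -> "ground-dominated"
    tail fraction > ``high`` -> "tail-dominated"
    otherwise                -> "mixed"
    """
    f = budget.tail_fraction
    if f < low:
        return "ground-dominated"
    if f > high:
        return "tail-dominated"
    return "mixed"
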