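"""End-to-end per-trial analysis: raw traces to strike metrics.

Order of operations for one trial:

1. synchronize the force and video clocks at the camera trigger;
2. smooth the head path, detect a provisional onset from head speed;
3. estimate the strike direction from the first 10 video frames of head
   travel and rotate both the force and digitization axes into the
   strike-aligned frame;
4. re-detect onset and end of forward progress on the fore-aft head
   velocity;
5. compute the strike variables (and, optionally, the two-mass momentum
   budget) over the strike window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .frame import StrikeFrameSpec, compute_strike_direction, rotate_to_strike_frame
from .io import ForceTrace, KinematicTrace, TrialMeta, synchronize
from .metrics import StrikeMetrics, compute_metrics
from .momentum import MomentumBudget, classify_strategy, compute_budget, delivery_window
from .smooth import StrikeEvents, detect_end_forward, detect_onset, fit_smoothing_spline

__all__ = ["AnalysisConfig", "TrialResult", "analyze_trial", "detect_strike_events"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings (defaults logged with every result)."""

    n_frames_direction: int = 10
    onset_peak_fraction: float = 0.05
    onset_velocity_floor: float = 0.05  # m/s
    onset_hold_s: float = 0.010
    min_peak_velocity: float = 0.1  # m/s
    lam_force: float | None = None  # None -> GCV
    lam_kin: float | None = None
    spline_forces: bool = True
    tare_vertical: bool = False
    fv_floor_bw: float = 0.05
    sensor_camera_rotation: float = 0.0  # rad, fixed co-registration offset
    momentum_split: tuple[float, float] | None = None  # (head, tail) fractions


@dataclass(frozen=True)
class TrialResult:
    metrics: StrikeMetrics
    events: StrikeEvents
    frame: StrikeFrameSpec
    budget: MomentumBudget | None = None
    strategy: str | None = None

    def as_dict(self, meta: TrialMeta) -> dict:
        row = {
            "trial_id": meta.trial_id,
            "individual": meta.individual_id,
            "setup": meta.setup,
            "mass": meta.mass,
            "mu": meta.mu,
        }
        row.update(self.metrics.as_dict())
        if self.budget is not None:
            row.update(
                {
                    "head_momentum_change": self.budget.head_momentum_change,
                    "tail_momentum_change": self.budget.tail_momentum_change,
                    "ground_fa_impulse": self.budget.ground_fa_impulse,
                    "momentum_residual": self.budget.residual,
                    "tail_momentum_fraction": self.budget.tail_fraction,
                    "strategy": self.strategy,
                }
            )
        return row


def _eval_grid(t_lo: float, t_hi: float, rate: float) -> np.ndarray:
    n = int(np.floor((t_hi - t_lo) * rate))
    return t_lo + np.arange(n + 1) / rate


def detect_strike_events(
    velocity_time: np.ndarray,
    velocity: np.ndarray,
    config: AnalysisConfig = AnalysisConfig(),
) -> StrikeEvents:
    """Onset and end of forward progress from a fore-aft velocity signal."""
    t_on = detect_onset(
        velocity_time,
        velocity,
        peak_fraction=config.onset_peak_fraction,
        velocity_floor=config.onset_velocity_floor,
        hold_s=config.onset_hold_s,
        min_peak_velocity=config.min_peak_velocity,
    )
    t_end, warns = detect_end_forward(velocity_time, velocity, t_on)
    return StrikeEvents(t_onset=t_on, t_end_forward=t_end, warnings=warns)


def analyze_trial(
    force: ForceTrace,
    kin: KinematicTrace,
    meta: TrialMeta,
    config: AnalysisConfig = AnalysisConfig(),
) -> TrialResult:
    """Run the full analysis for one trial."""
    force_s, kin_s, (t_lo, t_hi) = synchronize(force, kin, meta)

    # provisional onset from head speed (direction-free)
    hx = fit_smoothing_spline(kin_s.time, kin_s.head_x, lam=config.lam_kin)
    hy = fit_smoothing_spline(kin_s.time, kin_s.head_y, lam=config.lam_kin)
    grid = _eval_grid(t_lo, t_hi, meta.force_rate)
    speed = np.hypot(hx(grid, nu=1), hy(grid, nu=1))
    t_on0 = detect_onset(
        grid,
        speed,
        peak_fraction=config.onset_peak_fraction,
        velocity_floor=config.onset_velocity_floor,
        hold_s=config.onset_hold_s,
        min_peak_velocity=config.min_peak_velocity,
    )

    # estimate the direction from the smoothed head path: the raw 10-frame
    # displacement is only a few mm and digitization noise would dominate
    kin_smooth = dataclasses.replace(
        kin_s, head_x=np.asarray(hx(kin_s.time)), head_y=np.asarray(hy(kin_s.time))
    )
    spec = compute_strike_direction(
        kin_smooth, t_on0, n_frames=config.n_frames_direction
    )
    if config.sensor_camera_rotation != 0.0:
        # forces live in the sensor frame, rotated from the camera frame by a
        # fixed, known angle; fold it into the force rotation
        theta_f = spec.theta + config.sensor_camera_rotation
        theta_f = float(np.angle(np.exp(1j * theta_f)))
        force_spec = StrikeFrameSpec(theta=theta_f, origin=spec.origin)
    else:
        force_spec = spec
    force_sf = rotate_to_strike_frame(force_s, force_spec)
    kin_sf = rotate_to_strike_frame(kin_s, spec)

    # final events from the fore-aft head velocity
    hx_sf = fit_smoothing_spline(kin_sf.time, kin_sf.head_x, lam=config.lam_kin)
    v_fa = hx_sf(grid, nu=1)
    events = detect_strike_events(grid, v_fa, config)

    metrics = compute_metrics(
        force_sf,
        kin_sf,
        events,
        meta,
        theta=spec.theta,
        spline_forces=config.spline_forces,
        tare_vertical=config.tare_vertical,
        lam_force=config.lam_force,
        lam_kin=config.lam_kin,
        fv_floor_bw=config.fv_floor_bw,
    )

    budget = strategy = None
    if config.momentum_split is not None:
        head_frac, tail_frac = config.momentum_split
        tx_sf = fit_smoothing_spline(kin_sf.time, kin_sf.tail_x, lam=config.lam_kin)
        ffa_sig = fit_smoothing_spline(force_sf.time, force_sf.fx, lam=config.lam_force)
        window = delivery_window(
            lambda t: hx_sf(t, nu=1), events.t_onset, events.t_end_forward
        )
        budget = compute_budget(
            head_vel=lambda t: hx_sf(t, nu=1),
            tail_vel=lambda t: tx_sf(t, nu=1),
            f_fa=ffa_sig,
            window=window,
            mass=meta.mass,
            head_fraction=head_frac,
            tail_fraction=tail_frac,
        )
        strategy = classify_strategy(budget)

    return TrialResult(
        metrics=metrics, events=events, frame=spec, budget=budget, strategy=strategy
    )
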