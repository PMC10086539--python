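"""Strike variables computed from strike-frame signals and the event window.

Fourteen quantities are reported per trial: maximum fore-aft, lateral,
vertical, and total (vector-norm) force; maximum head velocity and
acceleration; fore-aft impulse; strike distance; maximum tail velocity,
acceleration, and signed displacement along the strike axis; maximum
fore-aft-to-vertical (FA/V) force ratio; the percentage of the strike with
FA/V above the slip threshold mu; and strike duration.

Forces are reported both in newtons and in body weights (force divided by
m*g). "Maximum" follows peak semantics: the largest interior local maximum
of the smoothed channel inside the strike window, falling back to the
window maximum (with a flag) when no interior peak exists. The fore-aft
impulse is the trapezoidal integral of fore-aft force over the window, i.e.
the horizontal momentum exchanged with the ground. Fore-aft force is
positive in the propulsive sense (ground pushing the snake along the strike
direction); the FA/V ratio uses its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import ForceTrace, KinematicTrace, TrialMeta
from .smooth import StrikeEvents, fit_smoothing_spline

__all__ = [
    "StrikeMetrics",
    "to_body_weights",
    "fore_aft_impulse",
    "trapz_between",
    "slip_fraction",
    "compute_metrics",
]

#: vertical-force floor (in BW) below which the FA/V ratio is undefined
FV_FLOOR_BW = 0.05


def to_body_weights(force_N, mass_kg: float, g: float = 9.81):
    """Normalize force to body weights: F / (m*g)."""
    if not mass_kg > 0:
        raise ValueError(f"mass must be positive, got {mass_kg}")
    return np.asarray(force_N, dtype=float) / (mass_kg * g)


def trapz_between(time: np.ndarray, values: np.ndarray, a: float, b: float) -> float:
    """Integral of the piecewise-linear interpolant of (time, values) on [a, b].

    Equivalent to the trapezoidal rule on the samples inside the window plus
    exact treatment of the fractional end intervals, which makes the result
    additive over adjacent windows.
    """
    if not a < b:
        raise ValueError(f"empty integration window [{a}, {b}]")
    if a < time[0] - 1e-12 or b > time[-1] + 1e-12:
        raise ValueError(f"window [{a}, {b}] outside trace [{time[0]}, {time[-1]}]")
    ya, yb = np.interp([a, b], time, values)
    inside = (time > a) & (time < b)
    t = np.concatenate([[a], time[inside], [b]])
    y = np.concatenate([[ya], values[inside], [yb]])
    return float(np.trapezoid(y, t))


def fore_aft_impulse(
    time: np.ndarray,
    f_fa: np.ndarray,
    events: StrikeEvents,
    mass_kg: float | None = None,
    g: float = 9.81,
) -> dict:
    """Trapezoidal fore-aft impulse over the strike window, in N*s (and BW*s)."""
    imp = trapz_between(
        np.asarray(time, dtype=float),
        np.asarray(f_fa, dtype=float),
        events.t_onset,
        events.t_end_forward,
    )
    out = {"fa_impulse": imp}
    if mass_kg is not None:
        out["fa_impulse_bw_s"] = imp / (mass_kg * g)
    return out


def slip_fraction(
    f_fa: np.ndarray,
    f_v: np.ndarray,
    mu: float,
    mass_kg: float,
    g: float = 9.81,
    fv_floor_bw: float = FV_FLOOR_BW,
) -> tuple[float, float, int]:
    """Maximum FA/V ratio and percentage of window samples above the slip
    threshold.

    Slip is predicted where the per-sample ratio |F_fa|/F_v exceeds the
    friction coefficient mu. Samples with vertical force below
    ``fv_floor_bw`` body weights are excluded from both counts (the ratio is
    unstable near zero vertical load); the number excluded is returned.
    Inputs are the window-restricted force samples in newtons.
    """
    f_fa = np.asarray(f_fa, dtype=float)
    f_v = np.asarray(f_v, dtype=float)
    floor = fv_floor_bw * mass_kg * g
    valid = f_v > floor
    n_excluded = int(np.count_nonzero(~valid))
    if not valid.any():
        raise ValueError(
            "all window samples excluded by the vertical-force floor; "
            "FA/V ratio undefined"
        )
    ratio = np.abs(f_fa[valid]) / f_v[valid]
    pct = 100.0 * float(np.count_nonzero(ratio > mu)) / int(valid.sum())
    return float(np.max(ratio)), pct, n_excluded


def _peak(values: np.ndarray) -> tuple[float, bool]:
    """Largest interior local maximum; fall back to the window max (flagged)."""
    idx, _ = find_peaks(values)
    if idx.size:
        return float(np.max(values[idx])), False
    return float(np.max(values)), True


@dataclass(frozen=True)
class StrikeMetrics:
    """The per-trial strike variables (forces in BW; N copies alongside)."""

    max_fa_force: float
    max_lateral_force: float
    max_vertical_force: float
    max_total_force: float
    max_fa_force_N: float
    max_lateral_force_N: float
    max_vertical_force_N: float
    max_total_force_N: float
    max_head_velocity: float  # m/s
    max_head_acceleration: float  # m/s^2
    fa_impulse: float  # N*s
    fa_impulse_bw_s: float
    strike_distance: float  # m
    max_tail_velocity: float  # m/s
    max_tail_acceleration: float  # m/s^2
    tail_displacement: float  # m, signed along the strike axis
    max_fa_v_ratio: float
    pct_above_slip: float  # %
    strike_duration: float  # s
    t_onset: float = 0.0
    t_end_forward: float = 0.0
    theta: float = 0.0  # strike direction, rad
    n_ratio_excluded: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not 0.0 <= self.pct_above_slip <= 100.0:
            raise ValueError("pct_above_slip must be in [0, 100]")

    def as_dict(self) -> dict:
        d = {
            f: getattr(self, f)
            for f in self.__dataclass_fields__
            if f != "flags"
        }
        d["flags"] = ";".join(self.flags)
        return d


def compute_metrics(
    force_sf: ForceTrace,
    kin_sf: KinematicTrace,
    events: StrikeEvents,
    meta: TrialMeta,
    theta: float = 0.0,
    spline_forces: bool = True,
    tare_vertical: bool = False,
    lam_force: float | None = None,
    lam_kin: float | None = None,
    fv_floor_bw: float = FV_FLOOR_BW,
) -> StrikeMetrics:
    """Compute all strike variables from strike-frame traces.

    ``force_sf`` and ``kin_sf`` must already be synchronized and rotated so
    fx is fore-aft and head_x/tail_x lie along the strike axis. Force
    channels are smoothed on their native 1 kHz grid (disable with
    ``spline_forces=False``); kinematic channels are smoothed on the video
    grid and differentiated analytically; metrics needing both are evaluated
    on the force grid restricted to the strike window. ``tare_vertical``
    subtracts the pre-strike vertical baseline (off by default: reported
    vertical maxima include resting body weight).
    """
    flags: list[str] = list(events.warnings)
    t0, t1 = events.t_onset, events.t_end_forward
    bw = meta.body_weight_N

    # window evaluation grid at the force rate
    tf = force_sf.time
    w = (tf >= t0 - 1e-12) & (tf <= t1 + 1e-12)
    if not np.count_nonzero(w) >= 2:
        raise ValueError("strike window contains fewer than 2 force samples")
    tw = tf[w]

    def force_channel(values: np.ndarray) -> np.ndarray:
        if spline_forces:
            return fit_smoothing_spline(tf, values, lam=lam_force)(tw)
        return values[w]

    f_fa = force_channel(force_sf.fx)
    f_lat = force_channel(force_sf.fy)
    f_v = force_channel(force_sf.fz)
    if tare_vertical:
        pre = force_sf.fz[tf < t0]
        if pre.size == 0:
            raise ValueError("no pre-strike samples available for taring")
        f_v = f_v - float(np.mean(pre))

    max_fa, fb1 = _peak(f_fa)
    max_lat, fb2 = _peak(np.abs(f_lat))
    max_v, fb3 = _peak(f_v)
    max_tot, fb4 = _peak(np.sqrt(f_fa**2 + f_lat**2 + f_v**2))
    if any((fb1, fb2, fb3, fb4)):
        flags.append("force-peak-fallback")

    ratio_max, pct, n_excl = slip_fraction(
        f_fa, f_v, meta.mu, meta.mass, meta.g, fv_floor_bw
    )
    if n_excl:
        flags.append(f"ratio-excluded-{n_excl}-samples")

    # impulse uses the raw (unsmoothed) fore-aft samples: trapezoidal
    # integration is itself insensitive to zero-mean noise
    imp = fore_aft_impulse(tf, force_sf.fx, events, meta.mass, meta.g)

    # kinematics: splines on the video grid, evaluated on the window grid
    hx = fit_smoothing_spline(kin_sf.time, kin_sf.head_x, lam=lam_kin)
    hy = fit_smoothing_spline(kin_sf.time, kin_sf.head_y, lam=lam_kin)
    tx = fit_smoothing_spline(kin_sf.time, kin_sf.tail_x, lam=lam_kin)

    head_v, fb5 = _peak(hx(tw, nu=1))
    head_a, fb6 = _peak(np.abs(hx(tw, nu=2)))
    if fb5 or fb6:
        flags.append("kinematic-peak-fallback")
    dx = float(hx(t1) - hx(t0))
    dy = float(hy(t1) - hy(t0))
    strike_distance = float(np.hypot(dx, dy))

    tail_disp = tx(tw) - float(tx(t0))
    i_ext = int(np.argmax(np.abs(tail_disp)))
    tail_v = float(np.max(np.abs(tx(tw, nu=1))))
    tail_a = float(np.max(np.abs(tx(tw, nu=2))))

    return StrikeMetrics(
        max_fa_force=max_fa / bw,
        max_lateral_force=max_lat / bw,
        max_vertical_force=max_v / bw,
        max_total_force=max_tot / bw,
        max_fa_force_N=max_fa,
        max_lateral_force_N=max_lat,
        max_vertical_force_N=max_v,
        max_total_force_N=max_tot,
        max_head_velocity=head_v,
        max_head_acceleration=head_a,
        fa_impulse=imp["fa_impulse"],
        fa_impulse_bw_s=imp["fa_impulse_bw_s"],
        strike_distance=strike_distance,
        max_tail_velocity=tail_v,
        max_tail_acceleration=tail_a,
        tail_displacement=float(tail_disp[i_ext]),
        max_fa_v_ratio=ratio_max,
        pct_above_slip=pct,
        strike_duration=events.duration,
        t_onset=t0,
        t_end_forward=t1,
        theta=theta,
        n_ratio_excluded=n_excl,
        flags=tuple(flags),
    )
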