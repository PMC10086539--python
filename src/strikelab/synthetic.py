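"""Synthetic strike trials: force, kinematics, metadata, and ground truth.

Real strike trials pair a 1 kHz force-plate record with 500 Hz dorsal-view
digitized head/tail coordinates. This module emulates that data with two
generators plus a cohort-level metric simulator:

* ``generate_two_mass_trial`` — a mechanistic model. The head (a point mass
  ``head_mass_fraction * m``) follows a minimum-jerk trajectory along the
  strike azimuth; the rest of the body is a second point mass. The
  horizontal ground-reaction force is the total horizontal momentum rate,
  ``F_fa = m_h a_h + m_t a_t``. In the walled setup the tail is stationary
  and the plate sees the full head force; in the open setup the tail recoils
  rearward just enough to keep the Coulomb slip ratio |F_fa|/F_v at or below
  the friction coefficient at every sample, mimicking the use of the
  posterior body as an inertial appendage.

* ``generate_direct_profile_trial`` — a calibration mode where per-axis
  force profiles are named closed forms (half-sine, trapezoid, piecewise
  constant), so peak forces, impulses, and slip fractions are specified
  exactly rather than emerging from dynamics.

* ``generate_cohort`` — per-trial metric values drawn from a two-factor
  mixed model (setup effect, individual random effect, interaction,
  residual) for calibrating the statistics layer.

Every generator is deterministic for a given seed and records the noiseless
ground truth alongside the noisy traces.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ForceTrace, KinematicTrace, TrialMeta

__all__ = [
    "StrikeScenario",
    "SyntheticTruth",
    "InfeasibleScenarioError",
    "generate_min_jerk_strike",
    "generate_two_mass_trial",
    "generate_direct_profile_trial",
    "generate_cohort",
    "load_scenario",
    "HalfSine",
    "Trapezoid",
    "Constant",
    "PiecewiseConstant",
]


class InfeasibleScenarioError(ValueError):
    """Open-setup slip cap cannot be met within the tail-acceleration bound."""


# ---------------------------------------------------------------------------
# minimum-jerk primitives
#
# x(tau) = D (10 tau^3 - 15 tau^4 + 6 tau^5) on tau = t/T in [0, 1], clamped
# outside. Peak speed 1.875 D/T at tau=1/2; peak |acceleration|
# (10/sqrt(3)) D/T^2 ~= 5.7735 D/T^2 at tau = 1/2 -+ 1/(2 sqrt(5)).

MINJERK_PEAK_SPEED = 1.875
MINJERK_PEAK_ACCEL = 10.0 / math.sqrt(3.0)


def minjerk_position(tau):
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def minjerk_velocity(tau):
    t = np.asarray(tau, dtype=float)
    inside = (t >= 0.0) & (t <= 1.0)
    tc = np.clip(t, 0.0, 1.0)
    return np.where(inside, 30.0 * tc**2 * (1.0 - tc) ** 2, 0.0)


def minjerk_acceleration(tau):
    t = np.asarray(tau, dtype=float)
    inside = (t >= 0.0) & (t <= 1.0)
    tc = np.clip(t, 0.0, 1.0)
    return np.where(inside, 60.0 * tc - 180.0 * tc**2 + 120.0 * tc**3, 0.0)


@dataclass(frozen=True)
class StrikeScenario:
    """Parameters of one simulated strike trial.

    Defaults describe a juvenile blood-python-sized subject: strike distance
    0.21 m and duration 0.118 s give a min-jerk peak head speed of
    3.34 m/s and peak acceleration of 87 m/s^2, in the measured range for
    striking snakes. ``setup`` selects the mechanistic mode: "open" caps the
    slip ratio via tail recoil, "walled" pins the tail.
    """

    strike_distance: float = 0.21  # D, m
    strike_duration: float = 0.118  # T, s
    strike_azimuth: float = 0.0  # rad, head travel direction in lab frame
    head_mass_fraction: float = 0.3
    mass: float = 0.586  # kg
    mu: float = 0.30
    setup: str = "open"
    noise_sd_force: float = 0.01  # N, per force channel
    noise_sd_position: float = 0.0005  # m, per digitized coordinate
    seed: int = 0
    g: float = 9.81
    # timing / bookkeeping
    lead_in: float = 0.2  # s of quiet record before the strike
    follow: float = 0.2  # s of record after the strike
    force_rate: float = 1000.0
    video_rate: float = 500.0
    trigger_force_sample: int = 100  # force samples recorded before frame 0
    vertical_bump_bw: float = 0.5  # peak of the smooth vertical overshoot, BW
    slip_margin: float = 0.02  # open setup: cap the FA/V ratio at (1-margin)*mu
    tail_offset: float = 0.6  # m, initial head-to-tail distance
    max_tail_accel: float = 500.0  # m/s^2 plausibility bound for the recoil
    head_start: tuple[float, float] = (0.05, 0.05)  # m, lab frame
    individual_id: str = "sim1"
    trial_id: str = "trial1"
    svl: float = 76.1  # cm

    def __post_init__(self):
        if self.strike_distance < 0:
            raise ValueError("strike_distance must be non-negative")
        if not self.strike_duration > 0:
            raise ValueError("strike_duration must be positive")
        if not 0 < self.head_mass_fraction <= 1:
            raise ValueError("head_mass_fraction must be in (0, 1]")
        if not self.mass > 0:
            raise ValueError("mass must be positive")
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if self.setup not in ("open", "walled"):
            raise ValueError(f"setup must be 'open' or 'walled', got {self.setup!r}")
        if self.noise_sd_force < 0 or self.noise_sd_position < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.slip_margin < 1:
            raise ValueError("slip_margin must be in [0, 1)")
        if self.strike_duration < 4.0 / self.video_rate:
            raise ValueError(
                f"strike_duration {self.strike_duration} s is shorter than 4 "
                f"video frames ({4.0 / self.video_rate} s); window too short"
            )

    def meta(self) -> TrialMeta:
        return TrialMeta(
            individual_id=self.individual_id,
            setup=self.setup,
            trial_id=self.trial_id,
            mass=self.mass,
            svl=self.svl,
            mu=self.mu,
            force_rate=self.force_rate,
            video_rate=self.video_rate,
            trigger_force_sample=self.trigger_force_sample,
            g=self.g,
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Noiseless ground truth of a generated trial (recovery-test oracle).

    Scalar fields mirror the measured strike variables; ``debug`` carries the
    noiseless internal arrays for invariant checks and is never serialized.
    """

    max_head_velocity: float  # m/s
    max_head_acceleration: float  # m/s^2
    strike_distance: float  # m
    strike_duration: float  # s
    max_fa_force_bw: float
    max_lateral_force_bw: float
    max_vertical_force_bw: float
    max_total_force_bw: float
    fa_impulse: float  # N*s over the strike window
    max_fa_v_ratio: float
    pct_above_slip: float  # %
    tail_displacement: float  # m, signed extremum along the strike axis
    max_tail_velocity: float  # m/s
    max_tail_acceleration: float  # m/s^2
    t_onset: float = 0.0  # s, trigger-based time axis
    debug: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name == "debug":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite truth field {f.name}")
        if not 0.0 <= self.pct_above_slip <= 100.0:
            raise ValueError("pct_above_slip must be in [0, 100]")


# ---------------------------------------------------------------------------
# mechanistic generator


def _mechanics(sc: StrikeScenario):
    """Noiseless two-mass dynamics on the force grid (trigger-based time)."""
    record = sc.lead_in + sc.strike_duration + sc.follow
    n_kin = int(round(record * sc.video_rate)) + 1
    n_pre = sc.trigger_force_sample
    step = int(round(sc.force_rate / sc.video_rate))  # force samples per frame
    n_force = n_pre + step * (n_kin - 1) + 1
    tf = (np.arange(n_force) - n_pre) / sc.force_rate  # sync time, t=0 at trigger
    tk = np.arange(n_kin) / sc.video_rate

    D, T, t0 = sc.strike_distance, sc.strike_duration, sc.lead_in
    m_h = sc.head_mass_fraction * sc.mass
    m_t = sc.mass - m_h
    tau_f = (tf - t0) / T

    a_h = D / T**2 * minjerk_acceleration(tau_f)
    v_h = D / T * minjerk_velocity(tau_f)
    s_h = D * minjerk_position(tau_f)

    # vertical: body weight plus a smooth overshoot during the strike
    in_strike = (tau_f >= 0.0) & (tau_f <= 1.0)
    bump = np.where(in_strike, np.sin(np.pi * np.clip(tau_f, 0.0, 1.0)), 0.0)
    f_v = sc.mass * sc.g * (1.0 + sc.vertical_bump_bw * bump)

    f_head = m_h * a_h
    if sc.setup == "walled" or m_t == 0.0:
        a_t = np.zeros_like(a_h)
    else:
        # cap slightly below mu: the ratio hugs, but does not touch, the
        # slip threshold, so noise only rarely carries samples across it
        cap = sc.mu * f_v * (1.0 - max(sc.slip_margin, 1e-9))
        target = np.clip(f_head, -cap, cap)
        a_t = (target - f_head) / m_t
        over = np.abs(a_t) > sc.max_tail_accel
        if over.any():
            i = int(np.flatnonzero(over)[0])
            raise InfeasibleScenarioError(
                f"open-setup slip cap requires tail acceleration "
                f"{a_t[i]:.1f} m/s^2 (> bound {sc.max_tail_accel}) at sample "
                f"{i} (t={tf[i]:.4f} s)"
            )
    f_fa = f_head + m_t * a_t

    dt = 1.0 / sc.force_rate
    v_t = np.concatenate([[0.0], np.cumsum(0.5 * (a_t[1:] + a_t[:-1]) * dt)])
    s_t = np.concatenate([[0.0], np.cumsum(0.5 * (v_t[1:] + v_t[:-1]) * dt)])

    return {
        "tf": tf,
        "tk": tk,
        "n_pre": n_pre,
        "step": step,
        "m_h": m_h,
        "m_t": m_t,
        "a_h": a_h,
        "v_h": v_h,
        "s_h": s_h,
        "a_t": a_t,
        "v_t": v_t,
        "s_t": s_t,
        "f_fa": f_fa,
        "f_v": f_v,
        "window": (t0, t0 + T),
    }


def _truth_from_mechanics(sc: StrikeScenario, mech: dict) -> SyntheticTruth:
    tf = mech["tf"]
    t0, t1 = mech["window"]
    w = (tf >= t0 - 1e-12) & (tf <= t1 + 1e-12)
    bw = sc.mass * sc.g
    f_fa, f_v = mech["f_fa"], mech["f_v"]
    ratio = np.abs(f_fa[w]) / f_v[w]
    n_valid = int(w.sum())
    pct = 100.0 * float(np.count_nonzero(ratio > sc.mu)) / n_valid
    total = np.sqrt(f_fa**2 + f_v**2)  # lateral is identically zero
    impulse = float(np.trapezoid(f_fa[w], tf[w]))
    s_t = mech["s_t"]
    disp = s_t[w] - s_t[np.flatnonzero(w)[0]]
    i_ext = int(np.argmax(np.abs(disp)))
    D, T = sc.strike_distance, sc.strike_duration
    return SyntheticTruth(
        max_head_velocity=MINJERK_PEAK_SPEED * D / T,
        max_head_acceleration=MINJERK_PEAK_ACCEL * D / T**2,
        strike_distance=D,
        strike_duration=T,
        max_fa_force_bw=float(np.max(f_fa[w])) / bw,
        max_lateral_force_bw=0.0,
        max_vertical_force_bw=float(np.max(f_v[w])) / bw,
        max_total_force_bw=float(np.max(total[w])) / bw,
        fa_impulse=impulse,
        max_fa_v_ratio=float(np.max(ratio)),
        pct_above_slip=pct,
        tail_displacement=float(disp[i_ext]),
        max_tail_velocity=float(np.max(np.abs(mech["v_t"][w]))),
        max_tail_acceleration=float(np.max(np.abs(mech["a_t"][w]))),
        t_onset=t0,
        debug={
            "time": tf,
            "f_fa": f_fa,
            "f_v": f_v,
            "a_h": mech["a_h"],
            "v_h": mech["v_h"],
            "v_t": mech["v_t"],
            "a_t": mech["a_t"],
            "s_t": s_t,
            "m_h": mech["m_h"],
            "m_t": mech["m_t"],
            "window": mech["window"],
        },
    )


def _kinematics_from_mechanics(sc: StrikeScenario, mech: dict, rng) -> KinematicTrace:
    tk, n_pre, step = mech["tk"], mech["n_pre"], mech["step"]
    # kinematic frames land on force samples n_pre + step*j
    j = n_pre + step * np.arange(tk.size)
    ux, uy = math.cos(sc.strike_azimuth), math.sin(sc.strike_azimuth)
    tau_k = (tk - sc.lead_in) / sc.strike_duration
    s_h_k = sc.strike_distance * minjerk_position(tau_k)
    s_t_k = mech["s_t"][j]
    hx = sc.head_start[0] + ux * s_h_k
    hy = sc.head_start[1] + uy * s_h_k
    tx = sc.head_start[0] - ux * sc.tail_offset + ux * s_t_k
    ty = sc.head_start[1] - uy * sc.tail_offset + uy * s_t_k
    if sc.noise_sd_position > 0:
        hx = hx + rng.normal(0.0, sc.noise_sd_position, hx.shape)
        hy = hy + rng.normal(0.0, sc.noise_sd_position, hy.shape)
        tx = tx + rng.normal(0.0, sc.noise_sd_position, tx.shape)
        ty = ty + rng.normal(0.0, sc.noise_sd_position, ty.shape)
    return KinematicTrace(
        time=tk, head_x=hx, head_y=hy, tail_x=tx, tail_y=ty, rate=sc.video_rate
    )


def generate_min_jerk_strike(
    scenario: StrikeScenario,
) -> tuple[KinematicTrace, SyntheticTruth]:
    """Kinematics-only trial: min-jerk head path plus the derived tail path.

    The tail follows the momentum-constraint recoil in the open setup and is
    stationary in the walled setup (or when ``head_mass_fraction`` is 1).
    Ground truth carries the analytic min-jerk extrema.
    """
    rng = np.random.default_rng(scenario.seed)
    mech = _mechanics(scenario)
    truth = _truth_from_mechanics(scenario, mech)
    kin = _kinematics_from_mechanics(scenario, mech, rng)
    return kin, truth


def generate_two_mass_trial(
    scenario: StrikeScenario,
) -> tuple[ForceTrace, KinematicTrace, TrialMeta, SyntheticTruth]:
    """Full mechanistic trial: force plate + digitized kinematics + truth.

    Forces are expressed in the sensor frame (the strike azimuth rotates the
    horizontal ground force into Fx/Fy); the force record clock starts at its
    first sample, with the camera trigger at ``trigger_force_sample``.
    Gaussian sensor/digitization noise is added after the noiseless truth is
    recorded.
    """
    rng = np.random.default_rng(scenario.seed)
    mech = _mechanics(scenario)
    truth = _truth_from_mechanics(scenario, mech)

    ux, uy = math.cos(scenario.strike_azimuth), math.sin(scenario.strike_azimuth)
    fx = mech["f_fa"] * ux
    fy = mech["f_fa"] * uy
    fz = mech["f_v"].copy()
    if scenario.noise_sd_force > 0:
        fx = fx + rng.normal(0.0, scenario.noise_sd_force, fx.shape)
        fy = fy + rng.normal(0.0, scenario.noise_sd_force, fy.shape)
        fz = fz + rng.normal(0.0, scenario.noise_sd_force, fz.shape)
    # record clock: first force sample at t=0
    t_record = np.arange(fx.size) / scenario.force_rate
    force = ForceTrace(time=t_record, fx=fx, fy=fy, fz=fz, rate=scenario.force_rate)
    kin = _kinematics_from_mechanics(scenario, mech, rng)
    return force, kin, scenario.meta(), truth


# ---------------------------------------------------------------------------
# direct-profile generator (calibration mode)


@dataclass(frozen=True)
class HalfSine:
    """Half-sine pulse: amplitude * sin(pi (t-start)/duration) on its support."""

    amplitude: float
    start: float
    duration: float

    @property
    def support(self):
        return (self.start, self.start + self.duration)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        inside = (t >= self.start) & (t <= self.start + self.duration)
        phase = np.pi * (t - self.start) / self.duration
        return np.where(inside, self.amplitude * np.sin(phase), 0.0)

    def peak(self):
        return abs(self.amplitude)

    def integral(self):
        return 2.0 * self.amplitude * self.duration / np.pi


@dataclass(frozen=True)
class Trapezoid:
    """Linear rise, flat plateau, linear fall."""

    amplitude: float
    start: float
    rise: float
    plateau: float
    fall: float

    @property
    def support(self):
        return (self.start, self.start + self.rise + self.plateau + self.fall)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        t1 = self.start + self.rise
        t2 = t1 + self.plateau
        t3 = t2 + self.fall
        out = np.zeros_like(t)
        r = (t >= self.start) & (t < t1)
        out[r] = self.amplitude * (t[r] - self.start) / self.rise
        out[(t >= t1) & (t <= t2)] = self.amplitude
        f = (t > t2) & (t <= t3)
        out[f] = self.amplitude * (t3 - t[f]) / self.fall
        return out

    def peak(self):
        return abs(self.amplitude)

    def integral(self):
        return self.amplitude * (0.5 * self.rise + self.plateau + 0.5 * self.fall)


@dataclass(frozen=True)
class Constant:
    """Constant level over the whole record (e.g. a body-weight baseline)."""

    value: float

    support = None

    def __call__(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.value)

    def peak(self):
        return abs(self.value)


@dataclass(frozen=True)
class PiecewiseConstant:
    """Piecewise-constant profile: values[i] on [edges[i], edges[i+1]); 0 outside."""

    edges: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.edges) != len(self.values) + 1:
            raise ValueError("need len(edges) == len(values) + 1")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    @property
    def support(self):
        return (self.edges[0], self.edges[-1])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.edges, t, side="right") - 1
        inside = (idx >= 0) & (idx < len(self.values))
        out = np.zeros_like(t)
        out[inside] = np.asarray(self.values)[idx[inside]]
        return out

    def peak(self):
        return float(np.max(np.abs(self.values)))


def generate_direct_profile_trial(
    profiles: dict,
    window: tuple[float, float],
    meta: TrialMeta,
    head_distance: float = 0.21,
    pad: float = 0.2,
) -> tuple[ForceTrace, KinematicTrace, SyntheticTruth]:
    """Noiseless trial whose force channels are named closed-form profiles.

    ``profiles`` maps "fa"/"lateral"/"vertical" to profile objects; omitted
    horizontal channels default to zero and the vertical channel to a
    constant 1 BW baseline. The strike ``window`` (t0, t1) on the trigger
    time axis must contain the support of every windowed profile; the head
    travels ``head_distance`` along +x as a min-jerk so event detection
    finds the window. Truth equals the specified amplitudes/integrals
    exactly.
    """
    t0, t1 = window
    if not 0.0 <= t0 < t1:
        raise ValueError("window must satisfy 0 <= t0 < t1")
    fa = profiles.get("fa", Constant(0.0))
    lat = profiles.get("lateral", Constant(0.0))
    vert = profiles.get("vertical", Constant(meta.body_weight_N))
    unknown = set(profiles) - {"fa", "lateral", "vertical"}
    if unknown:
        raise ValueError(f"unknown profile axis {sorted(unknown)}")
    for name, prof in (("fa", fa), ("lateral", lat)):
        sup = getattr(prof, "support", None)
        if sup is not None and (sup[0] < t0 - 1e-12 or sup[1] > t1 + 1e-12):
            raise ValueError(
                f"{name} profile support {sup} lies outside the window {window}"
            )

    record_end = t1 + pad
    n_force = int(round(record_end * meta.force_rate)) + 1
    tf = np.arange(n_force) / meta.force_rate
    f_fa, f_lat, f_v = fa(tf), lat(tf), vert(tf)
    force = ForceTrace(time=tf, fx=f_fa, fy=f_lat, fz=f_v, rate=meta.force_rate)

    n_kin = int(round(record_end * meta.video_rate)) + 1
    tk = np.arange(n_kin) / meta.video_rate
    tau = (tk - t0) / (t1 - t0)
    hx = 0.0 + head_distance * minjerk_position(tau)
    zeros = np.zeros_like(tk)
    kin = KinematicTrace(
        time=tk,
        head_x=hx,
        head_y=zeros,
        tail_x=zeros - 0.3,
        tail_y=zeros,
        rate=meta.video_rate,
    )

    bw = meta.body_weight_N
    w = (tf >= t0 - 1e-12) & (tf <= t1 + 1e-12)
    floor = 0.05 * bw
    valid = f_v[w] > floor
    if not valid.any():
        raise ValueError("no valid vertical-force samples inside the window")
    ratio = np.abs(f_fa[w][valid]) / f_v[w][valid]
    pct = 100.0 * float(np.count_nonzero(ratio > meta.mu)) / int(valid.sum())
    total_peak = float(np.max(np.sqrt(f_fa**2 + f_lat**2 + f_v**2)[w]))
    impulse = (
        fa.integral()
        if hasattr(fa, "integral")
        else float(np.trapezoid(f_fa[w], tf[w]))
    )
    T = t1 - t0
    truth = SyntheticTruth(
        max_head_velocity=MINJERK_PEAK_SPEED * head_distance / T,
        max_head_acceleration=MINJERK_PEAK_ACCEL * head_distance / T**2,
        strike_distance=head_distance,
        strike_duration=T,
        max_fa_force_bw=fa.peak() / bw,
        max_lateral_force_bw=lat.peak() / bw,
        max_vertical_force_bw=vert.peak() / bw,
        max_total_force_bw=total_peak / bw,
        fa_impulse=float(impulse),
        max_fa_v_ratio=float(np.max(ratio)),
        pct_above_slip=pct,
        tail_displacement=0.0,
        max_tail_velocity=0.0,
        max_tail_acceleration=0.0,
        t_onset=t0,
        debug={"time": tf, "f_fa": f_fa, "f_v": f_v, "window": (t0, t1)},
    )
    return force, kin, truth


# ---------------------------------------------------------------------------
# cohort-level metric simulator


def generate_cohort(
    n_individuals: int = 4,
    trials_per_setup: int = 6,
    grand_mean: float = 0.0,
    setup_effect: float = 0.0,
    between_individual_sd: float = 1.0,
    interaction_sd: float = 0.5,
    residual_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-trial values of one metric under a two-factor mixed model.

    value = grand mean -+ setup_effect/2 (open/walled) + individual random
    effect + setup x individual interaction + residual, all Gaussian.
    Mirrors the study design of a handful of individuals tested repeatedly
    in both setups. Returns a long-format table (individual, setup, trial,
    value) and the drawn effects.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if trials_per_setup < 2:
        raise ValueError("need at least 2 trials per setup")
    for name, sd in (
        ("between_individual_sd", between_individual_sd),
        ("interaction_sd", interaction_sd),
        ("residual_sd", residual_sd),
    ):
        if sd < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    indiv_eff = rng.normal(0.0, between_individual_sd, n_individuals)
    inter_eff = rng.normal(0.0, interaction_sd, (n_individuals, 2))
    rows = []
    for i in range(n_individuals):
        for s, setup in enumerate(("open", "walled")):
            half = -0.5 if setup == "open" else 0.5
            eps = rng.normal(0.0, residual_sd, trials_per_setup)
            for k in range(trials_per_setup):
                rows.append(
                    {
                        "individual": f"snake{i + 1}",
                        "setup": setup,
                        "trial": f"snake{i + 1}_{setup}_{k + 1}",
                        "value": grand_mean
                        + half * setup_effect
                        + indiv_eff[i]
                        + inter_eff[i, s]
                        + eps[k],
                    }
                )
    truth = {
        "grand_mean": grand_mean,
        "setup_effect": setup_effect,
        "individual_effects": indiv_eff,
        "interaction_effects": inter_eff,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# scenario config

_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(StrikeScenario)}


def load_scenario(path: str | Path) -> StrikeScenario:
    """Load a StrikeScenario from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario file must be a mapping")
    unknown = set(raw) - _SCENARIO_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown scenario key(s) {sorted(unknown)}")
    if "head_start" in raw:
        raw["head_start"] = tuple(raw["head_start"])
    return StrikeScenario(**raw)
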