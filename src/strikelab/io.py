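"""Trial input/output: force and kinematics CSV files, metadata, synchronization.

A trial consists of three files: a force CSV sampled at the force-plate rate
(default 1 kHz), a DLTdv-style kinematics CSV of digitized head and tail
pixel coordinates at the video rate (default 500 Hz), and a metadata YAML.
The two clocks are joined through the camera trigger, whose sample index in
the force record is part of the metadata: video frame 0 coincides with that
force sample, and all times are reported in seconds with t=0 at the trigger.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrialMeta",
    "ForceTrace",
    "KinematicTrace",
    "TrialIOError",
    "read_force_csv",
    "write_force_csv",
    "read_kinematics_csv",
    "write_kinematics_csv",
    "read_meta_yaml",
    "write_meta_yaml",
    "synchronize",
    "write_metrics_csv",
]

SETUPS = ("open", "walled")

#: maximum run of missing frames that may be filled by linear interpolation
MAX_GAP_FRAMES = 3


class TrialIOError(ValueError):
    """Raised for malformed or inconsistent trial files."""


@dataclass(frozen=True)
class TrialMeta:
    """Per-trial metadata.

    Parameters
    ----------
    individual_id : str
        Subject identifier.
    setup : {"open", "walled"}
        Platform configuration: featureless plane or two adjacent walls.
    trial_id : str
        Unique trial label.
    mass : float
        Snake mass in kg; used for body-weight normalization.
    svl : float or None
        Snout–vent length in cm (bookkeeping only).
    mu : float
        Coefficient of static friction of the platform surface.
    force_rate, video_rate : float
        Sampling rates in Hz (defaults 1000 and 500).
    trigger_force_sample : int
        Index of the camera-trigger sample in the force record; video frame 0
        aligns with this sample and defines t=0.
    scale_m_per_px : float
        Conversion from digitized pixel coordinates to meters.
    g : float
        Gravitational acceleration in m s**-2.
    """

    individual_id: str
    setup: str
    trial_id: str
    mass: float
    svl: float | None = None
    mu: float = 0.30
    force_rate: float = 1000.0
    video_rate: float = 500.0
    trigger_force_sample: int = 0
    scale_m_per_px: float = 0.001
    g: float = 9.81

    def __post_init__(self):
        if self.setup not in SETUPS:
            raise TrialIOError(f"setup must be one of {SETUPS}, got {self.setup!r}")
        if not self.mass > 0:
            raise TrialIOError(f"mass must be positive, got {self.mass}")
        if not self.mu > 0:
            raise TrialIOError(f"mu must be positive, got {self.mu}")
        if not (self.force_rate > 0 and self.video_rate > 0):
            raise TrialIOError("sampling rates must be positive")
        if self.trigger_force_sample < 0:
            raise TrialIOError("trigger_force_sample must be non-negative")

    @property
    def body_weight_N(self) -> float:
        """Snake weight m*g in newtons (1 BW)."""
        return self.mass * self.g


def _check_uniform(time: np.ndarray, rate: float, what: str) -> None:
    if time.ndim != 1 or time.size < 2:
        raise TrialIOError(f"{what}: need at least 2 samples")
    dt = np.diff(time)
    expected = 1.0 / rate
    bad = np.flatnonzero(np.abs(dt - expected) > 1e-9)
    if bad.size:
        i = int(bad[0])
        raise TrialIOError(
            f"{what}: non-uniform time grid at rows {i}-{i + 1} "
            f"(interval {dt[i]:.9g} s, expected {expected:.9g} s)"
        )


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled force record in the sensor frame.

    ``fx``/``fy`` are the horizontal channels and ``fz`` the vertical, all in
    newtons. Torques, if present in the file, are carried along unused.
    """

    time: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    rate: float = 1000.0
    torques: np.ndarray | None = None  # (n, 3) N*m, parsed but unused

    def __post_init__(self):
        _check_uniform(self.time, self.rate, "force trace")
        for name in ("fx", "fy", "fz"):
            arr = getattr(self, name)
            if arr.shape != self.time.shape:
                raise TrialIOError(f"force trace: {name} length mismatch")
            if not np.all(np.isfinite(arr)):
                i = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise TrialIOError(f"force trace: non-finite {name} at row {i}")

    def __len__(self) -> int:
        return self.time.size

    def shifted(self, dt: float) -> "ForceTrace":
        """Return a copy with ``dt`` added to the time axis (values untouched)."""
        return dataclasses.replace(self, time=self.time + dt)


@dataclass(frozen=True)
class KinematicTrace:
    """Digitized head and tail planar positions in meters, camera frame."""

    time: np.ndarray
    head_x: np.ndarray
    head_y: np.ndarray
    tail_x: np.ndarray
    tail_y: np.ndarray
    rate: float = 500.0
    interpolated_frames: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        _check_uniform(self.time, self.rate, "kinematic trace")
        for name in ("head_x", "head_y", "tail_x", "tail_y"):
            arr = getattr(self, name)
            if arr.shape != self.time.shape:
                raise TrialIOError(f"kinematic trace: {name} length mismatch")
            if not np.all(np.isfinite(arr)):
                i = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise TrialIOError(f"kinematic trace: non-finite {name} at frame {i}")

    def __len__(self) -> int:
        return self.time.size

    def shifted(self, dt: float) -> "KinematicTrace":
        return dataclasses.replace(self, time=self.time + dt)


# ---------------------------------------------------------------------------
# force CSV

_FORCE_COLUMNS = {"time": "time", "fx": "Fx", "fy": "Fy", "fz": "Fz"}
_TORQUE_COLUMNS = ("Tx", "Ty", "Tz")


def read_force_csv(
    path: str | Path,
    meta: TrialMeta,
    column_map: dict[str, str] | None = None,
    force_scale: float = 1.0,
) -> ForceTrace:
    """Read a force CSV into a validated :class:`ForceTrace`.

    ``column_map`` maps the canonical names {"time","fx","fy","fz"} to the
    header names actually used in the file; ``force_scale`` multiplies the
    force channels (e.g. 0.001 for a file in millinewtons).
    """
    cols = dict(_FORCE_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise TrialIOError(f"{path}: missing force column(s) {missing}")
    time = df[cols["time"]].to_numpy(dtype=float)
    forces = {k: df[cols[k]].to_numpy(dtype=float) * force_scale for k in ("fx", "fy", "fz")}
    torques = None
    if all(c in df.columns for c in _TORQUE_COLUMNS):
        torques = df[list(_TORQUE_COLUMNS)].to_numpy(dtype=float)
    return ForceTrace(time=time, rate=meta.force_rate, torques=torques, **forces)


def write_force_csv(path: str | Path, trace: ForceTrace) -> None:
    df = pd.DataFrame(
        {"time": trace.time, "Fx": trace.fx, "Fy": trace.fy, "Fz": trace.fz}
    )
    if trace.torques is not None:
        for i, c in enumerate(_TORQUE_COLUMNS):
            df[c] = trace.torques[:, i]
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# kinematics CSV (DLTdv-style: pt1 = head, pt2 = tail, pixel units)


def _interp_gaps(values: np.ndarray, what: str) -> tuple[np.ndarray, list[int]]:
    """Linearly fill NaN runs of <= MAX_GAP_FRAMES frames; longer runs error."""
    isnan = ~np.isfinite(values)
    if not isnan.any():
        return values, []
    if isnan[0] or isnan[-1]:
        i = 0 if isnan[0] else int(values.size - 1)
        raise TrialIOError(f"{what}: missing value at trace boundary (frame {i})")
    idx = np.flatnonzero(isnan)
    # split into consecutive runs
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        if run.size > MAX_GAP_FRAMES:
            raise TrialIOError(
                f"{what}: gap of {run.size} frames starting at frame {run[0]} "
                f"exceeds the {MAX_GAP_FRAMES}-frame interpolation limit"
            )
    out = values.copy()
    good = np.flatnonzero(~isnan)
    out[idx] = np.interp(idx, good, values[good])
    return out, [int(i) for i in idx]


def read_kinematics_csv(
    path: str | Path,
    meta: TrialMeta,
    scale_m_per_px: float | None = None,
) -> KinematicTrace:
    """Read a DLTdv-style digitization CSV (pt1_X.. columns, pixels).

    Point 1 is the head, point 2 the tail. Short digitization dropouts
    (<= 3 frames) are linearly interpolated and flagged; longer gaps are an
    error. Positions are converted to meters via ``scale_m_per_px``
    (default: taken from the metadata).
    """
    scale = meta.scale_m_per_px if scale_m_per_px is None else scale_m_per_px
    if not scale > 0:
        raise TrialIOError(f"scale_m_per_px must be positive, got {scale}")
    df = pd.read_csv(path)

    def find(names: Sequence[str]) -> np.ndarray:
        for n in names:
            if n in df.columns:
                return df[n].to_numpy(dtype=float)
        raise TrialIOError(f"{path}: missing kinematics column (tried {list(names)})")

    channels = {
        "head_x": ("pt1_X", "pt1_cam1_X"),
        "head_y": ("pt1_Y", "pt1_cam1_Y"),
        "tail_x": ("pt2_X", "pt2_cam1_X"),
        "tail_y": ("pt2_Y", "pt2_cam1_Y"),
    }
    data = {}
    flagged: set[int] = set()
    for key, names in channels.items():
        filled, idx = _interp_gaps(find(names), f"{path}:{key}")
        data[key] = filled * scale
        flagged.update(idx)
    n = len(df)
    time = np.arange(n) / meta.video_rate
    return KinematicTrace(
        time=time,
        rate=meta.video_rate,
        interpolated_frames=tuple(sorted(flagged)),
        **data,
    )


def write_kinematics_csv(
    path: str | Path, trace: KinematicTrace, scale_m_per_px: float
) -> None:
    """Write positions back to DLTdv-style pixel columns."""
    if not scale_m_per_px > 0:
        raise TrialIOError("scale_m_per_px must be positive")
    df = pd.DataFrame(
        {
            "pt1_X": trace.head_x / scale_m_per_px,
            "pt1_Y": trace.head_y / scale_m_per_px,
            "pt2_X": trace.tail_x / scale_m_per_px,
            "pt2_Y": trace.tail_y / scale_m_per_px,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# metadata YAML

_META_FIELDS = {f.name for f in dataclasses.fields(TrialMeta)}


def read_meta_yaml(path: str | Path) -> TrialMeta:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise TrialIOError(f"{path}: metadata must be a mapping")
    unknown = set(raw) - _META_FIELDS
    if unknown:
        raise TrialIOError(f"{path}: unknown metadata key(s) {sorted(unknown)}")
    return TrialMeta(**raw)


def write_meta_yaml(path: str | Path, meta: TrialMeta) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(meta), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# synchronization


def synchronize(
    force: ForceTrace, kin: KinematicTrace, meta: TrialMeta
) -> tuple[ForceTrace, KinematicTrace, tuple[float, float]]:
    """Place both traces on a common time axis with t=0 at the camera trigger.

    The force record is shifted so that sample ``trigger_force_sample`` sits
    at t=0; video frame 0 is at t=0 by definition. Only timestamps change:
    signal values are never resampled or altered. Returns the shifted traces
    and the (start, end) of their overlap window.
    """
    if meta.trigger_force_sample >= len(force):
        raise TrialIOError(
            f"trigger_force_sample {meta.trigger_force_sample} outside force "
            f"record of length {len(force)}"
        )
    t_trigger = force.time[meta.trigger_force_sample]
    force_sync = force.shifted(-t_trigger)
    kin_sync = kin.shifted(-kin.time[0])
    lo = max(force_sync.time[0], kin_sync.time[0])
    hi = min(force_sync.time[-1], kin_sync.time[-1])
    if hi <= lo:
        raise TrialIOError(
            f"no overlap between force ({force_sync.time[0]:.3f}"
            f"..{force_sync.time[-1]:.3f} s) and kinematics "
            f"({kin_sync.time[0]:.3f}..{kin_sync.time[-1]:.3f} s)"
        )
    return force_sync, kin_sync, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# tidy outputs


def write_metrics_csv(path: str | Path, rows: Sequence[dict]) -> pd.DataFrame:
    """Write one row per trial (all metric columns) and return the frame."""
    df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format="%.12g")
    return df


def write_truth_json(path: str | Path, truth) -> None:
    """Serialize a SyntheticTruth (scalars only; debug arrays dropped)."""
    d = {
        k: v
        for k, v in dataclasses.asdict(truth).items()
        if np.isscalar(v) or v is None
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
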