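"""Domain types, session I/O, arena geometry and quality-control filters.

A *session* is one 30-minute recording of a rat shuttling between a nest
(N) zone and a foraging (F) zone to reach a reward/threat encounter (E)
zone, with simultaneously recorded prefrontal units (PL/IL).  Everything
downstream (decoding, population geometry, event analyses) consumes the
``Session`` container defined here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "Zone",
    "WithdrawalType",
    "UnitSpikeTrain",
    "TrackingTrace",
    "Trial",
    "EventLog",
    "ArenaGeometry",
    "Session",
    "SessionValidationError",
    "OutOfBoundsError",
    "load_session",
    "save_session",
    "apply_unit_qc",
    "unit_mean_rate",
    "session_passes_qc",
    "interpolate_tracking",
]


class SessionValidationError(ValueError):
    """A session component violates one of its invariants; the message names the field."""


class OutOfBoundsError(ValueError):
    """A point lies outside the arena."""


class Region(str, Enum):
    PL = "PL"
    IL = "IL"


class Zone(str, Enum):
    N = "N"  # nest
    F = "F"  # foraging
    E = "E"  # encounter


class WithdrawalType(str, Enum):
    AW = "AW"  # avoidance: head retraction before the attack
    EW = "EW"  # escape: head retraction after the attack


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class UnitSpikeTrain:
    """Spike timestamps (s from session start) of one sorted unit."""

    unit_id: str
    region: Region
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.region = Region(self.region)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise SessionValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise SessionValidationError(
                f"unit {self.unit_id}: spike_times must be nondecreasing"
            )

    def validate_range(self, duration: float) -> None:
        if self.spike_times.size and (
            self.spike_times[0] < 0 or self.spike_times[-1] > duration
        ):
            raise SessionValidationError(
                f"unit {self.unit_id}: spike_times outside [0, {duration}]"
            )


@dataclass
class TrackingTrace:
    """Head position over time; missing frames are NaN coordinates."""

    timestamps: np.ndarray
    head_xy: np.ndarray  # (n, 2) in cm
    sampling_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.head_xy = np.asarray(self.head_xy, dtype=float)
        if self.head_xy.shape != (self.timestamps.size, 2):
            raise SessionValidationError("tracking: head_xy must be (n, 2) matching timestamps")
        if np.any(np.diff(self.timestamps) <= 0):
            raise SessionValidationError("tracking: timestamps must be strictly increasing")


@dataclass
class Trial:
    gate_open_time: float
    ezone_entry_time: float
    first_lick_time: float
    lick_times: np.ndarray
    attack_latency: float | None  # 3.0 or 6.0 s, None if no attack scheduled
    attack_time: float | None
    withdrawal_time: float
    withdrawal_type: WithdrawalType
    gate_close_time: float

    def __post_init__(self) -> None:
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        self.withdrawal_type = WithdrawalType(self.withdrawal_type)

    def validate(self, index: int) -> None:
        name = f"trial {index}"
        seq = [
            ("gate_open_time", self.gate_open_time),
            ("ezone_entry_time", self.ezone_entry_time),
            ("first_lick_time", self.first_lick_time),
            ("withdrawal_time", self.withdrawal_time),
        ]
        for (fa, a), (fb, b) in zip(seq[:-1], seq[1:]):
            if a > b:
                raise SessionValidationError(f"{name}: {fa} > {fb}")
        if self.attack_time is not None:
            if self.attack_latency is None:
                raise SessionValidationError(f"{name}: attack_time without attack_latency")
            expected = self.first_lick_time + self.attack_latency
            if abs(self.attack_time - expected) > 1e-6:
                raise SessionValidationError(
                    f"{name}: attack_time != first_lick_time + attack_latency"
                )
            is_aw = self.withdrawal_time < self.attack_time
            if is_aw != (self.withdrawal_type is WithdrawalType.AW):
                raise SessionValidationError(
                    f"{name}: withdrawal_type inconsistent with withdrawal/attack order"
                )


@dataclass
class EventLog:
    trials: list[Trial]

    def __post_init__(self) -> None:
        for i, t in enumerate(self.trials):
            t.validate(i)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def times(self, name: str) -> np.ndarray:
        vals = [getattr(t, name) for t in self.trials]
        return np.asarray([np.nan if v is None else v for v in vals], dtype=float)


@dataclass
class ArenaGeometry:
    """Rectangular arena (cm): N zone behind a gated wall at ``wall_x``,
    F zone in the open middle, E zone a semicircle around the reward port
    on the far wall.  The E semicircle takes precedence over F.

    Defaults reflect an 80 x 48 cm arena; the E-zone radius (not printed
    anywhere authoritative) defaults to 25 cm, wide enough to cover the
    licking posture region in front of the port.
    """

    width: float = 80.0
    height: float = 48.0
    wall_x: float = 20.0
    gate_y: tuple[float, float] = (16.0, 32.0)  # opening in the N/F wall
    ezone_center: tuple[float, float] = (80.0, 24.0)
    ezone_radius: float = 25.0
    px_per_cm: float = 1.0

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return (
            (xy[:, 0] >= 0)
            & (xy[:, 0] <= self.width)
            & (xy[:, 1] >= 0)
            & (xy[:, 1] <= self.height)
        )

    def distance_to_goal(self, xy: np.ndarray) -> np.ndarray | float:
        """Euclidean distance (cm) from head position(s) to the E-zone center."""
        arr = np.atleast_2d(np.asarray(xy, dtype=float))
        d = np.hypot(arr[:, 0] - self.ezone_center[0], arr[:, 1] - self.ezone_center[1])
        return float(d[0]) if np.asarray(xy).ndim == 1 else d

    def assign_zone(self, xy: np.ndarray) -> np.ndarray | str:
        """Map point(s) to exactly one of N/F/E; raises if outside the arena."""
        arr = np.atleast_2d(np.asarray(xy, dtype=float))
        inside = self.contains(arr)
        if not np.all(inside):
            bad = arr[~inside][0]
            raise OutOfBoundsError(f"point {tuple(bad)} outside arena")
        d = np.hypot(arr[:, 0] - self.ezone_center[0], arr[:, 1] - self.ezone_center[1])
        zones = np.full(arr.shape[0], Zone.F.value, dtype="<U1")
        zones[arr[:, 0] < self.wall_x] = Zone.N.value
        in_e = (d <= self.ezone_radius) & (arr[:, 0] >= self.wall_x)
        zones[in_e] = Zone.E.value
        return str(zones[0]) if np.asarray(xy).ndim == 1 else zones

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "wall_x": self.wall_x,
            "gate_y": list(self.gate_y),
            "ezone_center": list(self.ezone_center),
            "ezone_radius": self.ezone_radius,
            "px_per_cm": self.px_per_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        return cls(
            width=d["width"],
            height=d["height"],
            wall_x=d["wall_x"],
            gate_y=tuple(d["gate_y"]),
            ezone_center=tuple(d["ezone_center"]),
            ezone_radius=d["ezone_radius"],
            px_per_cm=d.get("px_per_cm", 1.0),
        )


@dataclass
class Session:
    units: list[UnitSpikeTrain]
    tracking: TrackingTrace
    events: EventLog
    geometry: ArenaGeometry
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u in self.units:
            u.validate_range(self.duration)
        if self.tracking.timestamps.size and self.tracking.timestamps[-1] > self.duration + 1e-9:
            raise SessionValidationError("tracking: timestamps exceed session duration")
        for i, t in enumerate(self.events.trials):
            if t.gate_close_time > self.duration + 1e-9:
                raise SessionValidationError(f"trial {i}: gate_close_time exceeds duration")

    @property
    def n_units(self) -> int:
        return len(self.units)


# ---------------------------------------------------------------------------
# Convenience / QC operations
# ---------------------------------------------------------------------------

def unit_mean_rate(unit: UnitSpikeTrain, duration: float) -> float:
    return unit.spike_times.size / duration


def apply_unit_qc(
    session: Session,
    min_rate: float = 0.5,
    noise_rate: float = 60.0,
    noise_tol: float = 0.05,
) -> Session:
    """Drop artifact units: mean rate < 0.5 Hz, or mean rate at the 60 Hz
    mains frequency (within ``noise_tol``).  Unit order is preserved; an
    empty result is flagged in metadata rather than raised.
    """
    kept = [
        u
        for u in session.units
        if unit_mean_rate(u, session.duration) >= min_rate
        and abs(unit_mean_rate(u, session.duration) - noise_rate) > noise_tol
    ]
    meta = dict(session.metadata)
    meta["unit_qc"] = {
        "n_before": session.n_units,
        "n_after": len(kept),
        "removed": [u.unit_id for u in session.units if u not in kept],
    }
    if not kept:
        meta["unit_qc"]["empty_after_qc"] = True
    return replace(session, units=kept, metadata=meta)


def session_passes_qc(
    session: Session,
    min_units: int = 10,
    min_trials_per_30min: int = 20,
) -> tuple[bool, list[str]]:
    """Session-level inclusion: at least 10 units and at least 20 approach
    trials per 30 minutes (prorated for other durations)."""
    reasons: list[str] = []
    if session.n_units < min_units:
        reasons.append("units")
    required = min_trials_per_30min * session.duration / 1800.0
    if session.events.n_trials < required:
        reasons.append("approaches")
    return (not reasons), reasons


def interpolate_tracking(trace: TrackingTrace, max_gap: float = 0.5) -> TrackingTrace:
    """Linearly fill NaN tracking gaps up to ``max_gap`` seconds; longer gaps
    stay NaN and are excluded from label pairing downstream."""
    xy = trace.head_xy.copy()
    t = trace.timestamps
    missing = np.isnan(xy).any(axis=1)
    if not missing.any():
        return trace
    # identify contiguous missing runs
    idx = np.flatnonzero(missing)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    good = ~missing
    for run in splits:
        lo, hi = run[0], run[-1]
        t0 = t[lo - 1] if lo > 0 else None
        t1 = t[hi + 1] if hi + 1 < t.size else None
        if t0 is None or t1 is None or (t1 - t0) > max_gap:
            continue
        for k in (0, 1):
            xy[run, k] = np.interp(t[run], [t0, t1], [xy[lo - 1, k], xy[hi + 1, k]])
    return replace(trace, head_xy=xy)


# ---------------------------------------------------------------------------
# Session bundle I/O (units.csv, tracking.csv, events.csv, geometry.json, meta.json)
# ---------------------------------------------------------------------------

_EVENT_COLS = [
    "gate_open_time",
    "ezone_entry_time",
    "first_lick_time",
    "lick_times",
    "attack_latency",
    "attack_time",
    "withdrawal_time",
    "withdrawal_type",
    "gate_close_time",
]


def save_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = [
        {"unit_id": u.unit_id, "region": u.region.value, "spike_time_s": s}
        for u in session.units
        for s in u.spike_times
    ]
    pd.DataFrame(rows, columns=["unit_id", "region", "spike_time_s"]).to_csv(
        path / "units.csv", index=False
    )
    pd.DataFrame(
        {
            "t_s": session.tracking.timestamps,
            "x_cm": session.tracking.head_xy[:, 0],
            "y_cm": session.tracking.head_xy[:, 1],
        }
    ).to_csv(path / "tracking.csv", index=False)
    ev_rows = []
    for t in session.events.trials:
        ev_rows.append(
            {
                "gate_open_time": t.gate_open_time,
                "ezone_entry_time": t.ezone_entry_time,
                "first_lick_time": t.first_lick_time,
                "lick_times": ";".join(f"{x:.6f}" for x in t.lick_times),
                "attack_latency": "" if t.attack_latency is None else t.attack_latency,
                "attack_time": "" if t.attack_time is None else t.attack_time,
                "withdrawal_time": t.withdrawal_time,
                "withdrawal_type": t.withdrawal_type.value,
                "gate_close_time": t.gate_close_time,
            }
        )
    pd.DataFrame(ev_rows, columns=_EVENT_COLS).to_csv(path / "events.csv", index=False)
    (path / "geometry.json").write_text(json.dumps(session.geometry.to_dict(), indent=2))
    meta = dict(session.metadata)
    meta["duration"] = session.duration
    meta["tracking_sampling_rate"] = session.tracking.sampling_rate
    (path / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
    return path


def load_session(path: str | Path) -> Session:
    """Load a session bundle directory; raises ``SessionValidationError``
    naming the offending field on any malformed record."""
    path = Path(path)
    for fname in ("units.csv", "tracking.csv", "events.csv", "geometry.json", "meta.json"):
        if not (path / fname).exists():
            raise SessionValidationError(f"missing file: {fname}")
    meta = json.loads((path / "meta.json").read_text())
    duration = float(meta.pop("duration"))
    fs = float(meta.pop("tracking_sampling_rate", 30.0))
    geometry = ArenaGeometry.from_dict(json.loads((path / "geometry.json").read_text()))

    udf = pd.read_csv(path / "units.csv")
    units = []
    for (uid, reg), grp in udf.groupby(["unit_id", "region"], sort=False):
        units.append(UnitSpikeTrain(str(uid), Region(reg), np.sort(grp["spike_time_s"].to_numpy())))

    tdf = pd.read_csv(path / "tracking.csv")
    tracking = TrackingTrace(
        tdf["t_s"].to_numpy(), tdf[["x_cm", "y_cm"]].to_numpy(), sampling_rate=fs
    )

    edf = pd.read_csv(path / "events.csv")
    trials = []
    for _, r in edf.iterrows():
        licks = (
            np.array([float(x) for x in str(r["lick_times"]).split(";") if x])
            if pd.notna(r["lick_times"])
            else np.array([])
        )
        lat = None if pd.isna(r["attack_latency"]) else float(r["attack_latency"])
        atk = None if pd.isna(r["attack_time"]) else float(r["attack_time"])
        trials.append(
            Trial(
                gate_open_time=float(r["gate_open_time"]),
                ezone_entry_time=float(r["ezone_entry_time"]),
                first_lick_time=float(r["first_lick_time"]),
                lick_times=licks,
                attack_latency=lat,
                attack_time=atk,
                withdrawal_time=float(r["withdrawal_time"]),
                withdrawal_type=WithdrawalType(r["withdrawal_type"]),
                gate_close_time=float(r["gate_close_time"]),
            )
        )
    return Session(
        units=units,
        tracking=tracking,
        events=EventLog(trials),
        geometry=geometry,
        duration=duration,
        metadata=meta,
    )
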