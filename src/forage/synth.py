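"""Synthetic session generator.

Emulates the statistical structure of a naturalistic approach-avoidance
foraging session: a rat shuttles N -> F -> E -> F -> N on every trial,
licks at a sucrose port inside the E zone, and is attacked by the robot
3 s (30%) or 6 s (70%) after the first lick.  Withdrawal before the
attack is an avoidance (AW) trial, after it an escape (EW) trial.

Units are drawn from four archetypes:

* ``distance_tuned`` — Gaussian tuning to distance-from-goal,
  rate = baseline + peak * exp(-(d - d_pref)^2 / (2 w^2));
* ``type1_like``    — brief firing bump ~200 ms before E-zone head-entry,
  then suppression;
* ``type2_like``    — sustained elevation from head-entry to
  head-withdrawal, stronger on AW trials (avoidance-selective);
* ``noise``         — homogeneous Poisson.

Spikes are generated by thinning an inhomogeneous Poisson process on a
1 kHz grid, matching the 1 kHz serialization used downstream.  Every
generated unit/trial carries a ground-truth record for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    ArenaGeometry,
    EventLog,
    Region,
    Session,
    TrackingTrace,
    Trial,
    UnitSpikeTrain,
    WithdrawalType,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "GenerationError",
    "generate_trials",
    "generate_trajectory",
    "generate_units",
    "generate_session",
]

ARCHETYPES = ("distance_tuned", "type1_like", "type2_like", "noise")


class GenerationError(RuntimeError):
    pass


@dataclass
class GeneratorConfig:
    n_units: int = 20
    # archetype mix (must sum to 1); counts by largest-remainder rounding
    fractions: dict = field(
        default_factory=lambda: {
            "distance_tuned": 0.4,
            "type1_like": 0.2,
            "type2_like": 0.2,
            "noise": 0.2,
        }
    )
    # distance tuning (cm / Hz)
    pref_distance_range: tuple[float, float] = (5.0, 60.0)
    tuning_width: float = 12.0
    tuning_peak: float = 8.0
    tuning_baseline: float = 2.0
    # event modulation templates
    type1_baseline: float = 4.0
    type1_bump_amp: float = 10.0       # Hz, pre-entry anticipatory bump
    type1_bump_center: float = -0.2    # s relative to head-entry
    type1_bump_sd: float = 0.1         # s
    type1_suppression: float = 0.4     # multiplicative, for 2 s after entry
    type2_baseline: float = 3.0
    type2_amp_aw: float = 6.0          # Hz added entry->withdrawal on AW trials
    type2_amp_ew: float = 2.0          # on EW trials (AW-selective contrast)
    noise_rate: float = 5.0
    # trial flow
    n_trials: int = 40
    p_attack_3s: float = 0.30          # printed mixture: 3 s 30% / 6 s 70%
    aw_probability: float = 0.65       # printed AW proportion 65.11%
    balanced_outcomes: bool = False    # force exact AW/EW counts
    # locomotion
    speed_mean: float = 25.0           # cm/s
    speed_sd: float = 5.0
    jitter_cm: float = 0.3
    nonnav_fraction: float = 0.3       # fraction of N-zone dwell spent stationary
    # session
    duration: float = 1800.0
    tracking_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.get(a, 0.0) for a in ARCHETYPES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("archetype fractions must sum to 1")
        for p in (self.p_attack_3s, self.aw_probability, self.nonnav_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def archetype_counts(self) -> dict[str, int]:
        """Largest-remainder apportionment of n_units over archetypes."""
        raw = {a: self.fractions.get(a, 0.0) * self.n_units for a in ARCHETYPES}
        counts = {a: int(np.floor(v)) for a, v in raw.items()}
        short = self.n_units - sum(counts.values())
        order = sorted(ARCHETYPES, key=lambda a: raw[a] - counts[a], reverse=True)
        for a in order[:short]:
            counts[a] += 1
        return counts


@dataclass
class GroundTruth:
    units: list[dict]
    trials: list[dict]
    nonnav_segments: list[tuple[float, float]]


# Trajectory anchor points (cm) for the default geometry
def _anchors(geom: ArenaGeometry) -> dict:
    cy = geom.height / 2.0
    return {
        "nest": np.array([geom.wall_x / 2.0, cy]),
        "entry": np.array([geom.ezone_center[0] - geom.ezone_radius, cy]),
        "lick": np.array([geom.ezone_center[0] - 8.0, cy]),
    }


def generate_trials(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    geometry: ArenaGeometry | None = None,
) -> EventLog:
    """Generate the per-trial event schedule.

    Attack latency ~ Bernoulli(3 s with p_attack_3s, else 6 s); AW trials
    withdraw uniformly on [first_lick + 0.5, attack - 0.2], EW trials at
    attack + reaction ~ N(0.3, 0.1) truncated at 0.05 s.
    """
    if config.n_trials < 1:
        raise GenerationError("n_trials must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    geom = geometry or ArenaGeometry()
    anchors = _anchors(geom)
    out_dist = float(np.linalg.norm(anchors["entry"] - anchors["nest"]))
    lick_dist = float(np.linalg.norm(anchors["lick"] - anchors["entry"]))

    cycle = config.duration / config.n_trials
    if cycle < 14.0:
        raise GenerationError(
            f"trial cycle {cycle:.1f}s too short for the minimum traversal"
        )

    if config.balanced_outcomes:
        n_aw = int(round(config.aw_probability * config.n_trials))
        outcomes = np.array([True] * n_aw + [False] * (config.n_trials - n_aw))
        rng.shuffle(outcomes)
    else:
        outcomes = rng.random(config.n_trials) < config.aw_probability

    trials = []
    for i in range(config.n_trials):
        gate_open = i * cycle + 2.0
        speed = max(10.0, rng.normal(config.speed_mean, config.speed_sd))
        entry = gate_open + out_dist / speed
        first_lick = entry + lick_dist / speed + 0.2
        latency = 3.0 if rng.random() < config.p_attack_3s else 6.0
        attack = first_lick + latency
        if outcomes[i]:
            withdrawal = rng.uniform(first_lick + 0.5, attack - 0.2)
            wtype = WithdrawalType.AW
        else:
            withdrawal = attack + max(0.05, rng.normal(0.3, 0.1))
            wtype = WithdrawalType.EW
        licks = np.arange(first_lick, min(withdrawal, attack), 1.0 / 6.0)
        gate_close = max(withdrawal, attack) + 0.2
        trials.append(
            Trial(
                gate_open_time=gate_open,
                ezone_entry_time=entry,
                first_lick_time=first_lick,
                lick_times=licks,
                attack_latency=latency,
                attack_time=attack,
                withdrawal_time=withdrawal,
                withdrawal_type=wtype,
                gate_close_time=gate_close,
            )
        )
    return EventLog(trials)


def generate_trajectory(
    config: GeneratorConfig,
    events: EventLog,
    rng: np.random.Generator | None = None,
    geometry: ArenaGeometry | None = None,
) -> tuple[TrackingTrace, list[tuple[float, float]]]:
    """Piecewise N->F->E->F->N path through the trial keyframes, with
    optional stationary (non-navigational) dwell segments in the N zone.

    Returns the trace and the list of non-navigational (start, end) times.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    geom = geometry or ArenaGeometry()
    anchors = _anchors(geom)
    nest, entry_pt, lick_pt = anchors["nest"], anchors["entry"], anchors["lick"]
    ret_dist = float(np.linalg.norm(entry_pt - nest))

    key_t: list[float] = [0.0]
    key_xy: list[np.ndarray] = [nest]
    nonnav: list[tuple[float, float]] = []
    for tr in events.trials:
        # implied outbound speed from the event schedule
        speed = ret_dist / max(tr.ezone_entry_time - tr.gate_open_time, 1e-6)
        arrive_back = tr.withdrawal_time + ret_dist / speed
        if arrive_back >= config.duration:
            raise GenerationError("trial extends past session end")
        # N-zone dwell before gate opening: optionally stationary sub-segment
        dwell_start, dwell_end = key_t[-1], tr.gate_open_time
        if (
            config.nonnav_fraction > 0
            and dwell_end - dwell_start > 4.0
        ):
            span = (dwell_end - dwell_start - 2.0) * config.nonnav_fraction
            a = dwell_start + 1.0
            b = a + span
            spot = nest + rng.uniform(-4.0, 4.0, size=2)
            key_t += [a, b]
            key_xy += [spot, spot]
            if span > 0:
                nonnav.append((a, b))
        key_t += [
            tr.gate_open_time,
            tr.ezone_entry_time,
            max(tr.first_lick_time - 0.2, tr.ezone_entry_time),
            tr.withdrawal_time,
            arrive_back,
        ]
        key_xy += [nest, entry_pt, lick_pt, lick_pt, nest]
    key_t.append(config.duration)
    key_xy.append(nest)

    key_t_arr = np.asarray(key_t)
    key_xy_arr = np.asarray(key_xy)
    ts = np.arange(0.0, config.duration, 1.0 / config.tracking_rate)
    x = np.interp(ts, key_t_arr, key_xy_arr[:, 0])
    y = np.interp(ts, key_t_arr, key_xy_arr[:, 1])

    if config.jitter_cm > 0:
        jit = rng.normal(0.0, config.jitter_cm, size=(ts.size, 2))
        for a, b in nonnav:  # stationary segments stay stationary
            jit[(ts >= a) & (ts <= b)] = 0.0
        x = x + jit[:, 0]
        y = y + jit[:, 1]
    x = np.clip(x, 0.2, geom.width - 0.2)
    y = np.clip(y, 0.2, geom.height - 0.2)
    trace = TrackingTrace(ts, np.column_stack([x, y]), sampling_rate=config.tracking_rate)
    return trace, nonnav


def _rate_vectors(
    config: GeneratorConfig,
    archetypes: list[str],
    tracking: TrackingTrace,
    events: EventLog,
    geometry: ArenaGeometry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    """Per-unit 1 kHz rate vectors (Hz) and ground-truth parameter records."""
    n_ms = int(round(config.duration * 1000))
    t_ms = (np.arange(n_ms) + 0.5) * 1e-3
    x = np.interp(t_ms, tracking.timestamps, tracking.head_xy[:, 0])
    y = np.interp(t_ms, tracking.timestamps, tracking.head_xy[:, 1])
    d = np.hypot(x - geometry.ezone_center[0], y - geometry.ezone_center[1])

    entries = events.times("ezone_entry_time")
    withdrawals = events.times("withdrawal_time")
    is_aw = np.array([t.withdrawal_type is WithdrawalType.AW for t in events.trials])

    rates = np.empty((len(archetypes), n_ms))
    gt: list[dict] = []
    for i, arch in enumerate(archetypes):
        params: dict = {"archetype": arch}
        if arch == "distance_tuned":
            pref = rng.uniform(*config.pref_distance_range)
            r = config.tuning_baseline + config.tuning_peak * np.exp(
                -((d - pref) ** 2) / (2 * config.tuning_width**2)
            )
            params.update(
                preferred_distance=pref,
                width=config.tuning_width,
                peak=config.tuning_peak,
                baseline=config.tuning_baseline,
            )
        elif arch == "type1_like":
            r = np.full(n_ms, config.type1_baseline)
            for e in entries:
                c = e + config.type1_bump_center
                lo, hi = np.searchsorted(t_ms, [c - 0.5, c + 0.5])
                r[lo:hi] += config.type1_bump_amp * np.exp(
                    -((t_ms[lo:hi] - c) ** 2) / (2 * config.type1_bump_sd**2)
                )
                s0, s1 = np.searchsorted(t_ms, [e, e + 2.0])
                r[s0:s1] *= config.type1_suppression
            params.update(
                baseline=config.type1_baseline,
                bump_amp=config.type1_bump_amp,
                bump_center=config.type1_bump_center,
                bump_sd=config.type1_bump_sd,
            )
        elif arch == "type2_like":
            r = np.full(n_ms, config.type2_baseline)
            for e, w, aw in zip(entries, withdrawals, is_aw):
                amp = config.type2_amp_aw if aw else config.type2_amp_ew
                s0, s1 = np.searchsorted(t_ms, [e, w])
                r[s0:s1] += amp
            params.update(
                baseline=config.type2_baseline,
                amp_aw=config.type2_amp_aw,
                amp_ew=config.type2_amp_ew,
            )
        else:  # noise
            r = np.full(n_ms, config.noise_rate)
            params.update(rate=config.noise_rate)
        rates[i] = r
        gt.append(params)
    return rates, gt


def generate_units(
    config: GeneratorConfig,
    tracking: TrackingTrace,
    events: EventLog,
    rng: np.random.Generator | None = None,
    geometry: ArenaGeometry | None = None,
) -> tuple[list[UnitSpikeTrain], list[dict]]:
    """Inhomogeneous-Poisson spike trains by 1 kHz thinning."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    geom = geometry or ArenaGeometry()
    counts = config.archetype_counts()
    archetypes = [a for a in ARCHETYPES for _ in range(counts[a])]
    rates, gt = _rate_vectors(config, archetypes, tracking, events, geom, rng)

    units = []
    for i, arch in enumerate(archetypes):
        p = np.clip(rates[i] * 1e-3, 0.0, 1.0)
        hits = np.flatnonzero(rng.random(p.size) < p)
        spikes = (hits + 0.5) * 1e-3
        region = Region.PL if i % 5 < 3 else Region.IL  # ~60% PL, interleaved
        uid = f"u{i:03d}"
        units.append(UnitSpikeTrain(uid, region, spikes))
        gt[i]["unit_id"] = uid
        gt[i]["region"] = region.value
    return units, gt


def generate_session(config: GeneratorConfig) -> tuple[Session, GroundTruth]:
    """Assemble a full QC-passing session; deterministic under config.seed."""
    rng = np.random.default_rng(config.seed)
    geom = ArenaGeometry()
    events = generate_trials(config, rng=rng, geometry=geom)
    tracking, nonnav = generate_trajectory(config, events, rng=rng, geometry=geom)
    units, unit_gt = generate_units(config, tracking, events, rng=rng, geometry=geom)
    session = Session(
        units=units,
        tracking=tracking,
        events=events,
        geometry=geom,
        duration=config.duration,
        metadata={"rat_id": "synthetic", "session_id": f"seed{config.seed}", "condition": "Lobster"},
    )
    trial_gt = [
        {"withdrawal_type": t.withdrawal_type.value, "attack_latency": t.attack_latency}
        for t in events.trials
    ]
    return session, GroundTruth(units=unit_gt, trials=trial_gt, nonnav_segments=nonnav)
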