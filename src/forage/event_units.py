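"""Event-aligned unit analyses: peri-event time histograms (PETHs), the
3-sigma responsiveness criterion, run-and-stop event detection, the
pseudo-unit agglomerative clustering of response profiles, combined
Type 1 / Type 2 assignment, and regional type proportions.

PETHs span +/- 2 s around an event at 50 ms resolution (80 bins),
trial-averaged, and z-scored against the gate-opening-aligned baseline
vector (the rat faces away from the robot when the gate opens on its
return to the N zone, so that window serves as reference activity).

Clustering merges the most Pearson-correlated pair of (pseudo-)units
into a new pseudo-unit whose response is the plain average of the two
merged responses — deliberately unweighted by member count, so it is not
centroid linkage — until eight pseudo-units remain; pseudo-units with
fewer than 50 members are labeled artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .core import ArenaGeometry, Session, TrackingTrace, UnitSpikeTrain

logger = logging.getLogger(__name__)

__all__ = [
    "PETH",
    "ClusterResult",
    "ClusterAssignment",
    "DegenerateBaselineError",
    "build_peth",
    "is_responsive",
    "detect_run_and_stop",
    "hierarchical_cluster",
    "assign_combined_types",
    "regional_type_proportions",
]

PETH_BINS = 80
PETH_HALF = 2.0  # s before/after the event


class DegenerateBaselineError(ValueError):
    """Baseline vector has zero variance; the unit cannot be z-scored."""


@dataclass
class PETH:
    unit_id: str
    event: str
    z: np.ndarray                    # 80 z-scored bins, [-2 s, +2 s)
    baseline_mean: float
    baseline_sd: float
    n_events: int


@dataclass
class ClusterResult:
    labels: np.ndarray               # per input unit: 1-based cluster id (1 = largest)
    sizes: dict                      # id -> member count
    valid: dict                      # id -> size >= min_size
    templates: dict                  # id -> mean 80-bin response of members
    n_merges: int
    excluded: list                   # indices of constant-vector units left out


@dataclass
class ClusterAssignment:
    unit_id: str
    he_cluster: int | None           # None = artifact/excluded
    hw_cluster: int | None
    combined: str                    # "Type1" | "Type2" | "Other"


def _trial_average_counts(
    unit: UnitSpikeTrain, event_times: np.ndarray
) -> np.ndarray:
    edges = np.linspace(-PETH_HALF, PETH_HALF, PETH_BINS + 1)
    counts = np.zeros(PETH_BINS)
    n = 0
    for e in event_times:
        if not np.isfinite(e):
            continue
        h, _ = np.histogram(unit.spike_times - e, bins=edges)
        counts += h
        n += 1
    if n == 0:
        raise ValueError("no event occurrences")
    return counts / n


def build_peth(
    session: Session,
    unit_id: str,
    event_times: np.ndarray,
    event: str = "event",
    baseline_event_times: np.ndarray | None = None,
) -> PETH:
    """80-bin trial-averaged PETH, z-scored with the (mean, sd) of the
    gate-opening-aligned baseline vector."""
    unit = next(u for u in session.units if u.unit_id == unit_id)
    if baseline_event_times is None:
        baseline_event_times = session.events.times("gate_open_time")
    x = _trial_average_counts(unit, np.asarray(event_times, dtype=float))
    base = _trial_average_counts(unit, np.asarray(baseline_event_times, dtype=float))
    m, s = float(base.mean()), float(base.std())
    if s == 0:
        raise DegenerateBaselineError(f"unit {unit_id}: zero-variance baseline")
    return PETH(
        unit_id=unit_id,
        event=event,
        z=(x - m) / s,
        baseline_mean=m,
        baseline_sd=s,
        n_events=int(np.isfinite(event_times).sum()),
    )


def is_responsive(peth: PETH, threshold: float = 3.0) -> bool:
    """A unit is event-responsive if any PETH bin deviates from baseline
    by more than ``threshold`` sigma in either direction."""
    return bool(np.any(np.abs(peth.z) > threshold))


def detect_run_and_stop(
    tracking: TrackingTrace,
    geometry: ArenaGeometry,
    run_speed: float = 7.5,
    run_min_dur: float = 2.0,
    stop_speed: float = 5.0,
    stop_min_dur: float = 1.0,
    smooth_window: float = 0.2,
    adjacency_tol: float | None = None,
) -> np.ndarray:
    """Run-and-stop events: the boundary between a run segment
    (>= 7.5 cm/s for >= 2 s) and a stop segment (<= 5 cm/s for >= 1 s)
    that begins essentially immediately after it, with the boundary
    located outside the E zone.

    Speed is estimated by central differences on position smoothed with a
    200 ms moving average.  The smoothing unavoidably blurs a sharp
    run->stop transition into a brief mid-speed ramp, so the stop may
    begin up to one tracking sample plus half the smoothing window after
    the run ends (``adjacency_tol`` overrides); any longer mid-speed
    stretch breaks the pair.  The event time is the midpoint of run end
    and stop start.
    """
    t = tracking.timestamps
    if t.size < 3:
        return np.array([])
    win = max(int(round(smooth_window * tracking.sampling_rate)), 1)
    kern = np.ones(win) / win
    x = np.convolve(tracking.head_xy[:, 0], kern, mode="same")
    y = np.convolve(tracking.head_xy[:, 1], kern, mode="same")
    speed = np.hypot(np.gradient(x, t), np.gradient(y, t))
    if adjacency_tol is None:
        adjacency_tol = 1.0 / tracking.sampling_rate + smooth_window / 2.0

    def _segments(mask: np.ndarray) -> list[tuple[int, int]]:
        d = np.diff(mask.astype(int))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if mask[0]:
            starts = np.concatenate([[0], starts])
        if mask[-1]:
            ends = np.concatenate([ends, [mask.size]])
        return list(zip(starts, ends))  # end exclusive

    runs = [
        (s, e) for s, e in _segments(speed >= run_speed) if t[e - 1] - t[s] >= run_min_dur
    ]
    stops = [
        (s, e) for s, e in _segments(speed <= stop_speed) if t[e - 1] - t[s] >= stop_min_dur
    ]
    events = []
    for rs, re in runs:
        nxt = [s for s in stops if s[0] >= re and t[s[0]] - t[re - 1] <= adjacency_tol]
        if not nxt:
            continue
        ss, _ = nxt[0]
        boundary = 0.5 * (t[re - 1] + t[ss])
        xy = tracking.head_xy[ss]
        if np.isnan(xy).any():
            continue
        if geometry.assign_zone(xy) == "E":
            continue
        events.append(boundary)
    return np.asarray(events)


def hierarchical_cluster(
    peths: list[PETH] | np.ndarray,
    n_pseudo: int = 8,
    min_size: int = 50,
) -> ClusterResult:
    """Agglomerative pseudo-unit clustering of event-response vectors.

    Repeatedly merges the pair of (pseudo-)units with the highest Pearson
    correlation; the new pseudo-unit's response is the unweighted average
    of the two merged responses.  Stops when ``n_pseudo`` pseudo-units
    remain (exactly n_units - n_pseudo merges).  Ties break toward the
    lexicographically smallest index pair.  Constant response vectors
    (undefined correlation) are excluded with a log entry.
    """
    if isinstance(peths, np.ndarray):
        V = np.asarray(peths, dtype=float)
    else:
        V = np.vstack([p.z for p in peths])
    n_total = V.shape[0]
    const = np.flatnonzero(V.std(axis=1) == 0)
    for i in const:
        logger.warning("hierarchical_cluster: excluding constant-vector unit %d", i)
    active_ids = [i for i in range(n_total) if i not in set(const.tolist())]
    if len(active_ids) < n_pseudo:
        raise ValueError("fewer usable units than requested pseudo-units")

    members: dict[int, list[int]] = {i: [i] for i in active_ids}
    templates: dict[int, np.ndarray] = {i: V[i].astype(float) for i in active_ids}

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        den = np.sqrt((a @ a) * (b @ b))
        return float(a @ b / den) if den > 0 else -np.inf

    ids = sorted(members)
    R = {
        (i, j): _corr(templates[i], templates[j])
        for ai, i in enumerate(ids)
        for j in ids[ai + 1 :]
    }
    n_merges = 0
    while len(members) > n_pseudo:
        # max correlation; ties -> smallest (i, j)
        best = max(R.items(), key=lambda kv: (kv[1], (-kv[0][0], -kv[0][1])))
        (i, j), _ = best
        new = templates[i] + templates[j]
        templates[i] = new / 2.0  # unweighted average of the two merged responses
        members[i] = members[i] + members[j]
        del members[j], templates[j]
        R = {k: v for k, v in R.items() if j not in k and i not in k}
        for other in members:
            if other == i:
                continue
            key = (min(i, other), max(i, other))
            R[key] = _corr(templates[i], templates[other])
        n_merges += 1

    # 1-based ids ordered by member count (largest = 1); ties by root index
    order = sorted(members, key=lambda k: (-len(members[k]), k))
    labels = np.zeros(n_total, dtype=int)
    sizes, valid, out_templates = {}, {}, {}
    for rank, root in enumerate(order, start=1):
        for m in members[root]:
            labels[m] = rank
        sizes[rank] = len(members[root])
        valid[rank] = len(members[root]) >= min_size
        out_templates[rank] = V[members[root]].mean(axis=0)
    return ClusterResult(
        labels=labels,
        sizes=sizes,
        valid=valid,
        templates=out_templates,
        n_merges=n_merges,
        excluded=const.tolist(),
    )


def assign_combined_types(
    he: ClusterResult,
    hw: ClusterResult,
    unit_ids: list[str] | None = None,
) -> list[ClusterAssignment]:
    """Combine head-entry and head-withdrawal cluster memberships:
    Type 1 = HE1 & HW1, Type 2 = HE2 & HW2, everything else (including
    artifact clusters) Other.  Cluster numbering is by size (1 = largest
    valid cluster)."""
    n = he.labels.size
    if hw.labels.size != n:
        raise ValueError("HE and HW assignments cover different unit sets")
    unit_ids = unit_ids or [f"u{i:03d}" for i in range(n)]
    out = []
    for i in range(n):
        he_c = int(he.labels[i]) if he.labels[i] > 0 and he.valid.get(int(he.labels[i])) else None
        hw_c = int(hw.labels[i]) if hw.labels[i] > 0 and hw.valid.get(int(hw.labels[i])) else None
        if he_c == 1 and hw_c == 1:
            combined = "Type1"
        elif he_c == 2 and hw_c == 2:
            combined = "Type2"
        else:
            combined = "Other"
        out.append(ClusterAssignment(unit_ids[i], he_c, hw_c, combined))
    return out


def regional_type_proportions(
    assignments: list[ClusterAssignment],
    regions: list[str],
    type_name: str = "Type2",
) -> dict:
    """2x2 contingency (region x is-type) and Pearson chi-square (1 df,
    no continuity correction)."""
    if len(assignments) != len(regions):
        raise ValueError("assignments and regions differ in length")
    table = np.zeros((2, 2), dtype=int)
    for a, r in zip(assignments, regions):
        row = 0 if r == "PL" else 1
        col = 0 if a.combined == type_name else 1
        table[row, col] += 1
    if table.sum(axis=1).min() == 0:
        raise ValueError("a region has no units")
    chi2, p, dof, expected = chi2_contingency(table, correction=False)
    return {
        "table": table,
        "chi2": float(chi2),
        "p": float(p),
        "dof": int(dof),
        "expected": expected,
    }
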