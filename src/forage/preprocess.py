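"""Spike-train preprocessing: spike-density functions, normalization,
50 ms binning, and the paired feature/label datasets used by the decoders.

Each unit's spike train is serialized to a 1 kHz indicator vector,
convolved with a unit-sum Gaussian kernel (SD 100 ms, length 1 s),
z-scored over the whole session, and binned into 50 ms windows
(20 points per second).  Distance decoding pairs each 50 ms ensemble
vector with the rat's concurrent distance from the E-zone center;
outcome classification pairs 2 s withdrawal-aligned windows (40 bins
per unit) with the trial's AW/EW label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .core import Session, Zone, interpolate_tracking

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedEnsemble",
    "EventWindowMatrix",
    "DegenerateUnitError",
    "gaussian_kernel",
    "spike_density",
    "zscore_unit",
    "bin_50ms",
    "build_distance_dataset",
    "build_event_dataset",
    "equalize_distance_bins",
    "shuffle_labels",
    "spatial_firing_map",
]

FS = 1000  # serialization rate, Hz
BIN_MS = 50


class DegenerateUnitError(ValueError):
    """Zero-variance activity vector cannot be z-scored."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class BinnedEnsemble:
    """[n_bins x n_units] z-scored 50 ms ensemble activity with labels."""

    X: np.ndarray
    unit_ids: list[str]
    bin_centers: np.ndarray          # s
    distance: np.ndarray             # cm, per bin
    zone: np.ndarray                 # 'N'/'F'/'E' per bin
    flags: dict = field(default_factory=dict)   # name -> bool array
    norms: dict = field(default_factory=dict)   # unit_id -> (mean, sd) of the 1 kHz SDF

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]

    @property
    def n_units(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "BinnedEnsemble":
        return replace(
            self,
            X=self.X[idx],
            bin_centers=self.bin_centers[idx],
            distance=self.distance[idx],
            zone=self.zone[idx],
            flags={k: v[idx] for k, v in self.flags.items()},
        )

    def drop_units(self, unit_idx: np.ndarray | list[int]) -> "BinnedEnsemble":
        keep = np.setdiff1d(np.arange(self.n_units), np.asarray(unit_idx, dtype=int))
        return replace(
            self,
            X=self.X[:, keep],
            unit_ids=[self.unit_ids[i] for i in keep],
        )


@dataclass
class EventWindowMatrix:
    """[n_trials x (40 * n_units)] event-aligned activity with AW/EW labels.

    ``offset`` is the window end relative to the aligning event (s); the
    window always spans the preceding ``window_len`` seconds.
    """

    X: np.ndarray
    y: np.ndarray                    # 'AW'/'EW' per trial
    unit_ids: list[str]
    offset: float
    window_len: float = 2.0
    trial_index: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def bins_per_unit(self) -> int:
        return self.X.shape[1] // len(self.unit_ids)

    def unit_columns(self, unit_idx: int) -> slice:
        b = self.bins_per_unit
        return slice(unit_idx * b, (unit_idx + 1) * b)

    def drop_units(self, unit_idx: np.ndarray | list[int]) -> "EventWindowMatrix":
        drop = set(int(i) for i in np.asarray(unit_idx, dtype=int))
        keep = [i for i in range(self.n_units) if i not in drop]
        cols = np.concatenate([np.arange(self.X.shape[1])[self.unit_columns(i)] for i in keep])
        return replace(self, X=self.X[:, cols], unit_ids=[self.unit_ids[i] for i in keep])


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def gaussian_kernel(sd_ms: float = 100.0, length_ms: float = 1000.0) -> np.ndarray:
    """Unit-sum Gaussian kernel on the 1 kHz grid.

    Built with an odd tap count (length_ms + 1 samples, i.e. +/- length/2)
    so that 'same'-mode convolution is exactly centered.
    """
    half = int(round(length_ms / 2))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-(x**2) / (2 * sd_ms**2))
    return k / k.sum()


def spike_density(
    spike_times: np.ndarray,
    duration: float,
    sd_ms: float = 100.0,
    length_ms: float = 1000.0,
) -> np.ndarray:
    """Serialize spikes to a 1 kHz indicator and smooth with the Gaussian
    kernel (zero-padded, 'same' length).  Unit-sum kernel preserves total
    spike count up to edge losses."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * FS))
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size and (spikes.min() < 0 or spikes.max() > duration):
        raise ValueError("spike times outside [0, duration]")
    idx = np.minimum((spikes * FS).astype(int), n - 1)
    vec = np.bincount(idx, minlength=n).astype(float)
    if not spikes.size:
        return vec
    return fftconvolve(vec, gaussian_kernel(sd_ms, length_ms), mode="same")


def zscore_unit(sdf: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Session-wide z-scoring; the (mean, sd) pair is reused wherever the
    same unit is re-normalized (event windows)."""
    m = float(np.mean(sdf))
    s = float(np.std(sdf))
    if s == 0:
        raise DegenerateUnitError("zero-variance activity vector")
    return (sdf - m) / s, (m, s)


def bin_50ms(vec: np.ndarray, bin_ms: int = BIN_MS) -> np.ndarray:
    """Average consecutive 50-sample windows: 20 bins per second.  A
    non-multiple tail is truncated (logged)."""
    n = vec.size - (vec.size % bin_ms)
    if n != vec.size:
        logger.info("bin_50ms: truncating %d trailing samples", vec.size - n)
    return vec[:n].reshape(-1, bin_ms).mean(axis=1)


# ---------------------------------------------------------------------------
# Dataset builders
# ---------------------------------------------------------------------------

def _session_sdfs(session: Session) -> tuple[np.ndarray, dict]:
    """Z-scored 1 kHz SDF per unit, stacked [n_units x n_samples]."""
    mats, norms = [], {}
    for u in session.units:
        z, (m, s) = zscore_unit(spike_density(u.spike_times, session.duration))
        mats.append(z)
        norms[u.unit_id] = (m, s)
    return np.vstack(mats), norms


def build_distance_dataset(session: Session) -> BinnedEnsemble:
    """Pair each 50 ms ensemble bin with distance-to-goal, zone, and
    behavioral flags (door_closed, outbound, inbound, critical_event,
    non_navigational).  Bins with missing tracking are dropped."""
    Z, norms = _session_sdfs(session)
    X = np.stack([bin_50ms(z) for z in Z], axis=1)
    n_bins = X.shape[0]
    centers = (np.arange(n_bins) + 0.5) * (BIN_MS / FS)

    trace = interpolate_tracking(session.tracking)
    # nearest tracking sample to each bin center
    ts = trace.timestamps
    pos_idx = np.clip(np.searchsorted(ts, centers), 1, ts.size - 1)
    left_closer = (centers - ts[pos_idx - 1]) < (ts[pos_idx] - centers)
    pos_idx = pos_idx - left_closer.astype(int)
    xy = trace.head_xy[pos_idx]
    valid = ~np.isnan(xy).any(axis=1)

    geom = session.geometry
    distance = np.full(n_bins, np.nan)
    zone = np.full(n_bins, "?", dtype="<U1")
    if valid.any():
        distance[valid] = geom.distance_to_goal(xy[valid])
        zone[valid] = geom.assign_zone(xy[valid])

    ev = session.events
    gate_open = ev.times("gate_open_time")
    gate_close = ev.times("gate_close_time")
    entries = ev.times("ezone_entry_time")
    withdrawals = ev.times("withdrawal_time")

    door_closed = np.zeros(n_bins, dtype=bool)
    outbound = np.zeros(n_bins, dtype=bool)
    inbound = np.zeros(n_bins, dtype=bool)
    for i in range(ev.n_trials):
        nxt_open = gate_open[i + 1] if i + 1 < ev.n_trials else session.duration
        door_closed |= (centers >= gate_close[i]) & (centers < nxt_open)
        outbound |= (centers >= gate_open[i]) & (centers < entries[i])
        inbound |= (centers >= withdrawals[i]) & (centers < nxt_open)

    critical = np.zeros(n_bins, dtype=bool)
    for e in np.concatenate([entries, withdrawals]):
        critical |= (centers >= e - 1.0) & (centers < e + 1.0)

    # non-navigational: near-stationary while in the N zone (>=1 s below 2 cm/s)
    non_nav = np.zeros(n_bins, dtype=bool)
    if ts.size > 2:
        dt = np.gradient(ts)
        speed = np.hypot(np.gradient(trace.head_xy[:, 0]), np.gradient(trace.head_xy[:, 1])) / dt
        win = max(int(round(0.2 * trace.sampling_rate)), 1)
        speed = np.convolve(speed, np.ones(win) / win, mode="same")
        slow = speed < 2.0
        bin_slow = slow[pos_idx]
        non_nav = bin_slow & (zone == "N")

    keep = valid
    flags = {
        "door_closed": door_closed,
        "outbound": outbound,
        "inbound": inbound,
        "critical_event": critical,
        "non_navigational": non_nav,
    }
    data = BinnedEnsemble(
        X=X,
        unit_ids=[u.unit_id for u in session.units],
        bin_centers=centers,
        distance=distance,
        zone=zone,
        flags=flags,
        norms=norms,
    )
    return data.subset(np.flatnonzero(keep))


def build_event_dataset(
    session: Session,
    align: str = "withdrawal_time",
    window_offset: float = 0.0,
    window_len: float = 2.0,
) -> EventWindowMatrix:
    """Per trial, bin each unit's z-scored activity over the window
    [t_event + offset - window_len, t_event + offset] into 50 ms bins
    (40 per unit for the default 2 s window) and concatenate units into
    one row.  Normalization reuses the session-wide per-unit (mean, sd).
    Trials whose window exits the recording are dropped with a warning.
    """
    Z, _ = _session_sdfs(session)
    event_times = session.events.times(align)
    labels = np.array([t.withdrawal_type.value for t in session.events.trials])

    nbin = int(round(window_len * FS / BIN_MS))
    rows, kept, kept_labels = [], [], []
    n_samples = Z.shape[1]
    for i, t_ev in enumerate(event_times):
        if np.isnan(t_ev):
            continue
        start = t_ev + window_offset - window_len
        s0 = int(round(start * FS))
        s1 = s0 + int(round(window_len * FS))
        if s0 < 0 or s1 > n_samples:
            warnings.warn(f"trial {i}: event window exits recording; dropped")
            continue
        seg = Z[:, s0:s1]  # [n_units x window samples]
        binned = seg.reshape(Z.shape[0], nbin, BIN_MS).mean(axis=2)
        rows.append(binned.reshape(-1))
        kept.append(i)
        kept_labels.append(labels[i])
    if not rows:
        raise ValueError("no trial window fits within the recording")
    return EventWindowMatrix(
        X=np.vstack(rows),
        y=np.asarray(kept_labels),
        unit_ids=[u.unit_id for u in session.units],
        offset=window_offset,
        window_len=window_len,
        trial_index=np.asarray(kept),
    )


def equalize_distance_bins(
    data: BinnedEnsemble, n_bins: int = 5, seed: int = 0
) -> BinnedEnsemble:
    """Split the distance range into ``n_bins`` equal-width bins and
    subsample each (without replacement) to the smallest bin count."""
    rng = np.random.default_rng(seed)
    d = data.distance
    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    groups = [np.flatnonzero(which == b) for b in range(n_bins)]
    sizes = [g.size for g in groups]
    if min(sizes) == 0:
        raise ValueError(f"empty distance bin (counts {sizes})")
    m = min(sizes)
    chosen = np.sort(
        np.concatenate([rng.choice(g, size=m, replace=False) for g in groups])
    )
    return data.subset(chosen)


def shuffle_labels(data, seed: int = 0):
    """Permute the feature/label pairing, preserving the label multiset.

    For a ``BinnedEnsemble`` the (distance, zone, flags) labels are jointly
    permuted against the activity matrix; for an ``EventWindowMatrix`` the
    AW/EW labels are permuted.
    """
    rng = np.random.default_rng(seed)
    if isinstance(data, BinnedEnsemble):
        perm = rng.permutation(data.n_bins)
        return replace(
            data,
            distance=data.distance[perm],
            zone=data.zone[perm],
            flags={k: v[perm] for k, v in data.flags.items()},
        )
    if isinstance(data, EventWindowMatrix):
        perm = rng.permutation(data.n_trials)
        return replace(data, y=data.y[perm])
    raise TypeError(f"cannot shuffle labels of {type(data)!r}")


def spatial_firing_map(
    session: Session,
    unit_id: str,
    px_size: float = 1.0,
    sigma_px: float = 15.0,
    truncate_px: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean of the unit's z-scored 1 kHz activity over visits,
    Gaussian-smoothed (normalized convolution so unvisited pixels do not
    bleed zeros into the average).

    Returns (map, visited mask); unvisited pixels are NaN before smoothing
    and filled by the normalized smoothing where reachable.
    """
    idx = [u.unit_id for u in session.units].index(unit_id)
    unit = session.units[idx]
    z, _ = zscore_unit(spike_density(unit.spike_times, session.duration))

    trace = interpolate_tracking(session.tracking)
    t_ms = (np.arange(z.size) + 0.5) / FS
    x = np.interp(t_ms, trace.timestamps, trace.head_xy[:, 0])
    y = np.interp(t_ms, trace.timestamps, trace.head_xy[:, 1])
    geom = session.geometry
    nx = int(np.ceil(geom.width / px_size))
    ny = int(np.ceil(geom.height / px_size))
    ix = np.clip((x / px_size).astype(int), 0, nx - 1)
    iy = np.clip((y / px_size).astype(int), 0, ny - 1)
    flat = iy * nx + ix
    sums = np.bincount(flat, weights=z, minlength=nx * ny).reshape(ny, nx)
    counts = np.bincount(flat, minlength=nx * ny).reshape(ny, nx)
    visited = counts > 0
    mean_map = np.full((ny, nx), np.nan)
    mean_map[visited] = sums[visited] / counts[visited]

    trunc = truncate_px / sigma_px  # ~1001 px support on the default scale
    num = gaussian_filter(np.where(visited, mean_map, 0.0), sigma_px, truncate=trunc, mode="constant")
    den = gaussian_filter(visited.astype(float), sigma_px, truncate=trunc, mode="constant")
    with np.errstate(invalid="ignore"):
        smoothed = num / den
    return smoothed, visited
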