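"""Population geometry: PCA projection of binned ensemble activity,
zone centroids, within/between-zone distances and centroid-pair
distances, with exclusion of critical event windows.

Distances are computed in the full PCA space by default (where they
coincide with distances in the original unit space up to rotation);
``n_components`` restricts the projection for the 2-D plotted variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .core import EventLog
from .preprocess import BinnedEnsemble

__all__ = [
    "ProjectedEnsemble",
    "project_pca",
    "zone_distance_stats",
    "centroid_pair_distances",
    "exclude_critical_events",
    "representative_subset",
]

ZONES = ("N", "F", "E")


@dataclass
class ProjectedEnsemble:
    scores: np.ndarray                # [n_bins x n_components]
    components: np.ndarray            # loadings [n_components x n_units]
    explained_variance_ratio: np.ndarray
    zone: np.ndarray
    centroids: dict                   # zone -> component-space centroid


def project_pca(data: BinnedEnsemble, n_components: int | None = None) -> ProjectedEnsemble:
    """Standard PCA of the [n_bins x n_units] activity matrix.  Component
    sign is fixed so each component's largest-magnitude loading is
    positive (PCA is otherwise sign-ambiguous)."""
    if n_components is not None and n_components > data.n_units:
        raise ValueError("n_components cannot exceed n_units")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(data.X)
    comps = pca.components_
    flip = np.sign(comps[np.arange(comps.shape[0]), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    scores = scores * flip[None, :]
    centroids = {
        z: scores[data.zone == z].mean(axis=0) for z in ZONES if np.any(data.zone == z)
    }
    return ProjectedEnsemble(
        scores=scores,
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_,
        zone=data.zone.copy(),
        centroids=centroids,
    )


def zone_distance_stats(proj: ProjectedEnsemble) -> dict:
    """Per-bin within-zone distance ||C^z - x|| (to the bin's own zone
    centroid) and between-zone distance (mean distance to the two other
    zone centroids), plus session-level means."""
    missing = [z for z in ZONES if z not in proj.centroids]
    if missing:
        raise ValueError(f"zones missing from projection: {missing}")
    n = proj.scores.shape[0]
    d_within = np.empty(n)
    d_between = np.empty(n)
    for z in ZONES:
        m = proj.zone == z
        if not m.any():
            continue
        own = proj.centroids[z]
        d_within[m] = np.linalg.norm(proj.scores[m] - own, axis=1)
        others = [proj.centroids[o] for o in ZONES if o != z]
        d_between[m] = (
            sum(np.linalg.norm(proj.scores[m] - c, axis=1) for c in others) / 2.0
        )
    return {
        "d_within": d_within,
        "d_between": d_between,
        "mean_within": float(d_within.mean()),
        "mean_between": float(d_between.mean()),
        "mean_within_by_zone": {
            z: float(d_within[proj.zone == z].mean()) for z in ZONES
        },
        "mean_between_by_zone": {
            z: float(d_between[proj.zone == z].mean()) for z in ZONES
        },
    }


def centroid_pair_distances(proj: ProjectedEnsemble) -> dict:
    """Euclidean distances between the three zone centroids."""
    out = {}
    for a, b in (("N", "F"), ("N", "E"), ("F", "E")):
        if a in proj.centroids and b in proj.centroids:
            out[f"{a}-{b}"] = float(
                np.linalg.norm(proj.centroids[a] - proj.centroids[b])
            )
    return out


def exclude_critical_events(
    data: BinnedEnsemble, events: EventLog, pad: float = 1.0
) -> BinnedEnsemble:
    """Remove bins within +/- ``pad`` s of any head-entry or head-withdrawal
    (union over trials; a bin is removed if its center lies in
    [event - pad, event + pad))."""
    crit = np.concatenate(
        [events.times("ezone_entry_time"), events.times("withdrawal_time")]
    )
    crit = crit[np.isfinite(crit)]
    mask = np.zeros(data.n_bins, dtype=bool)
    for e in crit:
        mask |= (data.bin_centers >= e - pad) & (data.bin_centers < e + pad)
    return data.subset(np.flatnonzero(~mask))


def representative_subset(
    proj: ProjectedEnsemble,
    zone: str,
    n_nearest: int = 2000,
    n_plot: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Indices of the plotted representative vectors for one zone: the
    ``n_nearest`` bins closest to the zone centroid, then ``n_plot``
    sampled at random (seeded)."""
    rng = np.random.default_rng(seed)
    m = np.flatnonzero(proj.zone == zone)
    d = np.linalg.norm(proj.scores[m] - proj.centroids[zone], axis=1)
    near = m[np.argsort(d)[: min(n_nearest, m.size)]]
    if near.size <= n_plot:
        return near
    return rng.choice(near, size=n_plot, replace=False)
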