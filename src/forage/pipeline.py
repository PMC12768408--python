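"""End-to-end orchestration: run every analysis stage on one or more
sessions in method order (preprocess -> distance decoding -> population
geometry -> event units -> outcome classification -> importance) and
emit a structured, reproducible report.

Every stage consumes only the session and the seeds recorded in the run
manifest, so a report regenerates bit-identically under a fixed config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import event_units as eu
from .classify import (
    ClassifierConfig,
    class_discrimination_index,
    crossval_classify,
    group_cdi_by_type,
    time_window_sweep,
)
from .core import Session, apply_unit_qc, load_session, session_passes_qc
from .decoder import (
    RegressorConfig,
    crossval_regress,
    fit_error_glm,
    train_null,
    zone_condition_mae,
)
from .importance import all_unit_importances, ablate_top_fraction, importance_correlation
from .popgeom import (
    centroid_pair_distances,
    exclude_critical_events,
    project_pca,
    zone_distance_stats,
)
from .preprocess import build_distance_dataset, build_event_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline", "analyze_session", "compare_conditions"]


@dataclass
class PipelineConfig:
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_pseudo: int = 8
    cluster_min_size: int = 50
    sweep_offsets: tuple[float, ...] = ()        # e.g. (-8, ..., 0); empty = skip
    importance_repeats: int = 5
    ablate_fraction: float = 0.20
    seed: int = 0


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def analyze_session(session: Session, config: PipelineConfig | None = None) -> dict:
    """All per-session stages; returns a JSON-serializable summary."""
    config = config or PipelineConfig()
    report: dict = {"metadata": dict(session.metadata), "n_units": session.n_units}
    timings: dict = {}

    t0 = time.perf_counter()
    data = build_distance_dataset(session)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    res = crossval_regress(data, config.regressor)
    null = train_null(data, config.regressor, seed=config.seed)
    report["distance_decoding"] = {
        "mae": res.mae,
        "shuffled_mae": null.mae,
        "per_zone_mae": res.per_zone_mae,
        "per_flag_mae": res.per_flag_mae,
    }
    timings["distance_decoding"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    proj = project_pca(data)
    stats_all = zone_distance_stats(proj)
    excl = exclude_critical_events(data, session.events)
    proj_excl = project_pca(excl)
    report["population_geometry"] = {
        "centroid_pair_distances": centroid_pair_distances(proj),
        "mean_within": stats_all["mean_within"],
        "mean_between": stats_all["mean_between"],
        "critical_excluded": {
            "centroid_pair_distances": centroid_pair_distances(proj_excl),
            "mean_within": zone_distance_stats(proj_excl)["mean_within"],
            "mean_between": zone_distance_stats(proj_excl)["mean_between"],
        },
    }
    timings["population_geometry"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    entries = session.events.times("ezone_entry_time")
    withdrawals = session.events.times("withdrawal_time")
    he_peths, hw_peths, peth_units = [], [], []
    for u in session.units:
        try:
            he = eu.build_peth(session, u.unit_id, entries, event="head_entry")
            hw = eu.build_peth(session, u.unit_id, withdrawals, event="head_withdrawal")
        except eu.DegenerateBaselineError:
            logger.warning("unit %s: degenerate baseline; excluded from PETHs", u.unit_id)
            continue
        he_peths.append(he)
        hw_peths.append(hw)
        peth_units.append(u.unit_id)
    he_clu = eu.hierarchical_cluster(he_peths, config.n_pseudo, config.cluster_min_size)
    hw_clu = eu.hierarchical_cluster(hw_peths, config.n_pseudo, config.cluster_min_size)
    assignments = eu.assign_combined_types(he_clu, hw_clu, peth_units)
    regions = [
        next(u.region.value for u in session.units if u.unit_id == uid) for uid in peth_units
    ]
    report["event_units"] = {
        "n_responsive_entry": int(sum(eu.is_responsive(p) for p in he_peths)),
        "n_responsive_withdrawal": int(sum(eu.is_responsive(p) for p in hw_peths)),
        "he_cluster_sizes": he_clu.sizes,
        "hw_cluster_sizes": hw_clu.sizes,
        "type_counts": {
            t: sum(a.combined == t for a in assignments) for t in ("Type1", "Type2", "Other")
        },
    }
    try:
        report["event_units"]["regional_type2"] = _jsonable(
            eu.regional_type_proportions(assignments, regions, "Type2")
        )
    except ValueError:
        report["event_units"]["regional_type2"] = None
    timings["event_units"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    event_data = build_event_dataset(session)
    clf_res = crossval_classify(event_data, config.classifier)
    cdi = class_discrimination_index(clf_res)
    report["classification"] = {
        "balanced_accuracy": clf_res.balanced_accuracy,
        "shuffled_balanced_accuracy": clf_res.shuffled_balanced_accuracy,
        "cdi_by_type": group_cdi_by_type(
            cdi, [a for a in assignments if a.unit_id in set(event_data.unit_ids)]
        )
        if len(assignments) == event_data.n_units
        else None,
    }
    if config.sweep_offsets:
        report["classification"]["sweep"] = time_window_sweep(
            session, list(config.sweep_offsets), config.classifier
        )
    timings["classification"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    reg_scores = all_unit_importances(res, data, config.importance_repeats, config.seed)
    clf_scores = all_unit_importances(
        clf_res, event_data, config.importance_repeats, config.seed, config=config.classifier
    )
    report["importance"] = {
        "regressor_scores": reg_scores.tolist(),
        "classifier_scores": clf_scores.tolist(),
        "correlation": importance_correlation(reg_scores, clf_scores),
        "regressor_ablation": _jsonable(
            ablate_top_fraction(
                data, reg_scores, config.ablate_fraction, regressor_config=config.regressor
            )
        ),
        "classifier_ablation": _jsonable(
            ablate_top_fraction(
                event_data, clf_scores, config.ablate_fraction, classifier_config=config.classifier
            )
        ),
    }
    timings["importance"] = time.perf_counter() - t0
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    return _jsonable(report)


def run_full_pipeline(
    sessions: list[Session | str | Path],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage on each QC-passing session; returns (and optionally
    writes) a manifest with per-session reports and pooled summaries."""
    config = config or PipelineConfig()
    manifest: dict = {
        "config": _jsonable(asdict(config)),
        "seed": config.seed,
        "sessions": [],
        "skipped": [],
    }
    reports = []
    for s in sessions:
        session = load_session(s) if not isinstance(s, Session) else s
        session = apply_unit_qc(session)
        ok, reasons = session_passes_qc(session)
        sid = session.metadata.get("session_id", "unknown")
        if not ok:
            logger.warning("session %s fails QC (%s); skipped", sid, reasons)
            manifest["skipped"].append({"session_id": sid, "reasons": reasons})
            continue
        rep = analyze_session(session, config)
        rep["session_id"] = sid
        reports.append(rep)
        manifest["sessions"].append(rep)
    if reports:
        manifest["pooled"] = {
            "mean_mae": float(np.mean([r["distance_decoding"]["mae"] for r in reports])),
            "mean_shuffled_mae": float(
                np.mean([r["distance_decoding"]["shuffled_mae"] for r in reports])
            ),
            "mean_balanced_accuracy": float(
                np.mean([r["classification"]["balanced_accuracy"] for r in reports])
            ),
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(manifest, indent=2))
        lines = [f"forage pipeline report ({len(reports)} sessions)"]
        for r in reports:
            lines.append(
                f"  {r['session_id']}: MAE {r['distance_decoding']['mae']:.2f} cm "
                f"(null {r['distance_decoding']['shuffled_mae']:.2f}), "
                f"AW/EW balanced acc {r['classification']['balanced_accuracy']:.3f}"
            )
        (out / "report.txt").write_text("\n".join(lines) + "\n")
    return manifest


def compare_conditions(session_reports: list[dict]) -> dict:
    """Assemble the session-level error table across conditions and fit
    the decoding-error GLM; also report the plain condition contrast."""
    rows = []
    for r in session_reports:
        rows.append(
            {
                "mae": r["distance_decoding"]["mae"],
                "n_units": r["n_units"],
                "condition": r["metadata"].get("condition", "Lobster"),
                "site": r["metadata"].get("site", "PL"),
            }
        )
    table = pd.DataFrame(rows)
    contrast = table.groupby("condition")["mae"].mean().to_dict()
    result: dict = {"condition_mean_mae": contrast, "n_sessions": len(table)}
    try:
        result["glm"] = fit_error_glm(table)
    except ValueError as err:
        result["glm"] = None
        result["glm_error"] = str(err)
    return result
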