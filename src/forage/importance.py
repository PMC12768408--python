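"""Permutation feature importance for the distance regressor and the
AW/EW classifier, top-fraction ablation with retraining, and the
cross-decoder importance correlation.

A unit's importance is the mean (over seeded repeats) increase in the
decoder's error when that unit's data — and only that unit's — is
permuted across samples: the single 50 ms column for the regressor
(error increase, cm), the whole 40-bin block trial-wise for the
classifier (balanced-accuracy drop).  Out-of-fold structure is reused:
each fold's trained model scores the permuted copies of its own test
rows, so no retraining is involved in the importance score itself.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .classify import ClassificationResult, ClassifierConfig, balanced_accuracy, crossval_classify
from .decoder import DecodingResult, RegressorConfig, crossval_regress, train_null
from .preprocess import BinnedEnsemble, EventWindowMatrix, shuffle_labels

__all__ = [
    "regressor_unit_importance",
    "classifier_unit_importance",
    "permutation_importance",
    "ablate_top_fraction",
    "importance_correlation",
]


def regressor_unit_importance(
    result: DecodingResult,
    data: BinnedEnsemble,
    unit_idx: int,
    n_repeats: int = 10,
    seed: int = 0,
) -> float:
    """MAE increase (cm) when the unit's column is permuted across bins."""
    rng = np.random.default_rng(seed)
    scores = np.empty(n_repeats)
    for r in range(n_repeats):
        Xp = data.X.copy()
        Xp[:, unit_idx] = Xp[rng.permutation(data.n_bins), unit_idx]
        preds = np.empty(data.n_bins)
        for fold, model in enumerate(result.models):
            te = np.flatnonzero(result.fold_of_bin == fold)
            preds[te] = model.predict(Xp[te])
        scores[r] = np.mean(np.abs(preds - result.labels)) - result.mae
    return float(scores.mean())


def classifier_unit_importance(
    result: ClassificationResult,
    data: EventWindowMatrix,
    unit_idx: int,
    config: ClassifierConfig | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> float:
    """Balanced-accuracy drop when the unit's 40-bin block is permuted
    trial-wise.  Refits each fold on the permuted copy is not needed:
    fold models are refit cheaply since NB fitting is closed-form, but
    the fold split is held fixed and only test rows are permuted."""
    config = config or ClassifierConfig()
    rng = np.random.default_rng(seed)
    cols = data.unit_columns(unit_idx)
    y = np.asarray(data.y)
    from sklearn.naive_bayes import BernoulliNB

    Xb = (data.X > config.binarize_threshold).astype(int)
    scores = np.empty(n_repeats)
    for r in range(n_repeats):
        Xp = Xb.copy()
        Xp[:, cols] = Xp[rng.permutation(data.n_trials)][:, cols]
        preds = np.empty(y.size, dtype=y.dtype)
        for fold in np.unique(result.fold_of_trial):
            te = np.flatnonzero(result.fold_of_trial == fold)
            tr = np.flatnonzero(result.fold_of_trial != fold)
            clf = BernoulliNB(alpha=config.alpha, fit_prior=False)
            clf.fit(Xb[tr], y[tr])  # trained on intact data
            preds[te] = clf.predict(Xp[te])
        scores[r] = result.balanced_accuracy - balanced_accuracy(y, preds)
    return float(scores.mean())


def permutation_importance(result, data, unit_idx, n_repeats: int = 10, seed: int = 0, **kw):
    """Dispatch on decoder type: DecodingResult -> error increase (cm),
    ClassificationResult -> balanced-accuracy drop."""
    if isinstance(result, DecodingResult):
        return regressor_unit_importance(result, data, unit_idx, n_repeats, seed)
    if isinstance(result, ClassificationResult):
        return classifier_unit_importance(result, data, unit_idx, n_repeats=n_repeats, seed=seed, **kw)
    raise TypeError(f"no importance rule for {type(result)!r}")


def all_unit_importances(result, data, n_repeats: int = 10, seed: int = 0, **kw) -> np.ndarray:
    n = data.n_units
    return np.array(
        [permutation_importance(result, data, i, n_repeats, seed + i, **kw) for i in range(n)]
    )


def ablate_top_fraction(
    data: BinnedEnsemble | EventWindowMatrix,
    scores: np.ndarray,
    fraction: float = 0.20,
    regressor_config: RegressorConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
    null_seed: int = 0,
) -> dict:
    """Drop the ceil(fraction * n_units) highest-importance units and
    re-run the full cross-validated pipeline; returns the re-trained
    metric and its label-shuffled null."""
    scores = np.asarray(scores, dtype=float)
    n = data.n_units
    n_drop = int(np.ceil(fraction * n))
    drop = np.argsort(scores)[::-1][:n_drop] if n_drop else np.array([], dtype=int)
    reduced = data.drop_units(drop)
    if isinstance(data, BinnedEnsemble):
        if reduced.n_units == 0:
            # nothing left: the best input-free constant predictor
            mu = float(np.mean(data.distance))
            metric = float(np.mean(np.abs(data.distance - mu)))
            return {"metric": metric, "null_metric": metric, "dropped": drop.tolist()}
        res = crossval_regress(reduced, regressor_config)
        null = train_null(reduced, regressor_config, seed=null_seed)
        return {"metric": res.mae, "null_metric": null.mae, "dropped": drop.tolist()}
    if isinstance(data, EventWindowMatrix):
        res = crossval_classify(reduced, classifier_config)
        return {
            "metric": res.balanced_accuracy,
            "null_metric": res.shuffled_balanced_accuracy,
            "dropped": drop.tolist(),
        }
    raise TypeError(f"cannot ablate {type(data)!r}")


def importance_correlation(
    scores_a: np.ndarray, scores_b: np.ndarray, trim: float = 0.01
) -> float:
    """Pearson r between two per-unit importance vectors after excluding
    the most extreme ~``trim`` fraction of units (round(trim/2 * n) from
    each tail of each score's marginal; union removed)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired scores required")
    k = int(round(trim / 2 * a.size))
    out: set[int] = set()
    if k:
        for v in (a, b):
            order = np.argsort(v)
            out.update(order[:k].tolist())
            out.update(order[-k:].tolist())
    keep = np.array([i for i in range(a.size) if i not in out])
    r, _ = stats.pearsonr(a[keep], b[keep])
    return float(r)
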