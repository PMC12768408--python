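"""AW/EW outcome classification with a Bernoulli naive Bayes model,
balanced accuracy, shuffled-label controls, the pre-withdrawal time-window
sweep, and the per-unit class-discrimination (log-odds) index.

Features are the 40 z-scored 50 ms bins per unit of a 2 s
withdrawal-aligned window, binarized at 0 (above/below the unit's
session mean).  The classifier uses Laplace smoothing alpha = 1 and a
uniform class prior, evaluated with stratified five-fold
cross-validation and scored by balanced accuracy (mean of per-class
recalls, robust to AW/EW imbalance).

The class discrimination index of a unit is

    LogOddsRatio = log( P(unit|AW) (1 - P(unit|EW))
                      / ((1 - P(unit|AW)) P(unit|EW)) )

where P(unit|class) joins the fitted per-bin Bernoulli class likelihoods
of the unit's 40 bins (natural logs summed per fold, averaged over the
five folds) and is mapped back into (0, 1) as the per-bin geometric
mean.  Positive values mean the unit's activity profile is better
explained by the AW model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB

from .core import Session
from .event_units import ClusterAssignment
from .preprocess import EventWindowMatrix, build_event_dataset, shuffle_labels

__all__ = [
    "ClassifierConfig",
    "ClassificationResult",
    "balanced_accuracy",
    "crossval_classify",
    "time_window_sweep",
    "class_discrimination_index",
    "group_cdi_by_type",
]

CLASSES = ("AW", "EW")


@dataclass
class ClassifierConfig:
    alpha: float = 1.0
    binarize_threshold: float = 0.0
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class ClassificationResult:
    predictions: np.ndarray            # out-of-fold class labels
    balanced_accuracy: float
    shuffled_balanced_accuracy: float | None
    unit_ids: list[str]
    # per-unit class likelihoods: mean-over-folds joint log-likelihood and
    # its geometric per-bin mapping into (0, 1)
    joint_loglik: dict = field(default_factory=dict)   # class -> array [n_units]
    p_unit: dict = field(default_factory=dict)         # class -> array in (0,1)
    fold_of_trial: np.ndarray | None = None


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("both classes must be present in y_true")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


def _fit_predict_fold(Xb, y, tr, te, config):
    clf = BernoulliNB(alpha=config.alpha, fit_prior=False)  # uniform prior
    clf.fit(Xb[tr], y[tr])
    return clf, clf.predict(Xb[te])


def crossval_classify(
    data: EventWindowMatrix,
    config: ClassifierConfig | None = None,
    with_shuffled: bool = True,
) -> ClassificationResult:
    """Stratified k-fold Bernoulli naive Bayes on binarized event windows;
    out-of-fold predictions are pooled and scored with balanced accuracy.
    A label-shuffled control through the identical pipeline is attached
    unless disabled."""
    config = config or ClassifierConfig()
    y = np.asarray(data.y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < config.k:
        raise ValueError("each class needs at least k trials for stratified folding")
    Xb = (data.X > config.binarize_threshold).astype(int)
    skf = StratifiedKFold(n_splits=config.k, shuffle=True, random_state=config.seed)

    preds = np.empty(y.size, dtype=y.dtype)
    fold_of = np.full(y.size, -1)
    n_units, bpu = data.n_units, data.bins_per_unit
    jll = {c: np.zeros(n_units) for c in CLASSES}
    for fold, (tr, te) in enumerate(skf.split(Xb, y)):
        clf, p = _fit_predict_fold(Xb, y, tr, te, config)
        preds[te] = p
        fold_of[te] = fold
        # per-bin Bernoulli class likelihoods -> per-unit joint log-likelihood
        for ci, c in enumerate(clf.classes_):
            logp = clf.feature_log_prob_[ci].reshape(n_units, bpu)
            jll[str(c)] += logp.sum(axis=1)
    for c in CLASSES:
        jll[c] /= config.k
    p_unit = {c: np.exp(jll[c] / bpu) for c in CLASSES}

    shuffled_ba = None
    if with_shuffled:
        shuffled = crossval_classify(
            shuffle_labels(data, seed=config.seed), config, with_shuffled=False
        )
        shuffled_ba = shuffled.balanced_accuracy
    return ClassificationResult(
        predictions=preds,
        balanced_accuracy=balanced_accuracy(y, preds),
        shuffled_balanced_accuracy=shuffled_ba,
        unit_ids=list(data.unit_ids),
        joint_loglik=jll,
        p_unit=p_unit,
        fold_of_trial=fold_of,
    )


def time_window_sweep(
    session: Session,
    offsets: list[float],
    config: ClassifierConfig | None = None,
) -> list[dict]:
    """Balanced accuracy (original vs shuffled) for 2 s windows ending at
    each ``offset`` (s, relative to head-withdrawal; 0 = window ending at
    the withdrawal)."""
    config = config or ClassifierConfig()
    out = []
    for off in offsets:
        data = build_event_dataset(session, window_offset=off)
        res = crossval_classify(data, config)
        out.append(
            {
                "offset": float(off),
                "balanced_accuracy": res.balanced_accuracy,
                "shuffled_balanced_accuracy": res.shuffled_balanced_accuracy,
                "n_trials": data.n_trials,
            }
        )
    return out


def class_discrimination_index(
    result: ClassificationResult, variant: str = "geometric"
) -> np.ndarray:
    """Per-unit log-odds ratio contrasting the unit's likelihood under the
    AW vs EW class models.  ``variant='geometric'`` (default) maps the
    joint over 40 bins to the per-bin geometric mean so both likelihoods
    lie in (0, 1); ``variant='joint'`` applies the same formula to the
    raw joint likelihoods in log space.  Antisymmetric under class swap;
    positive = activity more likely under AW.
    """
    if variant == "geometric":
        eps = 1e-12
        p_aw = np.clip(result.p_unit["AW"], eps, 1 - eps)
        p_ew = np.clip(result.p_unit["EW"], eps, 1 - eps)
        return np.log(p_aw * (1 - p_ew)) - np.log((1 - p_aw) * p_ew)
    if variant == "joint":
        l_aw = result.joint_loglik["AW"]
        l_ew = result.joint_loglik["EW"]
        # log[p(1-q)] - log[(1-p)q] evaluated stably for log-scale p, q
        return (l_aw + np.log1p(-np.exp(l_ew))) - (np.log1p(-np.exp(l_aw)) + l_ew)
    raise ValueError(f"unknown variant {variant!r}")


def group_cdi_by_type(
    cdi: np.ndarray, assignments: list[ClusterAssignment]
) -> dict:
    """Mean, SEM and two-tailed one-sample t test against 0 of the index
    within Type1 / Type2 / Other groups.  Single-unit groups are reported
    but flagged underpowered."""
    cdi = np.asarray(cdi, dtype=float)
    if cdi.size != len(assignments):
        raise ValueError("one index value per assignment required")
    groups = {"Type1": [], "Type2": [], "Other": []}
    for v, a in zip(cdi, assignments):
        groups[a.combined].append(v)
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals)
        entry: dict = {"n": int(arr.size)}
        if arr.size == 0:
            entry.update(mean=None, sem=None, t=None, p=None)
        else:
            entry["mean"] = float(arr.mean())
            entry["sem"] = float(stats.sem(arr)) if arr.size > 1 else None
            if arr.size > 1 and arr.std() > 0:
                t, p = stats.ttest_1samp(arr, 0.0)
                entry.update(t=float(t), p=float(p))
            else:
                entry.update(t=None, p=None, underpowered=True)
        out[name] = entry
    return out
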