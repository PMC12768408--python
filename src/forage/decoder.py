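"""Feed-forward distance regressor with stratified cross-validation,
label-shuffled null controls, zone/condition error tables, the decoding
error heatmap, and the session-level GLM on decoding error.

The network is a small fully connected regressor (hidden sizes
(256, 128, 64) by default, ReLU, dropout 0.5 after the first two hidden
layers, output layer to a single distance value).  Weights are
initialized from N(0, 0.2); training is plain minibatch SGD on mean
squared error.  Targets are standardized internally for numerical
stability and predictions mapped back to cm.  A ridge-regression
fallback with the same interface is provided for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import griddata
from scipy.ndimage import gaussian_filter
from sklearn.linear_model import Ridge
from sklearn.model_selection import StratifiedKFold

from .preprocess import BinnedEnsemble, shuffle_labels

__all__ = [
    "RegressorConfig",
    "DecodingResult",
    "MLPRegressor",
    "RidgeRegressor",
    "make_model",
    "crossval_regress",
    "train_null",
    "zone_condition_mae",
    "error_heatmap",
    "fit_error_glm",
]


@dataclass
class RegressorConfig:
    hidden: tuple[int, ...] = (256, 128, 64)
    dropout: float = 0.5          # after the first two hidden layers
    init_sd: float = 0.2
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 256
    seed: int = 0
    model: str = "mlp"            # "mlp" | "ridge"
    ridge_alpha: float = 1.0


class MLPRegressor:
    """Minimal numpy MLP: ReLU hidden layers, inverted dropout, MSE + SGD."""

    def __init__(self, config: RegressorConfig, n_inputs: int):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        sizes = [n_inputs, *config.hidden, 1]
        self.W = [
            self.rng.normal(0.0, config.init_sd, size=(a, b))
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(b) for b in sizes[1:]]
        self._y_mean = 0.0
        self._y_sd = 1.0

    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, list]:
        cache = []
        h = X
        n_hidden = len(self.W) - 1
        for i in range(n_hidden):
            z = h @ self.W[i] + self.b[i]
            a = np.maximum(z, 0.0)
            mask = None
            if train and self.cfg.dropout > 0 and i < 2:
                mask = (self.rng.random(a.shape) >= self.cfg.dropout) / (1 - self.cfg.dropout)
                a = a * mask
            cache.append((h, z, mask))
            h = a
        out = (h @ self.W[-1] + self.b[-1]).ravel()
        cache.append((h, None, None))
        return out, cache

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._y_mean = float(y.mean())
        self._y_sd = float(y.std()) or 1.0
        yt = (y - self._y_mean) / self._y_sd
        n = X.shape[0]
        bs = min(self.cfg.batch_size, n)
        for _ in range(self.cfg.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                self._step(X[idx], yt[idx])
        return self

    def _step(self, Xb: np.ndarray, yb: np.ndarray) -> None:
        out, cache = self._forward(Xb, train=True)
        m = Xb.shape[0]
        grad = (2.0 / m) * (out - yb)[:, None]  # d MSE / d out
        # output layer
        h_last = cache[-1][0]
        gW = h_last.T @ grad
        gb = grad.sum(axis=0)
        grad_h = grad @ self.W[-1].T
        self.W[-1] -= self.cfg.lr * gW
        self.b[-1] -= self.cfg.lr * gb
        # hidden layers, reversed
        for i in range(len(self.W) - 2, -1, -1):
            h_in, z, mask = cache[i]
            if mask is not None:
                grad_h = grad_h * mask
            grad_z = grad_h * (z > 0)
            gW = h_in.T @ grad_z
            gb = grad_z.sum(axis=0)
            grad_h = grad_z @ self.W[i].T
            self.W[i] -= self.cfg.lr * gW
            self.b[i] -= self.cfg.lr * gb

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return out * self._y_sd + self._y_mean


class RidgeRegressor:
    """Regularized linear fallback with the MLP's fit/predict interface."""

    def __init__(self, config: RegressorConfig, n_inputs: int):
        self._m = Ridge(alpha=config.ridge_alpha)

    def fit(self, X, y):
        self._m.fit(X, y)
        return self

    def predict(self, X):
        return self._m.predict(X)


def make_model(config: RegressorConfig, n_inputs: int):
    if config.model == "mlp":
        return MLPRegressor(config, n_inputs)
    if config.model == "ridge":
        return RidgeRegressor(config, n_inputs)
    raise ValueError(f"unknown model {config.model!r}")


@dataclass
class DecodingResult:
    predictions: np.ndarray       # out-of-fold, cm
    abs_errors: np.ndarray        # |pred - label|, cm
    mae: float
    fold_of_bin: np.ndarray
    per_zone_mae: dict
    per_flag_mae: dict
    models: list = field(default_factory=list, repr=False)
    labels: np.ndarray | None = None
    shuffled_mae: float | None = None


def crossval_regress(
    data: BinnedEnsemble,
    config: RegressorConfig | None = None,
    k: int = 5,
) -> DecodingResult:
    """Stratified k-fold (by zone) cross-validated regression.  Folds keep
    the three-zone proportions; out-of-fold predictions are concatenated
    and scored with MAE against the paired labels."""
    config = config or RegressorConfig()
    for z in ("N", "F", "E"):
        if np.sum(data.zone == z) < k:
            raise ValueError(f"zone {z!r} has fewer than {k} bins; cannot stratify")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    preds = np.full(data.n_bins, np.nan)
    fold_of = np.full(data.n_bins, -1)
    models = []
    for fold, (tr, te) in enumerate(skf.split(data.X, data.zone)):
        model = make_model(replace(config, seed=config.seed + fold), data.n_units)
        model.fit(data.X[tr], data.distance[tr])
        preds[te] = model.predict(data.X[te])
        fold_of[te] = fold
        models.append(model)
    abs_err = np.abs(preds - data.distance)
    result = DecodingResult(
        predictions=preds,
        abs_errors=abs_err,
        mae=float(abs_err.mean()),
        fold_of_bin=fold_of,
        per_zone_mae={},
        per_flag_mae={},
        models=models,
        labels=data.distance.copy(),
    )
    result.per_zone_mae, result.per_flag_mae = _error_tables(result, data)
    return result


def train_null(
    data: BinnedEnsemble, config: RegressorConfig | None = None, seed: int = 0, k: int = 5
) -> DecodingResult:
    """Identical pipeline on a label-shuffled copy of the dataset."""
    return crossval_regress(shuffle_labels(data, seed=seed), config, k=k)


def _error_tables(result: DecodingResult, data: BinnedEnsemble) -> tuple[dict, dict]:
    per_zone = {}
    for z in ("N", "F", "E"):
        m = data.zone == z
        per_zone[z] = float(result.abs_errors[m].mean()) if m.any() else None
    per_flag = {}
    fzone = data.zone == "F"
    for name in ("outbound", "inbound"):
        m = data.flags.get(name, np.zeros(data.n_bins, bool)) & fzone
        per_flag[name] = float(result.abs_errors[m].mean()) if m.any() else None
    m = data.flags.get("door_closed", np.zeros(data.n_bins, bool))
    per_flag["door_closed"] = float(result.abs_errors[m].mean()) if m.any() else None
    return per_zone, per_flag


def zone_condition_mae(result: DecodingResult, data: BinnedEnsemble) -> pd.DataFrame:
    """Per-zone and per-flag MAE table (outbound/inbound restricted to the
    F zone); empty subsets reported as missing, not zero."""
    per_zone, per_flag = _error_tables(result, data)
    rows = [{"subset": k, "mae": v} for k, v in {**per_zone, **per_flag}.items()]
    return pd.DataFrame(rows)


def error_heatmap(
    result: DecodingResult,
    data: BinnedEnsemble,
    session,
    px_size: float = 1.0,
    sigma_px: float = 15.0,
    n_levels: int = 25,
) -> dict:
    """Decoding-error map: per-pixel mean absolute error at visited pixels,
    scattered interpolation (linear inside the convex hull, nearest
    outside) to unvisited pixels, Gaussian smoothing (sigma 15 px), and
    25 contour levels.  Values in cm."""
    geom = session.geometry
    trace = session.tracking
    centers = data.bin_centers
    pos_idx = np.clip(np.searchsorted(trace.timestamps, centers), 1, trace.timestamps.size - 1)
    left = (centers - trace.timestamps[pos_idx - 1]) < (trace.timestamps[pos_idx] - centers)
    xy = trace.head_xy[pos_idx - left.astype(int)]

    nx = int(np.ceil(geom.width / px_size))
    ny = int(np.ceil(geom.height / px_size))
    ix = np.clip((xy[:, 0] / px_size).astype(int), 0, nx - 1)
    iy = np.clip((xy[:, 1] / px_size).astype(int), 0, ny - 1)
    flat = iy * nx + ix
    ok = np.isfinite(result.abs_errors)
    sums = np.bincount(flat[ok], weights=result.abs_errors[ok], minlength=nx * ny)
    counts = np.bincount(flat[ok], minlength=nx * ny)
    visited = counts.reshape(ny, nx) > 0
    mean_err = np.full((ny, nx), np.nan)
    mean_err[visited] = (sums / np.maximum(counts, 1)).reshape(ny, nx)[visited]

    gy, gx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack([gx[visited], gy[visited]])
    vals = mean_err[visited]
    centered = pts - pts.mean(axis=0)
    if pts.shape[0] >= 3 and np.linalg.matrix_rank(centered, tol=1e-8) == 2:
        grid = griddata(pts, vals, (gx, gy), method="linear")
        nearest = griddata(pts, vals, (gx, gy), method="nearest")
        grid = np.where(np.isnan(grid), nearest, grid)
    else:
        # degenerate (collinear or <3 visited pixels): interpolate along the
        # principal axis of the visit set
        axis = np.linalg.svd(centered, full_matrices=False)[2][0]
        proj = centered @ axis
        order = np.argsort(proj)
        gproj = (np.column_stack([gx.ravel(), gy.ravel()]) - pts.mean(axis=0)) @ axis
        grid = np.interp(gproj, proj[order], vals[order]).reshape(ny, nx)

    smoothed = gaussian_filter(grid, sigma_px, truncate=500.0 / sigma_px, mode="nearest")
    levels = np.linspace(float(smoothed.min()), float(smoothed.max()), n_levels)
    return {
        "mean_error": mean_err,
        "interpolated": grid,
        "smoothed": smoothed,
        "visited": visited,
        "contour_levels": levels,
        "px_size": px_size,
    }


def fit_error_glm(table: pd.DataFrame, response: str = "mae") -> dict:
    """Session-level linear model of decoding error on ensemble size,
    task condition and recording site:

        error = b0 + b1 * n_units + b2 * condition + b3 * site

    with dummy codes condition (0 = Lobster, 1 = Control) and site
    (0 = PL, 1 = IL).  Ordinary least squares via statsmodels.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 sessions to fit the error GLM")
    cond = table["condition"]
    if cond.dtype == object:
        cond = cond.map({"Lobster": 0, "Control": 1})
    site = table["site"]
    if site.dtype == object:
        site = site.map({"PL": 0, "IL": 1})
    cols = {
        "n_units": table["n_units"].astype(float).to_numpy(),
        "condition": cond.astype(float).to_numpy(),
        "site": site.astype(float).to_numpy(),
    }
    # all-zero predictors carry no information and collapse to the intercept;
    # constant *nonzero* predictors are collinear with it and refuse to fit
    active = {}
    for name, col in cols.items():
        if np.all(col == 0):
            continue
        if np.ptp(col) == 0:
            raise ValueError(f"predictor {name!r} is constant: rank-deficient design")
        active[name] = col
    Xd = sm.add_constant(
        np.column_stack(list(active.values())) if active else np.empty((len(table), 0)),
        has_constant="add",
    )
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("collinear predictors: design matrix is rank deficient")
    fit = sm.OLS(table[response].astype(float).to_numpy(), Xd).fit()
    names = ["intercept", *active.keys()]
    params = dict(zip(names, fit.params))
    for name in cols:
        params.setdefault(name, 0.0)
    return {
        "params": params,
        "bse": dict(zip(names, fit.bse)),
        "tvalues": dict(zip(names, fit.tvalues)),
        "pvalues": dict(zip(names, fit.pvalues)),
        "rsquared": float(fit.rsquared),
        "fvalue": float(fit.fvalue),
        "f_pvalue": float(fit.f_pvalue),
    }
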