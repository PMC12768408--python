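import numpy as np
import pandas as pd
import pytest

from forage import RegressorConfig, crossval_regress, fit_error_glm, train_null, zone_condition_mae
from forage.decoder import DecodingResult, MLPRegressor, error_heatmap
from forage.preprocess import BinnedEnsemble

RIDGE = RegressorConfig(model="ridge")
SMALL_MLP = RegressorConfig(hidden=(64, 32), epochs=30, lr=3e-3, seed=0)


class TestCrossval:
    def test_out_of_fold_coverage(self, tuned_dataset):
        res = crossval_regress(tuned_dataset, RIDGE)
        assert np.all(res.fold_of_bin >= 0)
        assert np.isfinite(res.predictions).all()
        counts = np.bincount(res.fold_of_bin)
        assert counts.size == 5 and counts.sum() == tuned_dataset.n_bins

    def test_folds_stratified_by_zone(self, tuned_dataset):
        res = crossval_regress(tuned_dataset, RIDGE)
        overall = np.mean(tuned_dataset.zone == "E")
        for f in range(5):
            m = res.fold_of_bin == f
            assert np.mean(tuned_dataset.zone[m] == "E") == pytest.approx(overall, abs=0.01)

    def test_signal_beats_shuffled_null(self, tuned_dataset):
        res = crossval_regress(tuned_dataset, RIDGE)
        null = train_null(tuned_dataset, RIDGE, seed=9)
        assert res.mae < null.mae

    def test_too_small_zone_raises(self, tuned_dataset):
        small = tuned_dataset.subset(np.arange(8))
        with pytest.raises(ValueError, match="stratify"):
            crossval_regress(small, RIDGE)

    def test_shuffled_null_matches_label_mad(self, tuned_dataset):
        """An uninformative MSE-trained predictor converges to the label
        mean, so its MAE approaches the label distribution's mean absolute
        deviation."""
        null = train_null(tuned_dataset, SMALL_MLP, seed=3)
        mad = np.mean(np.abs(tuned_dataset.distance - tuned_dataset.distance.mean()))
        assert null.mae == pytest.approx(mad, rel=0.15)

    def test_untrained_network_is_null_level(self, tuned_dataset):
        cfg = RegressorConfig(hidden=(64, 32), epochs=0, seed=0)
        res = crossval_regress(tuned_dataset, cfg)
        mad = np.mean(np.abs(tuned_dataset.distance - tuned_dataset.distance.mean()))
        # init-only network predicts ~the target mean (standardized head near 0)
        assert res.mae == pytest.approx(mad, rel=0.25)

    def test_mlp_deterministic_under_seed(self, tuned_dataset):
        cfg = RegressorConfig(hidden=(32,), epochs=3, seed=7)
        r1 = crossval_regress(tuned_dataset, cfg)
        r2 = crossval_regress(tuned_dataset, cfg)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)


class TestMLP:
    def test_init_distribution(self):
        cfg = RegressorConfig(hidden=(256, 128), init_sd=0.2, seed=0)
        m = MLPRegressor(cfg, n_inputs=50)
        w = np.concatenate([wi.ravel() for wi in m.W])
        assert abs(w.mean()) < 0.01 and abs(w.std() - 0.2) < 0.01

    def test_learns_linear_map(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2000, 4))
        y = X @ [3.0, -2.0, 1.0, 0.5] + 10
        cfg = RegressorConfig(hidden=(32, 16), dropout=0.0, epochs=60, lr=1e-2, seed=1)
        m = MLPRegressor(cfg, 4).fit(X, y)
        mae = np.mean(np.abs(m.predict(X) - y))
        assert mae < 0.5 * np.mean(np.abs(y - y.mean()))


def _toy_result_and_data():
    zones = np.array(["N", "N", "F", "F", "E", "E"])
    errors = np.array([2.0, 4.0, 1.0, 3.0, 5.0, 7.0])
    data = BinnedEnsemble(
        X=np.zeros((6, 1)),
        unit_ids=["u"],
        bin_centers=np.arange(6) * 0.05,
        distance=np.zeros(6),
        zone=zones,
        flags={
            "outbound": np.array([0, 0, 1, 0, 0, 0], bool),
            "inbound": np.array([0, 0, 0, 1, 0, 0], bool),
            "door_closed": np.zeros(6, bool),
        },
    )
    res = DecodingResult(
        predictions=errors,
        abs_errors=errors,
        mae=float(errors.mean()),
        fold_of_bin=np.zeros(6, int),
        per_zone_mae={},
        per_flag_mae={},
        labels=np.zeros(6),
    )
    return res, data


class TestZoneTable:
    def test_exact_means_and_missing_subsets(self):
        res, data = _toy_result_and_data()
        table = zone_condition_mae(res, data).set_index("subset")["mae"]
        assert table["N"] == 3.0 and table["F"] == 2.0 and table["E"] == 6.0
        assert table["outbound"] == 1.0 and table["inbound"] == 3.0
        assert table["door_closed"] is None or np.isnan(table["door_closed"])

    def test_uniform_errors_give_uniform_zone_mae(self):
        res, data = _toy_result_and_data()
        res.abs_errors = np.full(6, 2.5)
        table = zone_condition_mae(res, data).set_index("subset")["mae"]
        assert table["N"] == table["F"] == table["E"] == 2.5


class TestHeatmap:
    def _session_line(self, errors, xs):
        """Fake straight-line session along the arena mid-height."""
        from types import SimpleNamespace

        from forage.core import ArenaGeometry, TrackingTrace

        t = np.arange(len(xs)) * 0.05 + 0.025
        trace = TrackingTrace(t, np.column_stack([xs, np.full(len(xs), 24.0)]), 20.0)
        data = BinnedEnsemble(
            X=np.zeros((len(xs), 1)),
            unit_ids=["u"],
            bin_centers=t,
            distance=np.zeros(len(xs)),
            zone=np.array(["F"] * len(xs)),
        )
        res = DecodingResult(
            predictions=np.zeros(len(xs)),
            abs_errors=np.asarray(errors, float),
            mae=float(np.mean(errors)),
            fold_of_bin=np.zeros(len(xs), int),
            per_zone_mae={},
            per_flag_mae={},
            labels=np.zeros(len(xs)),
        )
        session = SimpleNamespace(geometry=ArenaGeometry(), tracking=trace)
        return res, data, session

    def test_linear_interpolation_midpoint(self):
        res, data, session = self._session_line([0.0, 10.0], xs=[30.0, 50.0])
        hm = error_heatmap(res, data, session, sigma_px=1.0)
        assert hm["interpolated"][24, 40] == pytest.approx(5.0, abs=1e-6)

    def test_uniform_field_stays_flat(self):
        res, data, session = self._session_line([4.0] * 10, xs=np.linspace(25, 55, 10))
        hm = error_heatmap(res, data, session)
        np.testing.assert_allclose(hm["smoothed"], 4.0, atol=1e-6)
        assert hm["contour_levels"].size == 25


class TestErrorGLM:
    def _table(self, beta, n=40, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        nu = rng.integers(10, 31, size=n)
        cond = rng.integers(0, 2, size=n)
        site = rng.integers(0, 2, size=n)
        mae = beta[0] + beta[1] * nu + beta[2] * cond + beta[3] * site
        mae = mae + rng.normal(0, noise, size=n)
        return pd.DataFrame({"mae": mae, "n_units": nu, "condition": cond, "site": site})

    def test_noiseless_exact_recovery(self):
        beta = (20.0, -0.3, 2.5, -1.0)
        fit = fit_error_glm(self._table(beta))
        got = [fit["params"][k] for k in ("intercept", "n_units", "condition", "site")]
        np.testing.assert_allclose(got, beta, atol=1e-8)
        assert fit["rsquared"] == pytest.approx(1.0)

    def test_noise_shrinks_with_n(self):
        beta = (20.0, -0.3, 2.5, -1.0)
        rmse = []
        for n in (20, 400):
            fit = fit_error_glm(self._table(beta, n=n, noise=2.0, seed=1))
            got = np.array([fit["params"][k] for k in ("intercept", "n_units", "condition", "site")])
            rmse.append(np.sqrt(np.mean((got - beta) ** 2)))
        assert rmse[1] < rmse[0]

    def test_constant_condition_raises(self):
        t = self._table((20.0, -0.3, 0.0, 0.0))
        t["condition"] = 1
        with pytest.raises(ValueError, match="rank"):
            fit_error_glm(t)

    def test_all_zero_predictors_collapse_to_intercept(self):
        t = pd.DataFrame(
            {"mae": [3.0, 5.0, 7.0, 9.0], "n_units": 0, "condition": 0, "site": 0}
        )
        fit = fit_error_glm(t)
        assert fit["params"]["intercept"] == pytest.approx(6.0)
        assert fit["params"]["condition"] == 0.0
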