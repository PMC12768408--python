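import numpy as np
import pytest

from forage import build_event_dataset, equalize_distance_bins, shuffle_labels, spike_density
from forage.preprocess import (
    BinnedEnsemble,
    DegenerateUnitError,
    bin_50ms,
    gaussian_kernel,
    spatial_firing_map,
    zscore_unit,
)


def direct_convolution_oracle(spike_times, duration, sd_ms=100.0, length_ms=1000.0):
    """Brute force: add one kernel copy centered at each spike sample."""
    n = int(round(duration * 1000))
    k = gaussian_kernel(sd_ms, length_ms)
    half = (k.size - 1) // 2
    out = np.zeros(n)
    for t in spike_times:
        c = min(int(t * 1000), n - 1)
        for j, kv in enumerate(k):
            idx = c + j - half
            if 0 <= idx < n:
                out[idx] += kv
    return out


class TestSpikeDensity:
    def test_matches_direct_convolution(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 5.0, size=40))
        got = spike_density(spikes, 5.0)
        want = direct_convolution_oracle(spikes, 5.0)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_no_spikes_all_zero(self):
        assert not spike_density(np.array([]), 2.0).any()

    def test_single_spike_is_centered_kernel(self):
        out = spike_density(np.array([2.5]), 5.0)
        k = gaussian_kernel()
        c = int(2.5 * 1000)
        np.testing.assert_allclose(out[c - 500 : c + 501], k, atol=1e-12)

    def test_superposition_of_two_spikes(self):
        a = spike_density(np.array([2.0]), 5.0)
        b = spike_density(np.array([2.01]), 5.0)
        both = spike_density(np.array([2.0, 2.01]), 5.0)
        np.testing.assert_allclose(both, a + b, atol=1e-9)

    def test_mass_preserves_spike_count(self):
        spikes = np.linspace(1.0, 9.0, 25)  # interior: no edge loss
        assert spike_density(spikes, 10.0).sum() == pytest.approx(25.0, rel=1e-9)

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            spike_density(np.array([0.1]), 0.0)


class TestNormalizeAndBin:
    def test_zscore_moments(self):
        rng = np.random.default_rng(1)
        z, (m, s) = zscore_unit(rng.gamma(2.0, 1.0, size=5000))
        assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9
        assert s > 0

    def test_zero_variance_errors(self):
        with pytest.raises(DegenerateUnitError):
            zscore_unit(np.zeros(100))

    def test_twenty_bins_per_second(self):
        assert bin_50ms(np.ones(1000)).size == 20

    def test_constant_and_ramp(self):
        np.testing.assert_allclose(bin_50ms(np.full(500, 3.7)), np.full(10, 3.7))
        ramp = np.arange(1000, dtype=float)
        # bin k averages samples [50k, 50k+50): mean = 50k + 24.5
        np.testing.assert_allclose(bin_50ms(ramp), 24.5 + 50 * np.arange(20))


class TestDistanceDataset:
    def test_shape_and_row_bound(self, tuned_session, tuned_dataset):
        session, _ = tuned_session
        assert tuned_dataset.n_units == session.n_units
        assert tuned_dataset.n_bins <= int(session.duration * 20)

    def test_labels_match_geometry(self, tuned_session, tuned_dataset):
        session, _ = tuned_session
        assert np.all(tuned_dataset.distance >= 0)
        assert set(np.unique(tuned_dataset.zone)) <= {"N", "F", "E"}
        # door_closed bins lie between a gate close and the next gate open
        gc = session.events.times("gate_close_time")
        flag = tuned_dataset.flags["door_closed"]
        assert flag.any()
        centers = tuned_dataset.bin_centers[flag]
        go = session.events.times("gate_open_time")
        for c in centers[:: max(1, centers.size // 50)]:
            i = np.searchsorted(gc, c) - 1
            nxt = go[i + 1] if i + 1 < go.size else session.duration
            assert gc[i] <= c < nxt


class TestEventDataset:
    def test_forty_bins_per_unit(self, event_session):
        session, _ = event_session
        data = build_event_dataset(session)
        assert data.X.shape == (session.events.n_trials, 40 * session.n_units)
        assert set(np.unique(data.y)) == {"AW", "EW"}

    def test_window_exiting_recording_drops_trial(self, event_session):
        session, _ = event_session
        first_withdrawal = session.events.times("withdrawal_time")[0]
        offset = -(first_withdrawal - 1.0)  # pushes trial 0's window before t=0
        with pytest.warns(UserWarning, match="dropped"):
            data = build_event_dataset(session, window_offset=offset)
        assert 0 not in data.trial_index

    def test_rows_invariant_to_unit_order(self, event_session):
        from dataclasses import replace

        session, _ = event_session
        a = build_event_dataset(session)
        perm = [session.n_units - 1 - i for i in range(session.n_units)]
        reordered = replace(session, units=[session.units[i] for i in perm])
        b = build_event_dataset(reordered)
        for new_pos, old_pos in enumerate(perm):
            np.testing.assert_allclose(
                b.X[:, b.unit_columns(new_pos)], a.X[:, a.unit_columns(old_pos)], atol=1e-12
            )


def _toy_ensemble(distances):
    n = len(distances)
    return BinnedEnsemble(
        X=np.zeros((n, 2)),
        unit_ids=["a", "b"],
        bin_centers=np.arange(n) * 0.05,
        distance=np.asarray(distances, dtype=float),
        zone=np.array(["F"] * n),
        flags={"door_closed": np.zeros(n, bool)},
    )


class TestEqualizeAndShuffle:
    def test_min_count_rule(self):
        d = np.concatenate(
            [np.full(100, 5.0), np.full(80, 15.0), np.full(60, 25.0), np.full(40, 35.0), np.full(20, 45.0)]
        )
        out = equalize_distance_bins(_toy_ensemble(d), n_bins=5, seed=0)
        assert out.n_bins == 100
        vals, counts = np.unique(out.distance, return_counts=True)
        assert np.all(counts == 20)

    def test_empty_bin_errors(self):
        d = np.concatenate([np.full(10, 0.0), np.full(10, 100.0)])
        with pytest.raises(ValueError, match="empty"):
            equalize_distance_bins(_toy_ensemble(d), n_bins=5, seed=0)

    def test_shuffle_preserves_multiset_and_is_seeded(self):
        data = _toy_ensemble(np.arange(50, dtype=float))
        s1 = shuffle_labels(data, seed=5)
        s2 = shuffle_labels(data, seed=5)
        assert sorted(s1.distance) == sorted(data.distance.tolist())
        assert not np.array_equal(s1.distance, data.distance)
        np.testing.assert_array_equal(s1.distance, s2.distance)
        np.testing.assert_array_equal(s1.X, data.X)  # features untouched


def test_spatial_map_peaks_near_preferred_ring(tuned_session):
    session, gt = tuned_session
    tuned = [u for u in gt.units if u["archetype"] == "distance_tuned"]
    u = tuned[0]
    smap, visited = spatial_firing_map(session, u["unit_id"])
    masked = np.where(np.isfinite(smap), smap, -np.inf)
    iy, ix = np.unravel_index(np.argmax(masked), smap.shape)
    d_peak = session.geometry.distance_to_goal(np.array([ix + 0.5, iy + 0.5]))
    assert abs(d_peak - u["preferred_distance"]) <= 15.0  # one smoothing sigma
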