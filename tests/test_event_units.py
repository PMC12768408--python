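import numpy as np
import pytest

from forage import (
    ArenaGeometry,
    assign_combined_types,
    build_peth,
    detect_run_and_stop,
    hierarchical_cluster,
    is_responsive,
    regional_type_proportions,
)
from forage.core import TrackingTrace
from forage.event_units import PETH, ClusterAssignment, ClusterResult

from conftest import two_template_population


def _peth(z):
    return PETH("u", "head_entry", np.asarray(z, float), 0.0, 1.0, 10)


class TestResponsiveness:
    @pytest.mark.parametrize(
        "peak,expected", [(3.5, True), (-3.5, True), (2.9, False), (0.0, False)]
    )
    def test_three_sigma_criterion(self, peak, expected):
        z = np.zeros(80)
        z[40] = peak
        assert is_responsive(_peth(z)) is expected

    def test_homogeneous_unit_not_responsive(self, tuned_session):
        session, gt = tuned_session
        noise_ids = [u["unit_id"] for u in gt.units if u["archetype"] == "noise"]
        entries = session.events.times("ezone_entry_time")
        p = build_peth(session, noise_ids[0], entries)
        assert abs(p.z.mean()) < 1.0

    def test_planted_type2_modulation_at_withdrawal(self, event_session):
        session, gt = event_session
        t2 = [u["unit_id"] for u in gt.units if u["archetype"] == "type2_like"]
        withdrawals = session.events.times("withdrawal_time")
        p = build_peth(session, t2[0], withdrawals, event="head_withdrawal")
        pre = p.z[30:40].mean()   # just before the withdrawal
        post = p.z[60:].mean()    # well after
        assert pre > post
        assert is_responsive(p)

    def test_peth_has_80_bins(self, event_session):
        session, _ = event_session
        p = build_peth(session, session.units[0].unit_id, session.events.times("ezone_entry_time"))
        assert p.z.size == 80


class TestRunStop:
    def _trace(self, segments, fs=30.0, y=40.0, x0=25.0):
        """segments: list of (speed cm/s, duration s) along +x."""
        xs, t, x = [], [], x0
        clock = 0.0
        for speed, dur in segments:
            n = int(round(dur * fs))
            for _ in range(n):
                xs.append(x)
                t.append(clock)
                x += speed / fs
                clock += 1.0 / fs
        pos = np.column_stack([xs, np.full(len(xs), y)])
        return TrackingTrace(np.asarray(t), pos, fs)

    def test_run_then_stop_one_event(self):
        trace = self._trace([(10.0, 3.0), (0.0, 2.0)])
        ev = detect_run_and_stop(trace, ArenaGeometry())
        assert ev.size == 1
        assert 2.5 < ev[0] < 3.5  # near the transition at t = 3 s

    def test_short_run_no_event(self):
        trace = self._trace([(10.0, 1.5), (0.0, 2.0)])
        assert detect_run_and_stop(trace, ArenaGeometry()).size == 0

    def test_short_stop_no_event(self):
        trace = self._trace([(10.0, 3.0), (0.0, 0.5), (10.0, 3.0)])
        assert detect_run_and_stop(trace, ArenaGeometry()).size == 0

    def test_transition_inside_ezone_excluded(self):
        # path along mid-height ends at x=75 (< 25 cm from the E center)
        trace = self._trace([(10.0, 3.0), (0.0, 2.0)], y=24.0, x0=45.0)
        assert detect_run_and_stop(trace, ArenaGeometry()).size == 0

    def test_resampling_invariance(self):
        e30 = detect_run_and_stop(self._trace([(10.0, 3.0), (0.0, 2.0)], fs=30.0), ArenaGeometry())
        e10 = detect_run_and_stop(self._trace([(10.0, 3.0), (0.0, 2.0)], fs=10.0), ArenaGeometry())
        assert e30.size == e10.size == 1
        assert abs(e30[0] - e10[0]) <= 0.2


class TestClustering:
    def test_no_merges_when_n_equals_pseudo(self):
        rng = np.random.default_rng(0)
        V = rng.normal(size=(8, 80))
        res = hierarchical_cluster(V, n_pseudo=8, min_size=50)
        assert res.n_merges == 0
        assert sorted(res.sizes.values()) == [1] * 8
        assert not any(res.valid.values())  # all below min_size: artifacts

    def test_exact_tie_merges_smallest_pair(self):
        base = np.sin(np.linspace(0, 3, 80))
        V = np.vstack([base, base, base])
        res = hierarchical_cluster(V, n_pseudo=2, min_size=1)
        # identical vectors: first merge must be (0, 1)
        assert res.labels[0] == res.labels[1] != res.labels[2]

    def test_planted_two_templates_recovered(self):
        rng = np.random.default_rng(0)
        V, truth = two_template_population(300, noise_sd=0.5, rng=rng)
        res = hierarchical_cluster(V, n_pseudo=8, min_size=50)
        assert res.n_merges == 300 - 8
        assert sum(res.sizes.values()) == 300
        valid = [c for c, ok in res.valid.items() if ok]
        assert len(valid) == 2
        # best label alignment against ground truth
        m1 = res.labels == 1
        agree = max(np.mean(m1 == (truth == 0)), np.mean(m1 == (truth == 1)))
        assert agree >= 0.95

    def test_permutation_invariant_partition(self):
        rng = np.random.default_rng(3)
        V, _ = two_template_population(60, noise_sd=0.3, rng=rng)
        perm = rng.permutation(60)
        a = hierarchical_cluster(V, n_pseudo=4, min_size=10)
        b = hierarchical_cluster(V[perm], n_pseudo=4, min_size=10)
        # same partition up to relabeling: co-membership matrices match
        co_a = a.labels[:, None] == a.labels[None, :]
        bl = np.empty(60, int)
        bl[perm] = b.labels
        co_b = bl[:, None] == bl[None, :]
        np.testing.assert_array_equal(co_a, co_b)

    def test_constant_vector_excluded(self):
        rng = np.random.default_rng(4)
        V = rng.normal(size=(10, 80))
        V[3] = 2.0
        res = hierarchical_cluster(V, n_pseudo=4, min_size=1)
        assert res.excluded == [3]
        assert res.labels[3] == 0


def _cr(labels, valid):
    sizes = {c: int(np.sum(np.asarray(labels) == c)) for c in set(labels) if c > 0}
    return ClusterResult(
        labels=np.asarray(labels),
        sizes=sizes,
        valid={c: valid.get(c, True) for c in sizes},
        templates={},
        n_merges=0,
        excluded=[],
    )


class TestCombinedTypes:
    def test_intersection_rule(self):
        he = _cr([1, 2, 2, 1, 3], valid={1: True, 2: True, 3: False})
        hw = _cr([1, 2, 3, 2, 1], valid={1: True, 2: True, 3: True})
        combined = [a.combined for a in assign_combined_types(he, hw)]
        assert combined == ["Type1", "Type2", "Other", "Other", "Other"]

    def test_artifact_cluster_is_other(self):
        he = _cr([1, 1], valid={1: False})
        hw = _cr([1, 1], valid={1: True})
        assert all(a.combined == "Other" for a in assign_combined_types(he, hw))


class TestRegionalProportions:
    @staticmethod
    def _chi2_brute(table):
        table = np.asarray(table, float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        exp = row * col / table.sum()
        return float(((table - exp) ** 2 / exp).sum())

    def _assignments(self, table):
        assignments, regions = [], []
        for r, region in enumerate(("PL", "IL")):
            for c, combined in enumerate(("Type2", "Other")):
                for _ in range(table[r][c]):
                    assignments.append(ClusterAssignment("u", 1, 1, combined))
                    regions.append(region)
        return assignments, regions

    @pytest.mark.parametrize("table", [[[10, 10], [10, 10]], [[30, 10], [10, 30]], [[25, 5], [12, 40]]])
    def test_matches_brute_force_formula(self, table):
        a, r = self._assignments(table)
        out = regional_type_proportions(a, r)
        assert out["chi2"] == pytest.approx(self._chi2_brute(table), abs=1e-9)
        assert out["dof"] == 1
        np.testing.assert_array_equal(out["table"], table)

    def test_independent_table_zero(self):
        a, r = self._assignments([[10, 10], [10, 10]])
        assert regional_type_proportions(a, r)["chi2"] == 0.0

    def test_empty_region_raises(self):
        a, r = self._assignments([[5, 5], [0, 0]])
        with pytest.raises(ValueError, match="region"):
            regional_type_proportions(a, r)
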