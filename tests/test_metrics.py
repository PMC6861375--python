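"""Raster metrics: rates, phase coherence, bursts, similarity, NS."""

import numpy as np
import pytest

import ratephase as rp
from ratephase.metrics import (burst_order_similarity, detect_bursts,
                               feature_similarity, firing_rates, mpc_summary,
                               network_similarity_score, pairwise_phase)
from ratephase.synth import RasterSpec, locked_raster, poisson_raster


def _regular(rate, duration, lag=0.0):
    return np.arange(lag, duration, 1000.0 / rate)


def _raster(trains, duration, n_inh=0):
    labels = np.ones(len(trains), dtype=bool)
    if n_inh:
        labels[-n_inh:] = False
    return rp.SpikeRaster(spikes=trains, ei_labels=labels, duration=duration)


class TestFiringRates:
    def test_counts_over_window(self):
        r = _raster([_regular(10.0, 5000.0)], 5000.0)
        fv = firing_rates(r)
        assert fv.rates[0] == pytest.approx(10.0)

    def test_identical_rates_have_zero_cov(self):
        r = _raster([_regular(10.0, 1000.0, lag) for lag in (0.0, 3.0, 7.0)],
                    1000.0)
        assert firing_rates(r).cov == pytest.approx(0.0)

    def test_cov_hand_value(self):
        # rates 5, 10, 15 Hz -> population std / mean = 0.40824829
        r = _raster([_regular(x, 1000.0) for x in (5.0, 10.0, 15.0)], 1000.0)
        assert firing_rates(r).cov == pytest.approx(0.408248290463863)

    def test_silent_raster_marks_cov_undefined(self):
        r = _raster([[], []], 1000.0)
        assert np.isnan(firing_rates(r).cov)


class TestPairwisePhase:
    def test_identical_trains_are_perfectly_coherent_at_zero_phase(self):
        t = _regular(20.0, 3000.0)
        r = _raster([t, t.copy()], 3000.0)
        rel = pairwise_phase(r, 0, 1)
        assert rel.coherence == pytest.approx(1.0, abs=1e-12)
        assert rel.mean_phase == pytest.approx(0.0, abs=1e-12)

    def test_half_period_lag_gives_phase_pi(self):
        p = 100.0
        r = _raster([_regular(10.0, 5000.0, lag=p / 2), _regular(10.0, 5000.0)],
                    5000.0)
        rel = pairwise_phase(r, 0, 1)
        assert rel.coherence == pytest.approx(1.0, abs=1e-12)
        assert rel.mean_phase == pytest.approx(np.pi, abs=1e-9)

    def test_independent_poisson_trains_decohere(self):
        r = poisson_raster(RasterSpec(n_neurons=2, rates=20.0, duration=200_000.0,
                                      seed=3))
        rel = pairwise_phase(r, 0, 1)
        assert rel.coherence < 3.0 / np.sqrt(rel.n_samples)

    def test_sparse_pair_is_excluded(self):
        r = _raster([_regular(2.0, 5000.0), _regular(10.0, 5000.0)], 5000.0)
        assert pairwise_phase(r, 0, 1) is None  # 10 spikes < 30

    def test_asymmetry_of_the_measure(self):
        a = np.sort(np.concatenate([_regular(10.0, 20_000.0),
                                    _regular(10.0, 20_000.0, lag=13.0)]))
        b = _regular(10.0, 20_000.0, lag=50.0)
        r = _raster([a, b], 20_000.0)
        assert pairwise_phase(r, 0, 1).coherence != pytest.approx(
            pairwise_phase(r, 1, 0).coherence)


class TestMPCSummary:
    def test_synchronous_raster_has_unit_mpc(self):
        r = locked_raster(RasterSpec(n_neurons=10, rates=10.0, period=100.0,
                                     lags=np.zeros(10), duration=5000.0,
                                     n_inhibitory=2, seed=0))
        mp = mpc_summary(r)
        assert mp.network_mpc == pytest.approx(1.0, abs=1e-12)

    def test_poisson_raster_has_low_mpc(self):
        r = poisson_raster(RasterSpec(n_neurons=10, rates=15.0,
                                      duration=60_000.0, n_inhibitory=2, seed=1))
        assert mpc_summary(r).network_mpc < 0.1

    def test_global_time_translation_invariance(self):
        spec = RasterSpec(n_neurons=8, rates=10.0, period=100.0,
                          lags=np.linspace(0, 60, 8), jitter=2.0,
                          duration=5000.0, n_inhibitory=2, seed=5)
        r = locked_raster(spec)
        shifted = rp.SpikeRaster(spikes=[s + 500.0 for s in r.spikes],
                                 ei_labels=r.ei_labels, duration=6000.0)
        a = mpc_summary(r)
        b = mpc_summary(shifted)
        assert b.network_mpc == pytest.approx(a.network_mpc, abs=1e-12)

    def test_reference_fallback_warns_and_uses_next_inhibitory(self):
        trains = [_regular(10.0, 5000.0, lag=i) for i in range(4)]
        trains.append(np.array([100.0]))          # sparse inhibitory neuron
        trains.append(_regular(10.0, 5000.0, 2.5))  # qualifying inhibitory
        r = _raster(trains, 5000.0, n_inh=2)
        with pytest.warns(UserWarning):
            mp = mpc_summary(r, reference=4)
        assert mp.reference == 5


class TestBursts:
    def test_empty_raster_has_no_bursts(self):
        r = _raster([[] for _ in range(20)], 1000.0)
        assert detect_bursts(r).intervals.shape == (0, 2)

    def test_single_population_event_is_one_padded_burst(self):
        r = _raster([[100.0 + 0.01 * i] for i in range(50)], 300.0)
        b = detect_bursts(r)
        assert len(b.orders) == 1
        lo, hi = b.intervals[0]
        assert lo < 100.0 < hi
        # threshold crossing ~1.5 ms around the event plus the 10 ms pad
        assert lo == pytest.approx(100.0 - 11.5, abs=0.5)
        assert hi == pytest.approx(100.5 + 11.5, abs=0.5)
        assert b.orders[0].size == 50

    def test_two_events_hundred_ms_apart_stay_separate(self):
        trains = [[100.0 + 0.01 * i, 200.0 + 0.01 * i] for i in range(50)]
        b = detect_bursts(_raster(trains, 400.0))
        assert len(b.orders) == 2
        assert b.intervals[0][1] < b.intervals[1][0]

    def test_nearby_events_merge_after_padding(self):
        trains = [[100.0 + 0.01 * i, 115.0 + 0.01 * i] for i in range(50)]
        b = detect_bursts(_raster(trains, 400.0))
        assert len(b.orders) == 1

    def test_invariance_to_neuron_relabeling(self):
        rng = np.random.default_rng(0)
        trains = [np.sort(rng.uniform(95.0, 105.0, 3)) for _ in range(40)]
        r1 = _raster(trains, 300.0)
        perm = rng.permutation(40)
        r2 = _raster([trains[p] for p in perm], 300.0)
        b1, b2 = detect_bursts(r1), detect_bursts(r2)
        assert np.allclose(b1.intervals, b2.intervals)
        assert np.allclose(np.sort(b1.first_times[0]), np.sort(b2.first_times[0]))


class TestBurstOrder:
    def test_identical_bursts_correlate_perfectly(self):
        ids = np.arange(10)
        t = np.linspace(0.0, 9.0, 10)
        assert burst_order_similarity(ids, t, ids, t) == pytest.approx(1.0)

    def test_reversed_order_gives_minus_one(self):
        ids = np.arange(10)
        t = np.linspace(0.0, 9.0, 10)
        assert burst_order_similarity(ids, t, ids, 9.0 - t) == pytest.approx(-1.0)

    def test_single_adjacent_transposition_hand_value(self):
        # Spearman rho for one adjacent swap among 5 = 1 - 12/120 = 0.9
        ids = np.arange(5)
        a = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 0.0, 2.0, 3.0, 4.0])
        assert burst_order_similarity(ids, a, ids, b) == pytest.approx(0.9)

    def test_too_few_common_neurons_is_undefined(self):
        assert burst_order_similarity(np.array([0, 1]), np.zeros(2),
                                      np.array([2, 3]), np.zeros(2)) is None


class TestFeatureSimilarity:
    def test_self_similarity_is_one(self):
        x = np.array([[1.0, 2.0, 3.0, 5.0], [2.0, 1.0, 4.0, 3.0]])
        for mode in ("pearson", "pca"):
            s = feature_similarity(x, [0, 1], mode=mode)
            assert np.allclose(np.diag(s.s), 1.0)

    def test_orthogonal_vectors_have_zero_similarity(self):
        x = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
        s = feature_similarity(x, [0, 1], mode="pearson")
        assert s.s[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_scramble_destroys_group_structure(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(5, 15, 40)
        x = np.array([base + rng.normal(0, 0.5, 40) for _ in range(6)])
        groups = [0, 0, 0, 1, 1, 1]
        plain = feature_similarity(x, groups, mode="pearson")
        scr = feature_similarity(x, groups, mode="pearson", scramble=True, seed=7)
        assert np.nanmean(np.abs(scr.s[~np.eye(6, dtype=bool)])) < \
            np.nanmean(np.abs(plain.s[~np.eye(6, dtype=bool)]))

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            feature_similarity(np.ones((1, 4)), [0])


class TestNSScore:
    def test_identical_runs_across_groups_score_exactly_zero(self):
        x = np.tile(np.array([3.0, 1.0, 4.0, 1.0, 5.0]), (8, 1))
        groups = np.repeat([0, 1, 2, 3], 2)
        for mode in ("pearson", "pca"):
            sim = feature_similarity(x, groups, mode=mode)
            for sc in network_similarity_score(sim):
                assert sc.ns == 0.0

    def test_orthogonal_groups_reach_the_half_maximum(self):
        # within-group similarity 1, between-group 0 -> NS = (1-0)/2
        v = np.array([[1.0, 1.0, -1.0, -1.0],
                      [1.0, -1.0, 1.0, -1.0],
                      [1.0, -1.0, -1.0, 1.0]])
        x = np.repeat(v, 2, axis=0)
        sim = feature_similarity(x, np.repeat([0, 1, 2], 2), mode="pearson")
        scores = network_similarity_score(sim)
        assert all(sc.ns == pytest.approx(0.5) for sc in scores)

    def test_scaled_variant_multiplies_by_group_scale(self):
        v = np.repeat(np.array([[1.0, 1.0, -1.0, -1.0],
                                [1.0, -1.0, 1.0, -1.0]]), 2, axis=0)
        sim = feature_similarity(v, [0, 0, 1, 1], mode="pearson")
        scores = network_similarity_score(sim, scales={0: 0.4, 1: 0.8})
        assert scores[0].ns_scaled == pytest.approx(0.4 * scores[0].ns)
        assert scores[1].ns_scaled == pytest.approx(0.8 * scores[1].ns)

    def test_squared_reading_available(self):
        v = np.repeat(np.array([[1.0, 1.0, -1.0, -1.0],
                                [1.0, -1.0, 1.0, -1.0]]), 2, axis=0)
        sim = feature_similarity(v, [0, 0, 1, 1], mode="pearson")
        sq = network_similarity_score(sim, squared=True)
        assert all(sc.ns == pytest.approx(1.0) for sc in sq)

    def test_group_permutation_centres_the_score_on_zero(self):
        from ratephase.synth import grouped_cohort

        rasters, labels = grouped_cohort(3, 4, structure="rate", effect=1.0,
                                         seed=11)
        x = np.array([firing_rates(r).rates for r in rasters])
        rng = np.random.default_rng(5)
        means = []
        for _ in range(12):
            perm = rng.permutation(labels)
            sim = feature_similarity(x, perm, mode="pearson")
            means.append(np.mean([s.ns for s in network_similarity_score(sim)]))
        means = np.asarray(means)
        assert abs(means.mean()) < 0.05
        assert means.min() < 0.0 < means.max()
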