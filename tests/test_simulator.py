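"""Integration contracts: determinism, calibration transfer, noise, dt."""

from dataclasses import replace

import numpy as np
import pytest

import ratephase as rp


def _uniform_pattern(current, n):
    return rp.generate_input_pattern(0, mean=current, n_neurons=n, range_=0.0)


class TestDeterminism:
    def test_identical_seeds_give_bit_identical_rasters(self, small_net, cell0,
                                                        syn, current_10hz):
        pat = rp.generate_input_pattern(2, mean=current_10hz,
                                        n_neurons=small_net.n_neurons)
        cfg = rp.SimConfig(duration=1500.0, analysis_window=1000.0, run_seed=5)
        noise = rp.NoiseSpec(rate=2.0, noise_seed=9)
        a = rp.run_simulation(small_net, pat, None, noise, cell0, syn, cfg)
        b = rp.run_simulation(small_net, pat, None, noise, cell0, syn, cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a.spikes, b.spikes))

    def test_different_run_seed_changes_the_raster(self, small_net, cell0, syn,
                                                   current_10hz):
        pat = rp.generate_input_pattern(2, mean=current_10hz,
                                        n_neurons=small_net.n_neurons)
        a = rp.run_simulation(
            small_net, pat, None, None, cell0, syn,
            rp.SimConfig(duration=1500.0, analysis_window=1000.0, run_seed=1))
        b = rp.run_simulation(
            small_net, pat, None, None, cell0, syn,
            rp.SimConfig(duration=1500.0, analysis_window=1000.0, run_seed=2))
        assert any(not np.array_equal(x, y) for x, y in zip(a.spikes, b.spikes))


class TestRates:
    def test_uncoupled_network_fires_at_the_calibrated_rate(self, small_net,
                                                            cell0, syn,
                                                            current_10hz):
        """With synapses off and a uniform input at the calibrated mean,
        every neuron reproduces the isolated 10 Hz within 2%."""
        pat = _uniform_pattern(current_10hz, small_net.n_neurons)
        cfg = rp.SimConfig(run_seed=3)
        silent = replace(syn, w_e=0.0, w_i=0.0)
        raster = rp.run_simulation(small_net, pat, None, None, cell0, silent, cfg)
        rates = raster.counts(cfg.window) / 5.0
        assert np.all(np.abs(rates - 10.0) <= 0.2 + 1e-9)

    def test_far_subthreshold_input_gives_an_empty_raster(self, small_net,
                                                          cell0, syn):
        pat = _uniform_pattern(-1.5, small_net.n_neurons)
        cfg = rp.SimConfig(duration=1500.0, analysis_window=1000.0, run_seed=3)
        raster = rp.run_simulation(small_net, pat, None, None, cell0, syn, cfg)
        assert all(s.size == 0 for s in raster.spikes)


class TestConvergence:
    def test_halving_dt_shifts_single_neuron_spikes_below_tenth_ms(self, cell0):
        a = rp.single_neuron_spikes(cell0, 1.0, duration=1000.0, dt=0.05)
        b = rp.single_neuron_spikes(cell0, 1.0, duration=1000.0, dt=0.025)
        n = min(a.size, b.size)
        assert n >= 10
        assert np.max(np.abs(a[:n] - b[:n])) < 0.1


class TestNoise:
    def test_zero_rate_gives_empty_schedule(self):
        t, i = rp.inject_noise_spikes(rp.NoiseSpec(rate=0.0), rp.SimConfig(), 375)
        assert t.size == 0 and i.size == 0

    def test_poisson_event_count_at_reference_settings(self):
        # 1 Hz x 375 neurons x 7 s -> 2625 expected events
        t, i = rp.inject_noise_spikes(rp.NoiseSpec(rate=1.0, noise_seed=4),
                                      rp.SimConfig(run_seed=6), 375)
        assert abs(t.size - 2625) < 4 * np.sqrt(2625)
        assert np.all(np.diff(t) >= 0)
        t2, _ = rp.inject_noise_spikes(rp.NoiseSpec(rate=1.0, noise_seed=4),
                                       rp.SimConfig(run_seed=6), 375)
        assert np.array_equal(t, t2)

    def test_forced_spikes_drive_silent_neurons(self, small_net, cell0, syn):
        """Neurons far below rheobase only spike when the noise schedule
        forces them; counts then track the configured rate."""
        pat = _uniform_pattern(-1.5, small_net.n_neurons)
        cfg = rp.SimConfig(duration=4000.0, analysis_window=3000.0, run_seed=3)
        raster = rp.run_simulation(small_net, pat, None,
                                   rp.NoiseSpec(rate=5.0, noise_seed=1),
                                   cell0, syn, cfg)
        per_neuron = np.array([s.size for s in raster.spikes])
        expected = 5.0 * 4.0  # rate x duration
        assert abs(per_neuron.mean() - expected) / expected < 0.5


class TestRasterContainer:
    def test_unsorted_spike_times_rejected(self):
        with pytest.raises(ValueError):
            rp.SpikeRaster(spikes=[[3.0, 1.0]], ei_labels=[True], duration=10.0)

    def test_csv_roundtrip(self, tmp_path, small_net, cell0, syn, current_10hz):
        pat = rp.generate_input_pattern(2, mean=current_10hz,
                                        n_neurons=small_net.n_neurons)
        cfg = rp.SimConfig(duration=1200.0, analysis_window=1000.0, run_seed=8)
        raster = rp.run_simulation(small_net, pat, None, None, cell0, syn, cfg)
        p = tmp_path / "raster.csv"
        raster.to_csv(p)
        back = rp.SpikeRaster.from_csv(p)
        assert back.n_neurons == raster.n_neurons
        assert back.meta["run_seed"] == 8
        for x, y in zip(raster.spikes, back.spikes):
            assert np.allclose(x, y)

    def test_hdf5_roundtrip(self, tmp_path, small_net, cell0, syn,
                            current_10hz):
        pat = rp.generate_input_pattern(2, mean=current_10hz,
                                        n_neurons=small_net.n_neurons)
        cfg = rp.SimConfig(duration=1200.0, analysis_window=1000.0, run_seed=8)
        raster = rp.run_simulation(small_net, pat, None, None, cell0, syn, cfg)
        p = tmp_path / "raster.h5"
        raster.to_hdf5(p)
        back = rp.SpikeRaster.from_hdf5(p)
        assert back.meta == raster.meta
        for x, y in zip(raster.spikes, back.spikes):
            assert np.array_equal(x, y)
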