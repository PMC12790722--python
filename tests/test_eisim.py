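import numpy as np
import pytest

from meakit.core import ValidationError
from meakit import eisim


def short_config(**kwargs):
    defaults = dict(duration_s=5.0, warmup_s=1.0, seed=3)
    defaults.update(kwargs)
    return eisim.SimConfig(**defaults)


class TestBuildNetwork:
    def test_structural_audit(self):
        cfg = short_config(n_neurons=1000, n_excitatory=800, synapses_per_neuron=100)
        net = eisim.build_network(cfg)
        assert net.targets.shape == (1000, 100)
        # no self-connections
        assert not (net.targets == np.arange(1000)[:, None]).any()
        # inhibitory neurons project to excitatory neurons only
        assert (net.targets[800:] < 800).all()
        # delays: excitatory 1-20 ms, inhibitory 1 ms
        assert net.delays[:800].min() >= 1 and net.delays[:800].max() <= 20
        assert (net.delays[800:] == 1).all()
        # initial weights
        assert (net.weights[:800] == 6.0).all()
        assert (net.weights[800:] == -5.0).all()
        # neuron constants: regular-spiking vs fast-spiking split
        assert (net.a[:800] == 0.02).all() and (net.a[800:] == 0.1).all()
        assert (net.d[:800] == 8.0).all() and (net.d[800:] == 2.0).all()

    def test_all_inhibitory_network_builds_and_is_nearly_silent(self):
        cfg = short_config(n_neurons=200, n_excitatory=0, synapses_per_neuron=20)
        net = eisim.build_network(cfg)
        res = eisim.simulate(net, cfg)
        # only the externally kicked neurons fire; no recurrent excitation
        assert res.n_spikes < 2 * cfg.duration_s * 1000

    def test_same_seed_identical_adjacency(self):
        cfg = short_config()
        a = eisim.build_network(cfg)
        b = eisim.build_network(cfg)
        assert np.array_equal(a.targets, b.targets)
        assert np.array_equal(a.delays, b.delays)

    def test_too_many_synapses_rejected(self):
        with pytest.raises(ValidationError):
            short_config(n_neurons=50, n_excitatory=40, synapses_per_neuron=50)


class TestSimulate:
    def test_silent_without_drive_and_weights(self):
        cfg = short_config(input_amplitude=0.0, init_weight_exc=0.0, init_weight_inh=0.0)
        net = eisim.build_network(cfg)
        res = eisim.simulate(net, cfg)
        assert res.n_spikes == 0

    def test_determinism(self):
        cfg = short_config()
        a = eisim.simulate(eisim.build_network(cfg), cfg)
        b = eisim.simulate(eisim.build_network(cfg), cfg)
        assert np.array_equal(a.neuron_ids, b.neuron_ids)
        assert np.array_equal(a.spike_times_ms, b.spike_times_ms)
        assert np.array_equal(a.final_weights, b.final_weights)

    def test_stdp_off_leaves_weights_unchanged(self):
        cfg = short_config(stdp_enabled=False)
        net = eisim.build_network(cfg)
        res = eisim.simulate(net, cfg)
        assert np.array_equal(res.final_weights, net.weights)

    def test_excitatory_weights_stay_in_bounds(self):
        cfg = short_config(duration_s=10.0, warmup_s=0.0)
        net = eisim.build_network(cfg)
        res = eisim.simulate(net, cfg)
        w = res.final_weights[: cfg.n_excitatory]
        assert w.min() >= 0.0 and w.max() <= cfg.weight_cap
        # inhibitory weights fixed
        assert (res.final_weights[cfg.n_excitatory:] == -5.0).all()

    def test_single_neuron_period_matches_fine_step_oracle(self):
        """A driven regular-spiking cell fires periodically; the period of
        the dt = 1 ms two-half-step scheme agrees with a 0.1 ms Euler
        reference on the same equations."""
        cfg = eisim.SimConfig(
            n_neurons=1, n_excitatory=1, synapses_per_neuron=0,
            duration_s=10.0, warmup_s=1.0, stdp_enabled=False, seed=0,
        )
        net = eisim.build_network(cfg)
        res = eisim.simulate(net, cfg)
        periods = np.diff(res.spike_times_ms)
        assert periods.size > 10
        # reference: Euler at dt = 0.1 ms; the single neuron receives the
        # 20-unit external current on every coarse step, i.e. continuously
        dt = 0.1
        v, u = -65.0, -65.0 * 0.2
        spikes = []
        for step in range(int(11_000 / dt)):
            v += dt * (0.04 * v * v + 5.0 * v + 140.0 - u + 20.0)
            u += dt * 0.02 * (0.2 * v - u)
            if v >= 30.0:
                spikes.append(step * dt)
                v, u = -65.0, u + 8.0
        ref_periods = np.diff([s for s in spikes if s > 1000.0])
        assert np.mean(periods) == pytest.approx(np.mean(ref_periods), rel=0.1)

    def test_stationarity_without_stdp(self):
        """With plasticity off, doubling the scored duration roughly doubles
        the spike count."""
        short = short_config(duration_s=20.0, warmup_s=5.0, stdp_enabled=False)
        long = short_config(duration_s=40.0, warmup_s=5.0, stdp_enabled=False)
        n_short = eisim.simulate(eisim.build_network(short), short).n_spikes
        n_long = eisim.simulate(eisim.build_network(long), long).n_spikes
        assert n_long == pytest.approx(2 * n_short, rel=0.15)


class TestINF:
    def _result_from_counts(self, counts_per_bin, bin_ms=10.0, n_neurons=1000):
        ids = []
        times = []
        for b, k in enumerate(counts_per_bin):
            ids.extend(np.arange(k) % n_neurons)
            times.extend(np.full(k, b * bin_ms + 0.5 * bin_ms))
        cfg = eisim.SimConfig(
            n_neurons=n_neurons,
            duration_s=len(counts_per_bin) * bin_ms / 1000.0,
            warmup_s=0.0,
        )
        return eisim.SimResult(
            neuron_ids=np.array(ids, dtype=int),
            spike_times_ms=np.array(times),
            final_weights=np.zeros((1, 1)),
            config=cfg,
        )

    def test_empty_raster_zero_rate(self):
        res = self._result_from_counts([0] * 100)
        inf = eisim.instantaneous_network_firing(res)
        assert inf.inf_rate_per_min == 0.0

    def test_planted_surges_counted_exactly(self):
        counts = [10] * 20 + [300, 400] + [10] * 20 + [150] + [10] * 20 + [500, 500, 500] + [10] * 20
        res = self._result_from_counts(counts)
        inf = eisim.instantaneous_network_firing(res, phi=0.1)
        # brute-force: maximal runs of bins with count > 100
        hot = [c > 100 for c in counts]
        runs = sum(1 for i, h in enumerate(hot) if h and (i == 0 or not hot[i - 1]))
        assert len(inf.event_times_ms) == runs == 3
        assert inf.event_peaks.tolist() == [400, 150, 500]

    def test_counts_conserve_raster_size(self):
        counts = [7, 0, 3, 120, 5]
        res = self._result_from_counts(counts)
        inf = eisim.instantaneous_network_firing(res)
        assert inf.counts.sum() == res.n_spikes

    def test_raising_phi_never_increases_events(self):
        counts = [10] * 10 + [200] + [10] * 10 + [400] + [10] * 10
        res = self._result_from_counts(counts)
        events = [
            len(eisim.instantaneous_network_firing(res, phi=p).event_times_ms)
            for p in [0.05, 0.1, 0.25, 0.35, 0.5]
        ]
        assert all(a >= b for a, b in zip(events, events[1:]))


class TestSweep:
    def test_single_ratio_equals_direct_call(self):
        cfg = short_config(duration_s=10.0, warmup_s=2.0)
        table = eisim.ei_sweep([(800, 200)], reps=1, config=cfg, seed=5)
        run_seed = (5 * 100003) % (2**31)
        from dataclasses import replace

        direct_cfg = replace(cfg, n_excitatory=800, seed=run_seed)
        direct = eisim.instantaneous_network_firing(
            eisim.simulate(eisim.build_network(direct_cfg), direct_cfg)
        )
        assert table.inf_rate_mean[0] == pytest.approx(direct.inf_rate_per_min)

    def test_sweep_reproducible(self):
        cfg = short_config(duration_s=5.0, warmup_s=1.0)
        a = eisim.ei_sweep([(800, 200), (500, 500)], reps=2, config=cfg, seed=6)
        b = eisim.ei_sweep([(800, 200), (500, 500)], reps=2, config=cfg, seed=6)
        assert a.equals(b)

    def test_ratio_sum_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            eisim.ei_sweep([(800, 100)], reps=1, config=short_config(), seed=1)


class TestSaturationGuard:
    def test_runaway_network_stops_early_and_is_flagged(self):
        # no inhibition, weights at the cap, no plasticity: activity explodes
        cfg = eisim.SimConfig(
            n_neurons=300, n_excitatory=300, synapses_per_neuron=100,
            init_weight_exc=10.0, duration_s=30.0, warmup_s=0.0,
            stdp_enabled=False, seed=1,
        )
        res = eisim.simulate(eisim.build_network(cfg), cfg)
        assert res.saturated
        assert res.scored_duration_s < cfg.duration_s
        inf = eisim.instantaneous_network_firing(res)
        # a saturated raster collapses into very few long events
        assert len(inf.event_times_ms) <= 3
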