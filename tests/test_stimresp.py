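import numpy as np
import pytest

from meakit.core import GridGeometry, SpikeTrainSet, ValidationError
from meakit import stimresp as sr
from meakit import synthdata as sd


@pytest.fixture(scope="module")
def excitatory_session(geometry16):
    kernel = sd.gaussian_response_kernel(amplitude_hz=300.0, dist_scale_um=120.0)
    stim = [geometry16.n_channels // 2 + 8]
    session, truth = sd.generate_stim_session(
        geometry16, stim, n_pulses=25, kernel=kernel, seed=41
    )
    return session, truth


@pytest.fixture(scope="module")
def excitatory_map(excitatory_session):
    session, _ = excitatory_session
    return sr.evoked_response(session, seed=42)


class TestSession:
    def test_pulse_times_must_increase(self, background16):
        with pytest.raises(ValidationError):
            sr.StimulationSession(background16, [2.0, 1.0], [0])

    def test_same_seed_identical_session(self, geometry16):
        a, _ = sd.generate_stim_session(geometry16, [5], n_pulses=5, seed=9)
        b, _ = sd.generate_stim_session(geometry16, [5], n_pulses=5, seed=9)
        assert a.spikes == b.spikes
        assert np.array_equal(a.pulse_times, b.pulse_times)


class TestEvokedResponse:
    def test_planted_excitatory_channel_positive_in_early_bin(self, excitatory_session, excitatory_map):
        session, truth = excitatory_session
        planted = {c for c, s in truth.planted_response_channels.items() if s > 0}
        detected = set(excitatory_map.significant_channels(+1).tolist())
        assert planted  # fixture actually plants something
        assert len(detected & planted) / len(planted) >= 0.9
        # the stimulated-site response is in the first (5-10 ms) bin
        first_bin_pos = set(
            excitatory_map.channels[excitatory_map.significance[:, 0] > 0].tolist()
        )
        assert first_bin_pos & planted

    def test_planted_suppressive_channels_flagged_negative(self, geometry16):
        kernel = sd.suppressive_kernel(amplitude_hz=50.0, latency_mean_s=0.05, latency_sd_s=0.05)
        session, truth = sd.generate_stim_session(
            geometry16, [100], n_pulses=25, kernel=kernel, baseline_rate=10.0, seed=43
        )
        rmap = sr.evoked_response(session, seed=44)
        planted = {c for c, s in truth.planted_response_channels.items() if s < 0}
        neg = set(rmap.significant_channels(-1).tolist())
        pos = set(rmap.significant_channels(+1).tolist())
        assert planted
        assert len(neg & planted) / len(planted) >= 0.6
        # opposite-sign flags on planted channels stay at chance level
        assert len(pos & planted) / len(planted) <= 0.1

    def test_fdr_mode_is_more_conservative_but_keeps_strong_responses(
        self, excitatory_session, excitatory_map
    ):
        session, truth = excitatory_session
        rmap_fdr = sr.evoked_response(session, fdr=True, seed=42)
        assert np.abs(rmap_fdr.significance).sum() <= np.abs(excitatory_map.significance).sum()
        planted = {c for c, s in truth.planted_response_channels.items() if s > 0}
        detected = set(rmap_fdr.significant_channels(+1).tolist())
        assert len(detected & planted) / len(planted) >= 0.9

    def test_translation_invariance(self, geometry16):
        rng = np.random.default_rng(45)
        t = np.sort(rng.uniform(0, 30.0, 2000))
        ch = rng.integers(0, geometry16.n_channels, 2000)
        pulses = np.array([5.0, 10.0, 15.0, 20.0])
        rec_a = SpikeTrainSet(ch, t, 40.0, geometry16)
        rec_b = SpikeTrainSet(ch, t + 3.0, 40.0, geometry16)
        a = sr.evoked_response(sr.StimulationSession(rec_a, pulses, [0]), n_resamples=200, seed=1)
        b = sr.evoked_response(sr.StimulationSession(rec_b, pulses + 3.0, [0]), n_resamples=200, seed=1)
        assert np.allclose(a.response, b.response)
        assert np.array_equal(a.significance, b.significance)

    def test_ci_brackets_mean(self, excitatory_map):
        assert (excitatory_map.ci_low <= excitatory_map.response + 1e-9).all()
        assert (excitatory_map.ci_high >= excitatory_map.response - 1e-9).all()

    def test_overlapping_pulse_windows_rejected(self, background16):
        session = sr.StimulationSession(background16, [1.0, 1.05], [])
        with pytest.raises(ValidationError):
            sr.evoked_response(session)

    def test_null_type_one_error_rate(self):
        """Cell-wise false-positive rate under the null kernel <= 1.5 alpha."""
        g = GridGeometry(6, 6)
        rates = []
        for seed in range(100):
            session, _ = sd.generate_stim_session(
                g, [10], n_pulses=25, kernel=sd.null_kernel, baseline_rate=5.0, seed=seed
            )
            rmap = sr.evoked_response(session, n_resamples=300, seed=seed + 10_000)
            rates.append(np.abs(rmap.significance).mean())
        assert np.mean(rates) <= 1.5 * 0.05


class TestGlobalResponseCurve:
    def test_sums_to_one(self, excitatory_map):
        curve = sr.global_response_curve(excitatory_map)
        assert curve.sum() == pytest.approx(1.0)

    def test_point_mass_when_single_bin_responds(self):
        rmap = sr.ResponseMap(
            channels=np.arange(3),
            latency_edges=np.array([0.005, 0.010, 0.020]),
            response=np.array([[2.0, 0.0], [1.0, 0.0], [0.0, 0.0]]),
            ci_low=np.zeros((3, 2)),
            ci_high=np.zeros((3, 2)),
            significance=np.array([[1, 0], [1, 0], [0, 0]], dtype=np.int8),
        )
        assert sr.global_response_curve(rmap).tolist() == [1.0, 0.0]

    def test_all_zero_when_nothing_significant(self):
        rmap = sr.ResponseMap(
            channels=np.arange(2),
            latency_edges=np.array([0.005, 0.010]),
            response=np.array([[1.0], [2.0]]),
            ci_low=np.zeros((2, 1)),
            ci_high=np.zeros((2, 1)),
            significance=np.zeros((2, 1), dtype=np.int8),
        )
        assert (sr.global_response_curve(rmap) == 0).all()


class TestDispersionIndex:
    def _map_with_significance(self, geometry, sig_channels_per_bin):
        n_ch = geometry.n_channels
        n_bins = len(sig_channels_per_bin)
        sig = np.zeros((n_ch, n_bins), dtype=np.int8)
        for b, chans in enumerate(sig_channels_per_bin):
            sig[list(chans), b] = 1
        edges = np.linspace(0.005, 0.150, n_bins + 1)
        return sr.ResponseMap(
            channels=np.arange(n_ch),
            latency_edges=edges,
            response=sig.astype(float),
            ci_low=np.zeros((n_ch, n_bins)),
            ci_high=np.zeros((n_ch, n_bins)),
            significance=sig,
        )

    def test_single_channel_distance(self, geometry16):
        stim = 0
        resp = 3  # same row, 3 columns away -> 180 um
        rmap = self._map_with_significance(geometry16, [{resp}])
        curve = sr.dispersion_index(rmap, geometry16, [stim])
        assert curve.mean_distance[0] == pytest.approx(180.0)

    def test_matches_brute_force(self, geometry16, excitatory_map):
        stim = [geometry16.n_channels // 2 + 8]
        curve = sr.dispersion_index(excitatory_map, geometry16, stim)
        pos = geometry16.positions()
        sp = pos[stim[0]]
        for b in range(excitatory_map.n_bins):
            resp = np.flatnonzero(excitatory_map.significance[:, b] > 0)
            if resp.size == 0:
                assert np.isnan(curve.mean_distance[b])
            else:
                expected = np.mean(np.hypot(pos[resp, 0] - sp[0], pos[resp, 1] - sp[1]))
                assert curve.mean_distance[b] == pytest.approx(expected)

    def test_growing_activation_radius_gives_increasing_dispersion(self, geometry16):
        kernel = sd.gaussian_response_kernel(
            amplitude_hz=400.0,
            latency_mean_s=0.05,
            latency_sd_s=0.08,
            dist_scale_um=30.0,
            speed_um_per_s=4000.0,
        )
        session, _ = sd.generate_stim_session(
            geometry16, [geometry16.n_channels // 2 + 8], n_pulses=25, kernel=kernel, seed=47
        )
        rmap = sr.evoked_response(session, seed=48)
        curve = sr.dispersion_index(rmap, geometry16, session.stim_channels)
        d = curve.mean_distance[~np.isnan(curve.mean_distance)]
        assert d.size >= 3
        assert d[-1] > d[0]


class TestSelectStimChannels:
    def test_top_k_by_rate_with_tie_rule(self, geometry16):
        rng = np.random.default_rng(49)
        rates = rng.permutation(geometry16.n_channels).astype(float)
        ch = np.repeat(np.arange(geometry16.n_channels), rates.astype(int))
        t = rng.uniform(0, 10.0, ch.size)
        rec = SpikeTrainSet(ch, t, 10.0, geometry16)
        got = sr.select_stim_channels(rec, k=7)
        expected = np.argsort(-rates, kind="stable")[:7].tolist()
        assert got == expected

    def test_all_equal_rates_selects_lowest_ids(self, geometry16):
        ch = np.arange(geometry16.n_channels)
        rec = SpikeTrainSet(ch, np.full(ch.size, 1.0), 10.0, geometry16)
        assert sr.select_stim_channels(rec, k=7) == list(range(7))

    def test_fewer_active_than_k(self, geometry16):
        rec = SpikeTrainSet([3, 5], [1.0, 2.0], 10.0, geometry16)
        assert sorted(sr.select_stim_channels(rec, k=7)) == [3, 5]


class TestEvokedNB:
    def test_propagating_response_evokes_nb(self, geometry16):
        kernel = sd.gaussian_response_kernel(
            amplitude_hz=500.0, latency_mean_s=0.03, latency_sd_s=0.03, dist_scale_um=2000.0
        )
        session, _ = sd.generate_stim_session(
            geometry16, [100, 101, 102], n_pulses=10, kernel=kernel,
            baseline_rate=1.0, inter_pulse_s=2.0, seed=51,
        )
        report = sr.detect_evoked_nb(session)
        assert report["evoked_fraction"] >= 0.9
        assert report["evoked_nbd_s"] > 0

    def test_local_only_response_evokes_none(self, geometry16):
        kernel = sd.gaussian_response_kernel(
            amplitude_hz=400.0, latency_mean_s=0.01, latency_sd_s=0.003, dist_scale_um=20.0
        )
        session, _ = sd.generate_stim_session(
            geometry16, [100], n_pulses=10, kernel=kernel,
            baseline_rate=1.0, inter_pulse_s=2.0, seed=52,
        )
        report = sr.detect_evoked_nb(session)
        assert report["evoked_fraction"] <= 0.1

    def test_no_pulses_empty_report(self, background16):
        session = sr.StimulationSession(background16, [], [])
        report = sr.detect_evoked_nb(session)
        assert report["per_pulse"] == []
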