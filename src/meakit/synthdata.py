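"""Synthetic HD-MEA recordings with known ground truth.

Generators for the statistical structure the analysis stages assume:
independent Poisson background firing, recurrent propagating network bursts,
planted pairwise correlations, and planted distance/latency-dependent
stimulus responses.  Every generator is deterministic given (parameters,
seed) and returns, where relevant, a :class:`SyntheticGroundTruth` recording
exactly what was planted, so detection stages can be scored against truth.

These are statistical fixtures, not a biophysical culture model: spikes are
drawn from the prescribed point processes, nothing is simulated
mechanistically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import GridGeometry, SpikeTrainSet, ValidationError

__all__ = [
    "MixtureSpec",
    "SyntheticGroundTruth",
    "expected_inhibitory_fraction",
    "lognormal_rate_map",
    "generate_background",
    "generate_network_bursts",
    "plant_correlations",
    "generate_stim_session",
    "gaussian_response_kernel",
    "suppressive_kernel",
    "null_kernel",
    "nb_rate_for_ei_fraction",
    "ei_mixture_recording",
]


@dataclass(frozen=True)
class MixtureSpec:
    """A two-component culture mixture with known inhibitory content.

    ``ratio`` gives the weights of the two components (e.g. 0.8/0.2 for an
    80:20 co-culture of a mostly-excitatory and a mostly-inhibitory
    population); ``component_inhibitory_pct`` the percentage of inhibitory
    neurons within each component.
    """

    ratio: tuple[float, float]
    component_inhibitory_pct: tuple[float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.ratio, dtype=float)
        p = np.asarray(self.component_inhibitory_pct, dtype=float)
        if w.shape != (2,) or p.shape != (2,):
            raise ValidationError("MixtureSpec needs exactly two components")
        if (w < 0).any():
            raise ValidationError("mixture weights must be non-negative")
        if not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(f"mixture weights must sum to 1, got {w.sum()}")
        if (p < 0).any() or (p > 100).any():
            raise ValidationError("component inhibitory percentages must lie in [0, 100]")


def expected_inhibitory_fraction(mix: MixtureSpec) -> float:
    """Theoretical inhibitory-neuron percentage of a mixed culture.

    The weighted mean of the component inhibitory percentages: a culture
    mixing a 7%-inhibitory population with an 80%-inhibitory one at 80:20
    carries 21.6% inhibitory neurons, at 50:50 it carries 43.5%.
    """
    w = np.asarray(mix.ratio, dtype=float)
    p = np.asarray(mix.component_inhibitory_pct, dtype=float)
    return float(np.dot(w, p))


@dataclass
class SyntheticGroundTruth:
    """What a generator planted, for scoring detections against truth."""

    planted_nb_times: list[float] = field(default_factory=list)
    planted_nb_origin: list[tuple[float, float]] = field(default_factory=list)
    planted_graph: set[tuple[int, int]] = field(default_factory=set)
    planted_response_channels: dict[int, int] = field(default_factory=dict)  # channel -> sign
    ei_fraction: float | None = None

    def validate(self) -> None:
        times = np.asarray(self.planted_nb_times)
        if times.size and (np.diff(times) <= 0).any():
            raise ValidationError("planted NB times must be strictly increasing")
        for a, b in self.planted_graph:
            if a == b:
                raise ValidationError("planted graph must not contain self-pairs")

    def to_dict(self) -> dict:
        return {
            "planted_nb_times_s": [float(t) for t in self.planted_nb_times],
            "planted_nb_origin_um": [[float(x), float(y)] for x, y in self.planted_nb_origin],
            "planted_graph": sorted([int(a), int(b)] for a, b in self.planted_graph),
            "planted_response_channels": {str(k): int(v) for k, v in self.planted_response_channels.items()},
            "ei_fraction": self.ei_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticGroundTruth":
        return cls(
            planted_nb_times=list(d.get("planted_nb_times_s", [])),
            planted_nb_origin=[tuple(p) for p in d.get("planted_nb_origin_um", [])],
            planted_graph={tuple(sorted(p)) for p in d.get("planted_graph", [])},
            planted_response_channels={int(k): int(v) for k, v in d.get("planted_response_channels", {}).items()},
            ei_fraction=d.get("ei_fraction"),
        )


def lognormal_rate_map(
    geometry: GridGeometry,
    median_hz: float = 0.5,
    sigma: float = 1.0,
    silent_fraction: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-channel background rates drawn log-normally (median ``median_hz``).

    A log-normal spread exercises the active/inactive channel split: with
    the defaults ~5% of channels fall below the 0.1 Hz activity criterion.
    ``silent_fraction`` forces that share of channels to exactly zero.
    """
    rng = np.random.default_rng(seed)
    rates = rng.lognormal(mean=math.log(median_hz), sigma=sigma, size=geometry.n_channels)
    if silent_fraction > 0:
        n_silent = int(round(silent_fraction * geometry.n_channels))
        silent = rng.choice(geometry.n_channels, size=n_silent, replace=False)
        rates[silent] = 0.0
    return rates


def generate_background(
    geometry: GridGeometry,
    duration: float,
    rate_map: np.ndarray | float,
    seed: int,
) -> SpikeTrainSet:
    """Independent homogeneous Poisson spike trains, one per channel.

    ``rate_map`` is a scalar rate (Hz) applied to all channels or a
    per-channel array.  Deterministic given the seed.
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    rates = np.broadcast_to(np.asarray(rate_map, dtype=float), (geometry.n_channels,))
    if (rates < 0).any():
        raise ValidationError("firing rates must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates * duration)
    total = int(counts.sum())
    channels = np.repeat(np.arange(geometry.n_channels), counts)
    times = rng.uniform(0.0, duration, size=total)
    return SpikeTrainSet(channels, times, duration, geometry)


def _planted_nb_times(duration: float, n_nb: int, min_gap: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-regular burst times: an even grid with bounded random jitter."""
    if n_nb == 0:
        return np.empty(0)
    slot = duration / n_nb
    jitter_span = max(0.0, (slot - min_gap) / 2.0)
    centers = (np.arange(n_nb) + 0.5) * slot
    times = centers + rng.uniform(-jitter_span / 2, jitter_span / 2, size=n_nb)
    return np.sort(times)


def generate_network_bursts(
    base: SpikeTrainSet,
    nb_rate: float,
    nb_duration: float = 0.3,
    participation: float = 0.6,
    propagation_speed: float = 50.0,
    burst_rate_hz: float = 100.0,
    seed: int = 0,
) -> tuple[SpikeTrainSet, SyntheticGroundTruth]:
    """Superimpose propagating network bursts on a background recording.

    At each planted time an origin channel is drawn, a random fraction
    ``participation`` of channels is recruited, and each recruited channel
    fires one wavefront spike at its onset followed by a transient Poisson
    barrage at ``burst_rate_hz`` for ``nb_duration`` seconds, the onset
    lagging the burst time by distance(origin)/``propagation_speed`` (um
    per ms) — a radial wave whose centre of activity moves away from the
    origin.  ``propagation_speed`` may be ``inf`` for simultaneous onset.

    Returns the augmented recording and the ground truth (burst times and
    origins).
    """
    if nb_rate < 0:
        raise ValidationError("nb_rate must be non-negative")
    if not 0 < participation <= 1:
        raise ValidationError("participation must lie in (0, 1]")
    if nb_rate == 0:
        return base, SyntheticGroundTruth()
    rng = np.random.default_rng(seed)
    geometry = base.geometry
    n_nb = int(round(nb_rate * base.duration / 60.0))
    positions = geometry.positions()
    # leave headroom at the recording end for the propagation tail
    max_latency = 0.0 if math.isinf(propagation_speed) else (
        float(np.hypot(geometry.n_cols * geometry.pitch, geometry.n_rows * geometry.pitch)) / propagation_speed / 1000.0
    )
    usable = base.duration - nb_duration - max_latency
    if usable <= 0:
        raise ValidationError("recording too short for the requested burst shape")
    nb_times = _planted_nb_times(usable, n_nb, min_gap=nb_duration + max_latency + 0.2, rng=rng)

    truth = SyntheticGroundTruth()
    extra_ch: list[np.ndarray] = []
    extra_t: list[np.ndarray] = []
    n_recruit = max(1, int(round(participation * geometry.n_channels)))
    for t0 in nb_times:
        origin_channel = int(rng.integers(geometry.n_channels))
        origin = positions[origin_channel]
        recruited = rng.choice(geometry.n_channels, size=n_recruit, replace=False)
        dists = np.hypot(*(positions[recruited] - origin).T)
        latency = np.zeros_like(dists) if math.isinf(propagation_speed) else dists / propagation_speed / 1000.0
        counts = rng.poisson(burst_rate_hz * nb_duration, size=n_recruit)
        for ch, lat, k in zip(recruited, latency, counts):
            t = t0 + lat + np.concatenate([[0.0], rng.uniform(0.0, nb_duration, size=k)])
            extra_ch.append(np.full(k + 1, ch))
            extra_t.append(t)
        truth.planted_nb_times.append(float(t0))
        truth.planted_nb_origin.append((float(origin[0]), float(origin[1])))
    if extra_ch:
        channels = np.concatenate([base.channels, *extra_ch])
        times = np.concatenate([base.times, *extra_t])
    else:
        channels, times = base.channels, base.times
    times = np.clip(times, 0.0, np.nextafter(base.duration, 0.0))
    out = SpikeTrainSet(channels, times, base.duration, geometry, label=base.label)
    truth.validate()
    return out, truth


def plant_correlations(
    base: SpikeTrainSet,
    pairs: Sequence[tuple[int, int]],
    jitter: float = 0.002,
    copy_prob: float = 0.7,
    seed: int = 0,
) -> tuple[SpikeTrainSet, SyntheticGroundTruth]:
    """Plant pairwise correlations by probabilistic spike copying.

    For each (source, target) pair every source spike is copied to the
    target with probability ``copy_prob`` and Gaussian timing jitter of SD
    ``jitter`` seconds, producing a detectable near-zero-lag correlation.
    """
    if jitter < 0:
        raise ValidationError("jitter must be non-negative")
    if not 0 <= copy_prob <= 1:
        raise ValidationError("copy_prob must lie in [0, 1]")
    n_ch = base.geometry.n_channels
    for a, b in pairs:
        if not (0 <= a < n_ch and 0 <= b < n_ch):
            raise ValidationError(f"pair ({a}, {b}) references unknown channel")
        if a == b:
            raise ValidationError("cannot plant a self-correlation")
    rng = np.random.default_rng(seed)
    extra_ch: list[np.ndarray] = []
    extra_t: list[np.ndarray] = []
    for src, tgt in pairs:
        src_times = base.channel_times(src)
        keep = rng.random(src_times.size) < copy_prob
        copied = src_times[keep]
        if jitter > 0:
            copied = copied + rng.normal(0.0, jitter, size=copied.size)
        copied = copied[(copied >= 0) & (copied < base.duration)]
        extra_ch.append(np.full(copied.size, tgt))
        extra_t.append(copied)
    truth = SyntheticGroundTruth(planted_graph={tuple(sorted(p)) for p in pairs})
    truth.validate()
    if copy_prob == 0:
        return base, truth
    channels = np.concatenate([base.channels, *extra_ch])
    times = np.concatenate([base.times, *extra_t])
    out = SpikeTrainSet(channels, times, base.duration, base.geometry, label=base.label)
    return out, truth


# --- stimulation sessions ---------------------------------------------------

ResponseKernel = Callable[[np.ndarray, float], np.ndarray]
"""Evoked-rate kernel: (distances_um, latency_s) -> added rate in Hz per channel.

Positive values add evoked spikes on top of baseline; negative values
suppress baseline firing.  Evaluated on a 1 ms latency grid over the
post-stimulus window.
"""


def null_kernel(dist_um: np.ndarray, latency_s: float) -> np.ndarray:
    """No evoked response anywhere."""
    return np.zeros_like(dist_um, dtype=float)


def gaussian_response_kernel(
    amplitude_hz: float = 200.0,
    latency_mean_s: float = 0.008,
    latency_sd_s: float = 0.002,
    dist_scale_um: float = 150.0,
    speed_um_per_s: float = 0.0,
) -> ResponseKernel:
    """Excitatory response decaying with distance, peaked at a latency.

    With ``speed_um_per_s`` > 0 the spatial footprint widens linearly with
    latency (an activation radius growing over time), which makes the
    dispersion of responses increase across latency bins.
    """

    def kernel(dist_um: np.ndarray, latency_s: float) -> np.ndarray:
        scale = dist_scale_um + speed_um_per_s * latency_s
        spatial = np.exp(-0.5 * (dist_um / scale) ** 2)
        temporal = math.exp(-0.5 * ((latency_s - latency_mean_s) / latency_sd_s) ** 2)
        return amplitude_hz * spatial * temporal

    return kernel


def suppressive_kernel(
    amplitude_hz: float = 30.0,
    latency_mean_s: float = 0.05,
    latency_sd_s: float = 0.03,
    dist_scale_um: float = 200.0,
) -> ResponseKernel:
    """Inhibitory response: baseline firing is suppressed near the stimulus."""
    exc = gaussian_response_kernel(amplitude_hz, latency_mean_s, latency_sd_s, dist_scale_um)

    def kernel(dist_um: np.ndarray, latency_s: float) -> np.ndarray:
        return -exc(dist_um, latency_s)

    return kernel


def generate_stim_session(
    geometry: GridGeometry,
    stim_channels: Sequence[int],
    n_pulses: int = 25,
    kernel: ResponseKernel = null_kernel,
    baseline_rate: np.ndarray | float = 2.0,
    inter_pulse_s: float = 1.0,
    window_s: float = 0.150,
    lead_in_s: float = 1.0,
    seed: int = 0,
):
    """Simulate a stimulation session: baseline firing plus evoked responses.

    Baseline activity is homogeneous Poisson per channel.  After each pulse
    the kernel modulates each channel's rate over the post-stimulus window
    on a 1 ms grid, as a function of its distance from the nearest
    stimulated channel: positive modulation adds evoked spikes, negative
    modulation thins baseline spikes.  A net negative total rate is clipped
    at zero.

    Returns ``(session, truth)`` where session is a
    :class:`meakit.stimresp.StimulationSession` and truth flags each
    channel whose planted modulation is meaningfully positive (+1) or
    negative (-1).
    """
    from .stimresp import StimulationSession  # local import to avoid a cycle

    stim_channels = [int(c) for c in stim_channels]
    for c in stim_channels:
        if not 0 <= c < geometry.n_channels:
            raise ValidationError(f"stim channel {c} outside grid")
    if n_pulses < 1:
        raise ValidationError("need at least one pulse")
    rng = np.random.default_rng(seed)
    duration = lead_in_s + n_pulses * inter_pulse_s
    rates = np.broadcast_to(np.asarray(baseline_rate, dtype=float), (geometry.n_channels,)).copy()
    base = generate_background(geometry, duration, rates, seed=int(rng.integers(2**31)))
    pulse_times = lead_in_s + np.arange(n_pulses) * inter_pulse_s

    positions = geometry.positions()
    stim_pos = positions[stim_channels]
    dist = np.min(
        np.hypot(
            positions[:, None, 0] - stim_pos[None, :, 0],
            positions[:, None, 1] - stim_pos[None, :, 1],
        ),
        axis=1,
    )

    dt = 0.001
    lat_grid = np.arange(0.0, window_s, dt) + dt / 2
    modulation = np.stack([kernel(dist, lat) for lat in lat_grid], axis=1)  # (ch, lat)

    channels = [base.channels]
    times = [base.times]
    del_mask = np.ones(base.n_events, dtype=bool)
    pos_part = np.clip(modulation, 0.0, None)
    neg_part = np.clip(-modulation, 0.0, None)
    # thinning probability for baseline spikes under suppression
    with np.errstate(divide="ignore", invalid="ignore"):
        thin_p = np.where(rates[:, None] > 0, np.minimum(neg_part / rates[:, None], 1.0), 0.0)
    any_pos = pos_part.any()
    any_neg = neg_part.any()
    for t0 in pulse_times:
        if any_pos:
            counts = rng.poisson(pos_part * dt)  # (ch, lat)
            ch_idx, lat_idx = np.nonzero(counts)
            reps = counts[ch_idx, lat_idx]
            ch_new = np.repeat(ch_idx, reps)
            lat_new = np.repeat(lat_grid[lat_idx], reps) + rng.uniform(-dt / 2, dt / 2, size=reps.sum())
            channels.append(ch_new)
            times.append(t0 + np.clip(lat_new, 0.0, window_s))
        if any_neg:
            in_win = (base.times >= t0) & (base.times < t0 + window_s)
            idx = np.flatnonzero(in_win)
            if idx.size:
                lat_bin = np.minimum(((base.times[idx] - t0) / dt).astype(int), lat_grid.size - 1)
                p = thin_p[base.channels[idx], lat_bin]
                del_mask[idx] &= rng.random(idx.size) >= p
    channels[0] = base.channels[del_mask]
    times[0] = base.times[del_mask]
    spikes = SpikeTrainSet(
        np.concatenate(channels),
        np.clip(np.concatenate(times), 0.0, np.nextafter(duration, 0.0)),
        duration,
        geometry,
    )
    session = StimulationSession(spikes=spikes, pulse_times=pulse_times, stim_channels=stim_channels)

    # planted-truth flags: channels whose expected count change over the
    # window is at least half a spike per pulse in either direction
    expected_delta = modulation.sum(axis=1) * dt
    suppressible = np.minimum(neg_part, rates[:, None]).sum(axis=1) * dt
    truth = SyntheticGroundTruth()
    for ch in range(geometry.n_channels):
        if expected_delta[ch] >= 0.5:
            truth.planted_response_channels[ch] = +1
        elif suppressible[ch] >= 0.5:
            truth.planted_response_channels[ch] = -1
    return session, truth


# --- E/I mixture scenarios --------------------------------------------------

def nb_rate_for_ei_fraction(ei_fraction: float, peak_rate_per_min: float = 6.0) -> float:
    """Network-burst rate of a synthetic culture as a function of E/I mix.

    A smooth bump peaking at intermediate excitatory fractions: cultures
    near the extremes (almost purely excitatory or purely inhibitory) burst
    rarely, mixtures burst most.  This is a fixture contract for testing
    the analysis chain, not a biological model.
    """
    if not 0 <= ei_fraction <= 1:
        raise ValidationError("ei_fraction must lie in [0, 1]")
    return peak_rate_per_min * math.exp(-0.5 * ((ei_fraction - 0.65) / 0.18) ** 2)


def ei_mixture_recording(
    ei_fraction: float,
    geometry: GridGeometry | None = None,
    duration: float = 300.0,
    seed: int = 0,
    **nb_kwargs,
) -> tuple[SpikeTrainSet, SyntheticGroundTruth]:
    """Background + network bursts at the rate implied by an E/I fraction."""
    geometry = geometry or GridGeometry()
    rng = np.random.default_rng(seed)
    rates = lognormal_rate_map(geometry, seed=int(rng.integers(2**31)))
    base = generate_background(geometry, duration, rates, seed=int(rng.integers(2**31)))
    rec, truth = generate_network_bursts(
        base,
        nb_rate=nb_rate_for_ei_fraction(ei_fraction),
        seed=int(rng.integers(2**31)),
        **nb_kwargs,
    )
    truth.ei_fraction = ei_fraction
    return rec, truth
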