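"""Izhikevich spiking-network simulation with STDP and an E/I-ratio sweep.

A 1,000-neuron recurrent network in the self-organizing-network style:
regular-spiking excitatory neurons (a=0.02, b=0.2, c=-65, d=8) and
fast-spiking inhibitory neurons (a=0.1, b=0.2, c=-65, d=2), 100 random
outgoing synapses per neuron (inhibitory synapses target excitatory
neurons only), integer conduction delays of 1-20 ms on excitatory synapses
and 1 ms on inhibitory ones, initial weights +6 / -5, additive STDP on
excitatory weights clipped to [0, weight_cap], and an external drive of
one randomly chosen neuron receiving a 20 mV kick per millisecond.

The membrane equations are integrated at dt = 1 ms with two 0.5 ms
half-steps of the voltage equation per step (the customary scheme for this
model).

The Instantaneous Network Firing (INF) metric summarizes population-level
burst-like events: population spike counts in 10 ms bins, an event being a
maximal run of bins whose count exceeds a fraction phi (default 0.1) of
the network size, and the INF rate the number of such events per minute.
Sweeping the excitatory/inhibitory split while holding everything else
fixed locates the E/I ratio that maximizes the INF rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .core import GridGeometry, SpikeTrainSet, ValidationError

# Izhikevich parameter sets
EXC_PARAMS = (0.02, 0.2, -65.0, 8.0)  # regular spiking
INH_PARAMS = (0.1, 0.2, -65.0, 2.0)  # fast spiking

DEFAULT_SWEEP_RATIOS = [(e, 1000 - e) for e in range(900, 0, -100)]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one network simulation."""

    n_neurons: int = 1000
    n_excitatory: int = 800
    synapses_per_neuron: int = 100
    delay_range_exc_ms: tuple[int, int] = (1, 20)
    delay_inh_ms: int = 1
    init_weight_exc: float = 6.0
    init_weight_inh: float = -5.0
    weight_cap: float = 10.0
    stdp_a_plus: float = 0.1
    stdp_a_minus: float = 0.12
    stdp_tau_ms: float = 20.0
    stdp_drift_per_s: float = 0.01  # constant bias added at each per-second weight update
    stdp_update_interval_ms: float = 1000.0
    stdp_derivative_decay: float = 0.9  # derivative shrink factor per update interval
    stdp_enabled: bool = True
    input_amplitude: float = 20.0  # mV kick to one random neuron per ms
    dt_ms: float = 1.0
    duration_s: float = 120.0
    warmup_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_excitatory <= self.n_neurons:
            raise ValidationError("n_excitatory must lie in [0, n_neurons]")
        if self.synapses_per_neuron >= self.n_neurons:
            raise ValidationError("synapses_per_neuron must be smaller than the network")
        if self.dt_ms <= 0 or self.duration_s <= 0 or self.warmup_s < 0:
            raise ValidationError("dt, duration must be positive; warmup non-negative")
        if self.weight_cap <= 0:
            raise ValidationError("weight_cap must be positive")


@dataclass
class SimNetwork:
    """Wired network: per-neuron model constants plus the synapse table."""

    config: SimConfig
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    targets: np.ndarray  # (N, M) int32
    weights: np.ndarray  # (N, M) float64
    delays: np.ndarray  # (N, M) int32, in dt steps

    @property
    def n_excitatory(self) -> int:
        return self.config.n_excitatory


@dataclass
class SimResult:
    """Spike raster (ms, warmup excluded) and final weights.

    ``saturated`` marks runs terminated early because the network entered
    a pathological high-rate state; ``scored_duration_s`` is the scored
    model time actually simulated (equal to ``config.duration_s`` for
    normal runs).
    """

    neuron_ids: np.ndarray
    spike_times_ms: np.ndarray
    final_weights: np.ndarray
    config: SimConfig
    saturated: bool = False
    scored_duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.scored_duration_s is None:
            self.scored_duration_s = self.config.duration_s

    @property
    def n_spikes(self) -> int:
        return int(self.neuron_ids.size)

    def to_spike_train_set(self) -> SpikeTrainSet:
        """Raster as an event table (neuron id as channel) for the MEA metrics."""
        n = self.config.n_neurons
        side = int(np.ceil(np.sqrt(n)))
        geom = GridGeometry(n_rows=side, n_cols=side, pitch=60.0)
        return SpikeTrainSet(
            self.neuron_ids,
            self.spike_times_ms / 1000.0,
            self.config.duration_s,
            geom,
            label=f"eisim {self.config.n_excitatory}:{self.config.n_neurons - self.config.n_excitatory}",
        )


@dataclass
class INFSeries:
    """Instantaneous-network-firing summary of one raster."""

    bin_ms: float
    counts: np.ndarray
    event_times_ms: np.ndarray  # peak-bin time of each event
    event_peaks: np.ndarray  # peak population count of each event
    inf_rate_per_min: float


def build_network(config: SimConfig) -> SimNetwork:
    """Wire a network: random targets, no self-connections, seed-deterministic.

    The first ``n_excitatory`` neurons are excitatory (regular-spiking
    constants) and project to any other neuron with a uniform integer delay
    in ``delay_range_exc_ms``; the rest are inhibitory (fast-spiking
    constants) and project to excitatory neurons only with a fixed 1 ms
    delay.  In the degenerate all-inhibitory case targets fall back to any
    non-self neuron.
    """
    rng = np.random.default_rng(config.seed)
    n, ne, m = config.n_neurons, config.n_excitatory, config.synapses_per_neuron
    a = np.where(np.arange(n) < ne, EXC_PARAMS[0], INH_PARAMS[0]).astype(np.float64)
    b = np.where(np.arange(n) < ne, EXC_PARAMS[1], INH_PARAMS[1]).astype(np.float64)
    c = np.where(np.arange(n) < ne, EXC_PARAMS[2], INH_PARAMS[2]).astype(np.float64)
    d = np.where(np.arange(n) < ne, EXC_PARAMS[3], INH_PARAMS[3]).astype(np.float64)

    targets = np.empty((n, m), dtype=np.int32)
    delays = np.empty((n, m), dtype=np.int32)
    weights = np.empty((n, m), dtype=np.float64)
    lo, hi = config.delay_range_exc_ms
    for i in range(n):
        if i < ne:
            pool = np.delete(np.arange(n), i)
            targets[i] = rng.choice(pool, size=m, replace=False)
            delays[i] = rng.integers(lo, hi + 1, size=m)
            weights[i] = config.init_weight_exc
        else:
            if ne > 0:
                pool = np.arange(ne)
                targets[i] = rng.choice(pool, size=m, replace=m > ne)
            else:
                pool = np.delete(np.arange(n), i)
                targets[i] = rng.choice(pool, size=m, replace=False)
            delays[i] = config.delay_inh_ms
            weights[i] = config.init_weight_inh
    return SimNetwork(config=config, a=a, b=b, c=c, d=d, targets=targets, weights=weights, delays=delays)


@njit(cache=True)
def _run_kernel(
    a, b, c, d,
    targets, weights, delays,
    in_ptr, in_src, in_syn,
    n_exc, n_steps, warmup_steps,
    input_amplitude,
    a_plus, a_minus, tau_ms, drift, update_steps, sd_decay,
    stdp_on, weight_cap,
    max_delay, drive_neurons,
    saturation_window_limit,
    out_ids, out_times, info,
):  # pragma: no cover - exercised through simulate()
    n = a.size
    m = targets.shape[1]
    n_slots = max_delay + 1
    v = np.full(n, -65.0)
    u = b * v
    buffer = np.zeros((n_slots, n))
    # pair-based STDP state: per-neuron LTP/LTD traces, per-synapse derivative
    ltp = np.zeros(n)
    ltd = np.zeros(n)
    ltp_hist = np.zeros((n_slots, n))  # trace history so delays enter the pairing
    sd = np.zeros((n_exc, m))
    decay = np.exp(-1.0 / tau_ms)
    # arrival ring: flat exc-synapse ids due for delivery at each future step
    arr_cap = n * m
    arr_syn = np.empty((n_slots, arr_cap), dtype=np.int64)
    arr_cnt = np.zeros(n_slots, dtype=np.int64)
    fired = np.empty(n, dtype=np.int64)
    n_out = 0
    window_spikes = 0  # spikes in the trailing 1,000-step saturation window
    info[0] = n_steps
    info[1] = 0
    for t in range(n_steps):
        slot = t % n_slots
        current = buffer[slot].copy()
        for k in range(n):
            buffer[slot, k] = 0.0
        current[drive_neurons[t]] += input_amplitude

        fired_count = 0
        for i in range(n):
            if v[i] >= 30.0:
                v[i] = c[i]
                u[i] += d[i]
                fired[fired_count] = i
                fired_count += 1
        for fi in range(fired_count):
            i = fired[fi]
            if t >= warmup_steps and n_out < out_ids.size:
                out_ids[n_out] = i
                out_times[n_out] = t - warmup_steps
                n_out += 1
            ltp[i] = a_plus
            ltd[i] = a_minus
            if stdp_on:
                # potentiation of incoming exc synapses: the pre trace is read
                # at the arrival time (t - delay) via the trace history ring
                for p in range(in_ptr[i], in_ptr[i + 1]):
                    src = in_src[p]
                    syn = in_syn[p]
                    dl = delays[src, syn]
                    sd[src, syn] += ltp_hist[(t - dl) % n_slots, src]
            # synaptic delivery
            for s in range(m):
                j = targets[i, s]
                dl = delays[i, s]
                dslot = (t + dl) % n_slots
                buffer[dslot, j] += weights[i, s]
                if stdp_on and i < n_exc and arr_cnt[dslot] < arr_cap:
                    arr_syn[dslot, arr_cnt[dslot]] = i * m + s
                    arr_cnt[dslot] += 1

        if stdp_on:
            # depression at spike arrival: post fired shortly before arrival
            for k in range(arr_cnt[slot]):
                flat = arr_syn[slot, k]
                src = flat // m
                syn = flat % m
                sd[src, syn] -= ltd[targets[src, syn]]
        arr_cnt[slot] = 0

        window_spikes += fired_count
        if (t + 1) % 1000 == 0:
            if window_spikes > saturation_window_limit:
                # pathological saturated state: stop integrating, score what
                # was simulated (the caller records the shortened duration)
                info[0] = t + 1
                info[1] = 1
                return n_out
            window_spikes = 0

        if stdp_on and update_steps > 0 and (t + 1) % update_steps == 0:
            for i in range(n_exc):
                for s in range(m):
                    w = weights[i, s] + drift + sd[i, s]
                    weights[i, s] = min(max(w, 0.0), weight_cap)
                    sd[i, s] *= sd_decay

        # membrane integration: two half-steps for v, one step for u
        diverged = False
        for i in range(n):
            vi = v[i]
            ui = u[i]
            ii = current[i]
            vi += 0.5 * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + ii)
            if vi < 30.0:
                vi += 0.5 * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + ii)
            if vi > 30.0:
                vi = 30.0  # peak clamp; >= 30 marks a spike at the next step
            ui += a[i] * (b[i] * vi - ui)
            if not np.isfinite(vi) or not np.isfinite(ui):
                diverged = True
            v[i] = vi
            u[i] = ui
        if diverged:
            return -t - 1  # negative step index signals divergence
        for i in range(n):
            ltp[i] *= decay
            ltd[i] *= decay
            ltp_hist[slot, i] = ltp[i]
    return n_out


def simulate(network: SimNetwork, config: SimConfig | None = None) -> SimResult:
    """Integrate the network and return the post-warmup spike raster.

    External drive delivers a 20 mV kick to one uniformly drawn neuron per
    millisecond.  With STDP enabled, excitatory weights evolve under
    additive pair-based plasticity in the self-organizing-network style:
    per-synapse derivatives accumulate potentiation when the postsynaptic
    neuron fires after a spike arrival (the presynaptic trace read at the
    arrival time, so conduction delays enter the pairing) and depression
    when an arrival lands after a recent postsynaptic spike; once per
    second the weights are nudged by the accumulated derivative plus a
    small constant drift and clipped to [0, weight_cap], and the
    derivative is shrunk.  Inhibitory weights are fixed.  Raises on
    numeric divergence.
    """
    config = config or network.config
    if config.n_neurons != network.config.n_neurons:
        raise ValidationError("config does not match the network")
    n = config.n_neurons
    n_steps = int(round((config.duration_s + config.warmup_s) * 1000.0 / config.dt_ms))
    warmup_steps = int(round(config.warmup_s * 1000.0 / config.dt_ms))
    rng = np.random.default_rng(config.seed + 1)  # drive stream distinct from wiring
    drive = rng.integers(0, n, size=n_steps).astype(np.int64)

    # reverse adjacency over excitatory synapses (for potentiation at post-spike)
    ne = config.n_excitatory
    m = network.targets.shape[1]
    exc_src = np.repeat(np.arange(ne), m)
    exc_syn = np.tile(np.arange(m), ne)
    tgt_flat = network.targets[:ne].ravel()
    order = np.argsort(tgt_flat, kind="stable")
    in_src = exc_src[order].astype(np.int64)
    in_syn = exc_syn[order].astype(np.int64)
    in_counts = np.bincount(tgt_flat, minlength=n) if ne else np.zeros(n, dtype=int)
    in_ptr = np.concatenate([[0], np.cumsum(in_counts)]).astype(np.int64)

    weights = network.weights.copy()
    max_delay = int(network.delays.max()) if network.delays.size else 1
    # raster buffer at the physical ceiling (one spike per neuron per step);
    # np.empty reserves address space lazily, so quiet runs stay cheap
    cap_events = n * max(1, n_steps - warmup_steps)
    out_ids = np.empty(cap_events, dtype=np.int32)
    out_steps = np.empty(cap_events, dtype=np.int32)
    update_steps = int(round(config.stdp_update_interval_ms / config.dt_ms))
    # early-stop guard: a sustained network-mean rate above 300 Hz over one
    # second marks a pathological saturated state (normal synchronized runs
    # average well under 20 Hz); the run is then scored on the simulated part
    sat_limit = 300.0 * n * (1000.0 * config.dt_ms / 1000.0)
    info = np.zeros(2, dtype=np.int64)
    status = _run_kernel(
        network.a, network.b, network.c, network.d,
        network.targets.astype(np.int64), weights, network.delays.astype(np.int64),
        in_ptr, in_src, in_syn,
        config.n_excitatory, n_steps, warmup_steps,
        config.input_amplitude,
        config.stdp_a_plus, config.stdp_a_minus, config.stdp_tau_ms,
        config.stdp_drift_per_s, update_steps, config.stdp_derivative_decay,
        config.stdp_enabled, config.weight_cap,
        max_delay, drive,
        sat_limit,
        out_ids, out_steps, info,
    )
    if status < 0:
        raise FloatingPointError(
            f"membrane variables diverged at step {-status - 1} "
            f"(E/I {config.n_excitatory}:{n - config.n_excitatory}, seed {config.seed})"
        )
    n_out = int(status)
    simulated_steps = int(info[0])
    scored_steps = max(simulated_steps - warmup_steps, 0)
    return SimResult(
        neuron_ids=out_ids[:n_out].astype(np.int64),
        spike_times_ms=out_steps[:n_out] * config.dt_ms,
        final_weights=weights,
        config=config,
        saturated=bool(info[1]),
        scored_duration_s=scored_steps * config.dt_ms / 1000.0,
    )


def instantaneous_network_firing(
    result: SimResult,
    bin_ms: float = 10.0,
    phi: float = 0.1,
) -> INFSeries:
    """INF events: maximal runs of bins with population count > phi * N.

    Each run contributes one event at its peak bin; the INF rate is events
    per minute of scored simulation time.
    """
    if bin_ms <= 0 or not 0 < phi <= 1:
        raise ValidationError("bin_ms must be positive and phi in (0, 1]")
    duration_ms = result.scored_duration_s * 1000.0
    n_bins = max(1, int(np.ceil(duration_ms / bin_ms)))
    if result.n_spikes:
        idx = np.minimum((result.spike_times_ms / bin_ms).astype(int), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
    else:
        counts = np.zeros(n_bins, dtype=int)
    threshold = phi * result.config.n_neurons
    hot = counts > threshold
    event_times = []
    event_peaks = []
    if hot.any():
        edges = np.flatnonzero(np.diff(np.concatenate([[0], hot.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            peak = int(s + np.argmax(counts[s:e]))
            event_times.append((peak + 0.5) * bin_ms)
            event_peaks.append(int(counts[peak]))
    minutes = result.scored_duration_s / 60.0
    rate = len(event_times) / minutes if minutes > 0 else 0.0
    return INFSeries(
        bin_ms=bin_ms,
        counts=counts,
        event_times_ms=np.asarray(event_times),
        event_peaks=np.asarray(event_peaks),
        inf_rate_per_min=rate,
    )


def ei_sweep(
    ratios: list[tuple[int, int]] | None = None,
    reps: int = 3,
    config: SimConfig | None = None,
    seed: int = 0,
    inf_bin_ms: float = 10.0,
    inf_phi: float = 0.1,
) -> pd.DataFrame:
    """INF rate across an excitatory/inhibitory ratio sweep.

    Simulates ``reps`` networks (distinct seeds) per ratio and tabulates
    mean and SD of the INF rate.  The returned frame carries the argmax
    ratio in ``df.attrs['argmax_excitatory']``.
    """
    ratios = ratios if ratios is not None else list(DEFAULT_SWEEP_RATIOS)
    template = config or SimConfig()
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rows = []
    for r_idx, (ne, ni) in enumerate(ratios):
        if ne + ni != template.n_neurons:
            raise ValidationError(f"ratio {ne}:{ni} does not sum to {template.n_neurons}")
        rates = []
        for rep in range(reps):
            run_seed = (seed * 100003 + r_idx * 1009 + rep * 7919) % (2**31)
            cfg = replace(template, n_excitatory=ne, seed=run_seed)
            net = build_network(cfg)
            res = simulate(net, cfg)
            inf = instantaneous_network_firing(res, bin_ms=inf_bin_ms, phi=inf_phi)
            rates.append(inf.inf_rate_per_min)
        rates = np.asarray(rates)
        rows.append(
            {
                "n_excitatory": ne,
                "n_inhibitory": ni,
                "inf_rate_mean": float(rates.mean()),
                "inf_rate_sd": float(rates.std(ddof=1)) if reps > 1 else 0.0,
                "reps": reps,
            }
        )
    df = pd.DataFrame(rows)
    best = int(df.loc[df["inf_rate_mean"].idxmax(), "n_excitatory"])
    df.attrs["argmax_excitatory"] = best
    return df
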