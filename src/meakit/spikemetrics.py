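"""Per-channel activity metrics: firing rate, bursts, random spikes.

A burst is a maximal run of consecutive spikes on one channel whose every
inter-spike interval is at most ``max_isi`` and which contains at least
``min_spikes`` spikes (fixed-ISI-threshold detection, the standard MEA
convention).  Spikes outside all bursts are "random spikes"; burst and
random spike counts always sum to the channel total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpikeTrainSet, ValidationError

DEFAULT_MAX_ISI = 0.1  # s
DEFAULT_MIN_SPIKES = 5
DEFAULT_MIN_RATE = 0.1  # Hz, active-channel criterion


@dataclass(frozen=True)
class BurstAnnotation:
    """One detected single-channel burst."""

    channel: int
    start: float
    end: float
    n_spikes: int


def mean_firing_rate(spike_set: SpikeTrainSet) -> np.ndarray:
    """Per-channel mean firing rate in Hz (count / recording duration)."""
    if spike_set.duration <= 0:
        raise ValidationError("duration must be positive")
    return spike_set.counts_per_channel() / spike_set.duration


def detect_active_channels(rates: np.ndarray, min_rate: float = DEFAULT_MIN_RATE) -> np.ndarray:
    """Ids of channels firing at or above ``min_rate`` Hz.

    Channels with no spikes at all are never active, so ``min_rate=0``
    selects exactly the channels with at least one spike.
    """
    if min_rate < 0:
        raise ValidationError("min_rate must be non-negative")
    rates = np.asarray(rates, dtype=float)
    return np.flatnonzero((rates >= min_rate) & (rates > 0))


def _bursts_in_train(times: np.ndarray, max_isi: float, min_spikes: int) -> list[tuple[float, float, int]]:
    """Maximal ISI-runs in one sorted spike train: (start, end, n_spikes)."""
    if times.size < min_spikes:
        return []
    # break points where the gap exceeds the threshold
    breaks = np.flatnonzero(np.diff(times) > max_isi)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [times.size - 1]])
    out = []
    for s, e in zip(starts, ends):
        n = e - s + 1
        if n >= min_spikes:
            out.append((float(times[s]), float(times[e]), int(n)))
    return out


def detect_bursts(
    spike_set: SpikeTrainSet,
    max_isi: float = DEFAULT_MAX_ISI,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> list[BurstAnnotation]:
    """Fixed-ISI-threshold burst detection on every channel.

    Returns time-ordered, per-channel disjoint annotations.
    """
    if max_isi <= 0:
        raise ValidationError("max_isi must be positive")
    if min_spikes < 2:
        raise ValidationError("a burst needs at least 2 spikes")
    bursts: list[BurstAnnotation] = []
    order = np.argsort(spike_set.channels, kind="stable")
    ch_sorted = spike_set.channels[order]
    t_sorted = spike_set.times[order]
    bounds = np.flatnonzero(np.diff(ch_sorted)) + 1
    for seg_start, seg_end in zip(
        np.concatenate([[0], bounds]), np.concatenate([bounds, [ch_sorted.size]])
    ):
        if seg_start == seg_end:
            continue
        ch = int(ch_sorted[seg_start])
        for start, end, n in _bursts_in_train(t_sorted[seg_start:seg_end], max_isi, min_spikes):
            bursts.append(BurstAnnotation(ch, start, end, n))
    bursts.sort(key=lambda b: (b.channel, b.start))
    return bursts


def summarize_channels(
    spike_set: SpikeTrainSet,
    bursts: list[BurstAnnotation],
    min_rate: float = DEFAULT_MIN_RATE,
    bursting_over_all_channels: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-channel summary plus array-level aggregates.

    Per channel: mean firing rate (Hz), activity flag, mean burst rate
    (bursts/min), mean burst duration (s), random-spike fraction (spikes
    outside all bursts over total spikes) and a bursting flag (>= 1 burst).

    Aggregates: percentage of bursting electrodes (over active channels by
    default, over the whole grid with ``bursting_over_all_channels``) and
    the mean random-spike percentage over active channels.
    """
    n_ch = spike_set.geometry.n_channels
    counts = spike_set.counts_per_channel()
    for b in bursts:
        if not 0 <= b.channel < n_ch:
            raise ValidationError(f"burst references unknown channel {b.channel}")
        if b.n_spikes > counts[b.channel]:
            raise ValidationError(f"burst on channel {b.channel} larger than its spike count")
    rates = mean_firing_rate(spike_set)
    active = detect_active_channels(rates, min_rate)
    is_active = np.zeros(n_ch, dtype=bool)
    is_active[active] = True

    n_bursts = np.zeros(n_ch, dtype=int)
    burst_spikes = np.zeros(n_ch, dtype=int)
    burst_dur_sum = np.zeros(n_ch, dtype=float)
    for b in bursts:
        n_bursts[b.channel] += 1
        burst_spikes[b.channel] += b.n_spikes
        burst_dur_sum[b.channel] += b.end - b.start

    minutes = spike_set.duration / 60.0
    mbr = n_bursts / minutes
    with np.errstate(invalid="ignore"):
        mbd = np.where(n_bursts > 0, burst_dur_sum / np.maximum(n_bursts, 1), 0.0)
        random_frac = np.where(counts > 0, (counts - burst_spikes) / np.maximum(counts, 1), 1.0)
    is_bursting = n_bursts > 0

    summary = pd.DataFrame(
        {
            "channel": np.arange(n_ch),
            "mfr_hz": rates,
            "is_active": is_active,
            "n_bursts": n_bursts,
            "mbr_per_min": mbr,
            "mbd_s": mbd,
            "burst_spikes": burst_spikes,
            "random_spikes": counts - burst_spikes,
            "random_spike_fraction": random_frac,
            "is_bursting": is_bursting,
        }
    )
    denominator = n_ch if bursting_over_all_channels else max(active.size, 1)
    bursting_active = int((is_bursting & is_active).sum()) if not bursting_over_all_channels else int(is_bursting.sum())
    aggregates = {
        "n_active_channels": int(active.size),
        "pct_bursting_electrodes": 100.0 * bursting_active / denominator,
        "mbr_per_min": float(mbr[active].mean()) if active.size else 0.0,
        "mbd_s": float(mbd[is_bursting].mean()) if is_bursting.any() else 0.0,
        "pct_random_spikes": float(100.0 * random_frac[active].mean()) if active.size else 100.0,
        "mfr_hz": float(rates[active].mean()) if active.size else 0.0,
    }
    return summary, aggregates
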