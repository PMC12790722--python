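"""Array-wide network-burst detection and centre-of-activity trajectories.

A network burst (NB) is a brief episode of synchronized firing recruiting a
large share of the array's active channels.  Detection thresholds the
binned array-wide firing rate (mean + k*SD rule) jointly with a
channel-participation requirement; nearby supra-threshold runs are merged.
The centre-of-activity trajectory (CAT) tracks, bin by bin within one NB,
the spike-count-weighted centroid of electrode positions — the physical
"centre of mass" of the propagating activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import SpikeTrainSet, ValidationError
from .spikemetrics import DEFAULT_MIN_RATE, detect_active_channels, mean_firing_rate

logger = logging.getLogger(__name__)

DEFAULT_NB_BIN = 0.025  # s
DEFAULT_SD_FACTOR = 3.0
DEFAULT_MIN_PARTICIPATION = 0.2  # fraction of active channels per bin
DEFAULT_MERGE_GAP = 0.1  # s
DEFAULT_CAT_BIN = 0.005  # s


@dataclass(frozen=True)
class NetworkBurst:
    start: float
    end: float
    participating: frozenset[int]
    peak_rate: float  # array-wide spikes/s at the hottest bin

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class CATrajectory:
    """Time-resolved activity centroid within one network burst."""

    nb: NetworkBurst
    times: np.ndarray  # bin centres, s
    points: np.ndarray  # (n, 2) centroid positions, um

    @property
    def origin(self) -> tuple[float, float]:
        """Centroid of the first non-empty bin (where the NB starts)."""
        return (float(self.points[0, 0]), float(self.points[0, 1]))

    def path_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.hypot(*np.diff(self.points, axis=0).T).sum())


def array_firing_rate(spike_set: SpikeTrainSet, bin_s: float = DEFAULT_NB_BIN) -> np.ndarray:
    """Array-wide firing rate (spikes/s) per time bin; length ceil(T/bin)."""
    if bin_s <= 0:
        raise ValidationError("bin width must be positive")
    n_bins = int(np.ceil(spike_set.duration / bin_s))
    counts = np.bincount((spike_set.times / bin_s).astype(int), minlength=n_bins)
    return counts / bin_s


def detect_network_bursts(
    spike_set: SpikeTrainSet,
    bin_s: float = DEFAULT_NB_BIN,
    sd_factor: float = DEFAULT_SD_FACTOR,
    min_participation: float = DEFAULT_MIN_PARTICIPATION,
    merge_gap: float = DEFAULT_MERGE_GAP,
    min_rate: float = DEFAULT_MIN_RATE,
) -> list[NetworkBurst]:
    """Detect network bursts from the binned array rate.

    A bin is supra-threshold when the array rate exceeds
    mean + ``sd_factor``*SD of the binned rate AND at least
    ``min_participation`` of the active channels fire in it.  Maximal runs
    of supra-threshold bins become candidate NBs; runs separated by less
    than ``merge_gap`` are merged.
    """
    if bin_s <= 0 or merge_gap < 0 or not 0 < min_participation <= 1:
        raise ValidationError("invalid network-burst parameters")
    rates = mean_firing_rate(spike_set)
    active = detect_active_channels(rates, min_rate)
    if active.size == 0:
        logger.warning("no active channels; no network bursts can be detected")
        return []

    n_bins = int(np.ceil(spike_set.duration / bin_s))
    bin_idx = np.minimum((spike_set.times / bin_s).astype(int), n_bins - 1)
    rate_series = np.bincount(bin_idx, minlength=n_bins) / bin_s
    threshold = rate_series.mean() + sd_factor * rate_series.std()

    # distinct active channels firing per bin
    active_mask = np.zeros(spike_set.geometry.n_channels, dtype=bool)
    active_mask[active] = True
    sel = active_mask[spike_set.channels]
    pair = bin_idx[sel] * np.int64(spike_set.geometry.n_channels) + spike_set.channels[sel]
    uniq = np.unique(pair)
    participation = np.bincount((uniq // spike_set.geometry.n_channels).astype(int), minlength=n_bins)

    hot = (rate_series > threshold) & (participation >= min_participation * active.size)
    if not hot.any():
        return []

    # maximal runs of hot bins
    edges = np.flatnonzero(np.diff(np.concatenate([[0], hot.view(np.int8), [0]])))
    runs = list(zip(edges[::2], edges[1::2]))  # [start_bin, end_bin) pairs

    # merge runs closer than merge_gap
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if (s - merged[-1][1]) * bin_s < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    bursts = []
    for s, e in merged:
        t0, t1 = s * bin_s, e * bin_s
        in_nb = (spike_set.times >= t0) & (spike_set.times < t1)
        participating = frozenset(np.unique(spike_set.channels[in_nb]).tolist())
        peak = float(rate_series[s:e].max())
        bursts.append(NetworkBurst(start=t0, end=min(t1, spike_set.duration), participating=participating, peak_rate=peak))
    return bursts


def network_burst_rate(bursts: list[NetworkBurst], duration: float) -> float:
    """NB rate in bursts/min."""
    return len(bursts) / (duration / 60.0)


def network_burst_duration(bursts: list[NetworkBurst], statistic: str = "mean") -> float:
    """Mean (or median) NB duration in seconds; 0 when there are no NBs."""
    if not bursts:
        return 0.0
    durations = np.array([b.duration for b in bursts])
    if statistic == "mean":
        return float(durations.mean())
    if statistic == "median":
        return float(np.median(durations))
    raise ValidationError(f"unknown NBD statistic {statistic!r}")


def center_of_activity_trajectory(
    spike_set: SpikeTrainSet,
    nb: NetworkBurst,
    cat_bin: float = DEFAULT_CAT_BIN,
) -> CATrajectory:
    """Centre-of-activity trajectory of one network burst.

    For each ``cat_bin`` within [nb.start, nb.end] the centroid is
    CA(t) = sum_i n_i(t) p_i / sum_i n_i(t), with n_i(t) the spike count of
    channel i in the bin and p_i its electrode position.  Empty bins are
    skipped.  Every point is a convex combination of electrode positions
    and therefore lies within the grid's bounding box.
    """
    if cat_bin <= 0:
        raise ValidationError("cat_bin must be positive")
    if nb.start < 0 or nb.end > spike_set.duration:
        raise ValidationError("network burst lies outside the recording")
    positions = spike_set.geometry.positions()
    mask = (spike_set.times >= nb.start) & (spike_set.times < nb.end)
    t = spike_set.times[mask]
    ch = spike_set.channels[mask]
    n_bins = max(1, int(np.ceil((nb.end - nb.start) / cat_bin)))
    idx = np.minimum(((t - nb.start) / cat_bin).astype(int), n_bins - 1)
    counts = np.zeros(n_bins)
    sx = np.zeros(n_bins)
    sy = np.zeros(n_bins)
    np.add.at(counts, idx, 1.0)
    np.add.at(sx, idx, positions[ch, 0])
    np.add.at(sy, idx, positions[ch, 1])
    nonempty = counts > 0
    centres = nb.start + (np.arange(n_bins) + 0.5) * cat_bin
    pts = np.column_stack([sx[nonempty] / counts[nonempty], sy[nonempty] / counts[nonempty]])
    return CATrajectory(nb=nb, times=centres[nonempty], points=pts)
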