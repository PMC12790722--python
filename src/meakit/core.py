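"""Core containers for HD-MEA spike-train data.

A recording is an event table of (channel, time) pairs tied to the electrode
grid it was acquired on.  Channels are integer ids laid out row-major on a
regular lattice; positions are in micrometres.  All downstream analyses
(per-channel metrics, network-burst detection, connectivity, stimulation
response) consume these containers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a container or operation contract."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular electrode lattice of an HD-MEA chip.

    Channel ids run row-major: channel ``c`` sits at row ``c // n_cols``,
    column ``c % n_cols``.  Positions are in micrometres with the origin at
    channel 0.  The default is the 64x64 = 4,096-channel layout of
    high-density CMOS arrays; pitch defaults to 60 um.
    """

    n_rows: int = 64
    n_cols: int = 64
    pitch: float = 60.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have at least one row and column")
        if self.pitch <= 0:
            raise ValidationError("electrode pitch must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def channel_position(self, channel: int) -> tuple[float, float]:
        """(x, y) position of a channel in micrometres."""
        if not 0 <= channel < self.n_channels:
            raise ValidationError(f"channel {channel} outside grid of {self.n_channels}")
        row, col = divmod(int(channel), self.n_cols)
        return (col * self.pitch, row * self.pitch)

    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (x, y) positions in micrometres."""
        idx = np.arange(self.n_channels)
        rows, cols = np.divmod(idx, self.n_cols)
        return np.column_stack((cols * self.pitch, rows * self.pitch)).astype(float)

    def distances_from(self, channel: int) -> np.ndarray:
        """Euclidean distance (um) of every channel from ``channel``."""
        pos = self.positions()
        ref = np.asarray(self.channel_position(channel))
        return np.hypot(*(pos - ref).T)

    def centroid(self) -> tuple[float, float]:
        return ((self.n_cols - 1) * self.pitch / 2.0, (self.n_rows - 1) * self.pitch / 2.0)


class SpikeTrainSet:
    """Event table of a recording: sorted (channel, time) pairs.

    Events are kept time-sorted (ties broken by channel id) in two parallel
    arrays.  Times are double-precision seconds in ``[0, duration)``.
    """

    def __init__(
        self,
        channels: np.ndarray,
        times: np.ndarray,
        duration: float,
        geometry: GridGeometry,
        label: str = "",
        validate: bool = True,
    ) -> None:
        channels = np.asarray(channels, dtype=np.int64)
        times = np.asarray(times, dtype=np.float64)
        if channels.shape != times.shape or channels.ndim != 1:
            raise ValidationError("channels and times must be 1-D arrays of equal length")
        if duration <= 0:
            raise ValidationError("duration must be positive")
        order = np.lexsort((channels, times))
        channels = channels[order]
        times = times[order]
        if validate and channels.size:
            if times[0] < 0 or times[-1] >= duration:
                bad = int(np.flatnonzero((times < 0) | (times >= duration))[0])
                raise ValidationError(
                    f"event {bad} at t={times[bad]:.6f}s outside [0, {duration}s)"
                )
            if channels.min() < 0 or channels.max() >= geometry.n_channels:
                bad = int(np.flatnonzero((channels < 0) | (channels >= geometry.n_channels))[0])
                raise ValidationError(f"event {bad} references unknown channel {channels[bad]}")
        self.channels = channels
        self.times = times
        self.duration = float(duration)
        self.geometry = geometry
        self.label = label

    @property
    def n_events(self) -> int:
        return int(self.channels.size)

    def counts_per_channel(self) -> np.ndarray:
        """Spike count per channel, length ``geometry.n_channels``."""
        return np.bincount(self.channels, minlength=self.geometry.n_channels)

    def channel_times(self, channel: int) -> np.ndarray:
        """Sorted spike times of one channel."""
        return self.times[self.channels == channel]

    def select_window(self, start: float, end: float) -> "SpikeTrainSet":
        """Events with start <= t < end, re-referenced to the window start."""
        mask = (self.times >= start) & (self.times < end)
        return SpikeTrainSet(
            self.channels[mask],
            self.times[mask] - start,
            max(end - start, np.finfo(float).tiny),
            self.geometry,
            label=self.label,
            validate=False,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels, "time_s": self.times})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrainSet):
            return NotImplemented
        return (
            self.duration == other.duration
            and self.geometry == other.geometry
            and np.array_equal(self.channels, other.channels)
            and np.array_equal(self.times, other.times)
        )

    def __repr__(self) -> str:
        return (
            f"SpikeTrainSet({self.n_events} events, {self.duration:g}s, "
            f"{self.geometry.n_rows}x{self.geometry.n_cols} grid"
            + (f", label={self.label!r})" if self.label else ")")
        )


def merge_spike_trains(a: SpikeTrainSet, b: SpikeTrainSet) -> SpikeTrainSet:
    """Concatenate two recordings on the same grid, shifting ``b`` after ``a``."""
    if a.geometry != b.geometry:
        raise ValidationError("cannot merge recordings from different grids")
    return SpikeTrainSet(
        np.concatenate([a.channels, b.channels]),
        np.concatenate([a.times, b.times + a.duration]),
        a.duration + b.duration,
        a.geometry,
        label=a.label,
    )
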