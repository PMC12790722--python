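"""Reading and writing the recording interchange formats.

Two equivalent dialects carry a recording:

* CSV with header ``channel,time_s`` (grid geometry and duration supplied
  separately or as ``# key: value`` comment lines);
* HDF5 with datasets ``/events/channel`` and ``/events/time_s`` and root
  attributes ``duration_s``, ``n_rows``, ``n_cols``, ``pitch_um``,
  ``label``.

Stimulation sessions travel as a recording plus a JSON descriptor
``{"pulse_times_s": [...], "stim_channels": [...]}``; synthetic ground
truth as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import GridGeometry, SpikeTrainSet, ValidationError
from .synthdata import SyntheticGroundTruth


def write_recording_csv(spike_set: SpikeTrainSet, path: str | Path) -> None:
    """CSV dump with geometry/duration in comment header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# duration_s: {spike_set.duration}\n")
        fh.write(f"# n_rows: {spike_set.geometry.n_rows}\n")
        fh.write(f"# n_cols: {spike_set.geometry.n_cols}\n")
        fh.write(f"# pitch_um: {spike_set.geometry.pitch}\n")
        fh.write(f"# label: {spike_set.label}\n")
        fh.write("channel,time_s\n")
        for c, t in zip(spike_set.channels.tolist(), spike_set.times.tolist()):
            fh.write(f"{c},{t!r}\n")


def read_recording_csv(
    path: str | Path,
    duration: float | None = None,
    geometry: GridGeometry | None = None,
) -> SpikeTrainSet:
    """Parse a recording CSV, validating events row by row.

    Header comments supply duration/geometry when not passed explicitly.
    Malformed or out-of-range rows are reported with their line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                break
    if duration is None:
        if "duration_s" not in meta:
            raise ValidationError(f"{path}: no duration in header and none supplied")
        duration = float(meta["duration_s"])
    if geometry is None:
        geometry = GridGeometry(
            n_rows=int(meta.get("n_rows", 64)),
            n_cols=int(meta.get("n_cols", 64)),
            pitch=float(meta.get("pitch_um", 60.0)),
        )
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(df.columns) != ["channel", "time_s"]:
        raise ValidationError(f"{path}: expected header 'channel,time_s', got {list(df.columns)}")
    ch = df["channel"].to_numpy()
    t = df["time_s"].to_numpy(dtype=float)
    first_data_line = header_lines + 2  # comments + column header, 1-based
    bad = np.flatnonzero((t < 0) | (t >= duration))
    if bad.size:
        raise ValidationError(
            f"{path} line {first_data_line + bad[0]}: time {t[bad[0]]} outside [0, {duration})"
        )
    bad = np.flatnonzero((ch < 0) | (ch >= geometry.n_channels))
    if bad.size:
        raise ValidationError(
            f"{path} line {first_data_line + bad[0]}: unknown channel {ch[bad[0]]}"
        )
    return SpikeTrainSet(ch, t, duration, geometry, label=meta.get("label", ""))


def write_recording_hdf5(spike_set: SpikeTrainSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("events")
        g.create_dataset("channel", data=spike_set.channels)
        g.create_dataset("time_s", data=spike_set.times)
        f.attrs["duration_s"] = spike_set.duration
        f.attrs["n_rows"] = spike_set.geometry.n_rows
        f.attrs["n_cols"] = spike_set.geometry.n_cols
        f.attrs["pitch_um"] = spike_set.geometry.pitch
        f.attrs["label"] = spike_set.label


def read_recording_hdf5(path: str | Path) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        geometry = GridGeometry(
            n_rows=int(f.attrs["n_rows"]),
            n_cols=int(f.attrs["n_cols"]),
            pitch=float(f.attrs["pitch_um"]),
        )
        return SpikeTrainSet(
            f["events/channel"][:],
            f["events/time_s"][:],
            float(f.attrs["duration_s"]),
            geometry,
            label=str(f.attrs.get("label", "")),
        )


def read_recording(path: str | Path, fmt: str | None = None, **kwargs) -> SpikeTrainSet:
    """Dispatch on format (or file suffix: .h5/.hdf5 vs anything else = CSV)."""
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv"
    if fmt == "hdf5":
        return read_recording_hdf5(path)
    if fmt == "csv":
        return read_recording_csv(path, **kwargs)
    raise ValidationError(f"unknown recording format {fmt!r}")


def write_recording(spike_set: SpikeTrainSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        write_recording_hdf5(spike_set, path)
    else:
        write_recording_csv(spike_set, path)


def write_ground_truth(truth: SyntheticGroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_ground_truth(path: str | Path) -> SyntheticGroundTruth:
    return SyntheticGroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_session_json(pulse_times: np.ndarray, stim_channels: list[int], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "pulse_times_s": [float(t) for t in pulse_times],
                "stim_channels": [int(c) for c in stim_channels],
            },
            indent=1,
        )
    )


def read_session_json(path: str | Path) -> tuple[np.ndarray, list[int]]:
    d = json.loads(Path(path).read_text())
    return np.asarray(d["pulse_times_s"], dtype=float), [int(c) for c in d["stim_channels"]]
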