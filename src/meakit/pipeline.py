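"""End-to-end analysis pipeline over one or many recordings.

Runs per-channel metrics, network-burst detection and functional
connectivity (plus stimulation analysis when a session is supplied) on
each input recording, writes per-recording CSVs, and aggregates a
longitudinal summary table (metric x timepoint x condition, mean +- SEM
across replicates) in the style of a days-in-vitro development study.
Every run emits a manifest with input digests, the full configuration
snapshot and all output paths, so any result can be traced to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import SpikeTrainSet, ValidationError
from .funconn import (
    DEFAULT_CORR_BIN,
    DEFAULT_MAX_LAG,
    DEFAULT_THRESHOLD,
    build_graph,
    pairwise_correlation,
)
from .netbursts import (
    detect_network_bursts,
    network_burst_duration,
    network_burst_rate,
)
from .spikemetrics import (
    DEFAULT_MAX_ISI,
    DEFAULT_MIN_RATE,
    DEFAULT_MIN_SPIKES,
    detect_bursts,
    summarize_channels,
)

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "metrics": {"max_isi", "min_spikes", "min_rate", "bursting_over_all_channels"},
    "netbursts": {"bin_s", "sd_factor", "min_participation", "merge_gap", "min_rate"},
    "connectivity": {"bin_s", "max_lag", "threshold", "min_rate"},
    "stim": {"latency_edges_ms", "n_resamples", "alpha", "baseline_s"},
    "eisim": {
        "n_neurons", "n_excitatory", "synapses_per_neuron", "duration_s", "warmup_s",
        "reps", "ratios", "inf_bin_ms", "inf_phi",
    },
    "synth": {
        "duration", "nb_rate", "nb_duration", "participation", "propagation_speed",
        "median_hz", "sigma", "n_rows", "n_cols", "pitch",
    },
}


@dataclass
class AnalysisConfig:
    """Validated per-module parameter blocks plus global settings."""

    metrics: dict = field(default_factory=dict)
    netbursts: dict = field(default_factory=dict)
    connectivity: dict = field(default_factory=dict)
    stim: dict = field(default_factory=dict)
    eisim: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "meakit_out"

    def __post_init__(self) -> None:
        for block in _KNOWN_KEYS:
            params = getattr(self, block)
            unknown = set(params) - _KNOWN_KEYS[block]
            if unknown:
                raise ValidationError(f"unknown keys in config block {block!r}: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known_top = set(_KNOWN_KEYS) | {"seed", "out_dir"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "netbursts": self.netbursts,
            "connectivity": self.connectivity,
            "stim": self.stim,
            "eisim": self.eisim,
            "synth": self.synth,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    package_version: str
    inputs: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    started_at: float = 0.0
    finished_at: float = 0.0
    completed: bool = False

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def analyse_recording(spike_set: SpikeTrainSet, config: AnalysisConfig) -> dict:
    """All spontaneous-activity metrics of one recording as a flat dict."""
    m = config.metrics
    bursts = detect_bursts(
        spike_set,
        max_isi=m.get("max_isi", DEFAULT_MAX_ISI),
        min_spikes=m.get("min_spikes", DEFAULT_MIN_SPIKES),
    )
    _, agg = summarize_channels(
        spike_set,
        bursts,
        min_rate=m.get("min_rate", DEFAULT_MIN_RATE),
        bursting_over_all_channels=m.get("bursting_over_all_channels", False),
    )
    nb_kwargs = {k: v for k, v in config.netbursts.items()}
    nbs = detect_network_bursts(spike_set, **nb_kwargs)
    result = {
        "label": spike_set.label,
        "n_events": spike_set.n_events,
        "duration_s": spike_set.duration,
        **agg,
        "nbr_per_min": network_burst_rate(nbs, spike_set.duration),
        "nbd_s": network_burst_duration(nbs),
        "n_network_bursts": len(nbs),
    }
    c = config.connectivity
    try:
        matrix = pairwise_correlation(
            spike_set,
            bin_s=c.get("bin_s", DEFAULT_CORR_BIN),
            max_lag=c.get("max_lag", DEFAULT_MAX_LAG),
            min_rate=c.get("min_rate", DEFAULT_MIN_RATE),
        )
        graph = build_graph(matrix, threshold=c.get("threshold", DEFAULT_THRESHOLD))
        result["graph_nodes"] = graph.n_nodes
        result["graph_links"] = graph.n_links
    except ValidationError as exc:
        logger.warning("connectivity skipped: %s", exc)
        result["graph_nodes"] = 0
        result["graph_links"] = 0
    return result


def run_pipeline(
    recordings: list[tuple[SpikeTrainSet, str | Path | None]],
    config: AnalysisConfig,
    conditions: list[str] | None = None,
    timepoints: list[str] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[RunManifest, pd.DataFrame]:
    """Analyse a batch of recordings and build the longitudinal summary.

    ``recordings`` pairs each loaded recording with its source path (or
    None for in-memory inputs).  ``conditions``/``timepoints`` label each
    recording for aggregation; replicates sharing a (condition, timepoint)
    pair are summarized as mean +- SEM.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), package_version=__version__, started_at=time.time())
    n = len(recordings)
    conditions = conditions or [r[0].label or f"cond{i}" for i, r in enumerate(recordings)]
    timepoints = timepoints or ["t0"] * n
    if len(conditions) != n or len(timepoints) != n:
        raise ValidationError("condition/timepoint labels must match the recording count")

    rows = []
    ok = True
    for i, ((spike_set, src), cond, tp) in enumerate(zip(recordings, conditions, timepoints)):
        entry = {"index": i, "condition": cond, "timepoint": tp}
        if src is not None:
            entry["path"] = str(src)
            entry["sha256_16"] = _digest(Path(src))
        manifest.inputs.append(entry)
        try:
            res = analyse_recording(spike_set, config)
        except Exception:
            logger.exception("stage failure on recording %d", i)
            ok = False
            break
        res.update(condition=cond, timepoint=tp, index=i)
        rows.append(res)
        logger.info(
            "recording %d (%s/%s): %d events, NBR %.2f/min, %d nodes / %d links",
            i, cond, tp, res["n_events"], res["nbr_per_min"], res["graph_nodes"], res["graph_links"],
        )
    per_rec = pd.DataFrame(rows)
    per_path = out / "per_recording.csv"
    per_rec.to_csv(per_path, index=False)
    manifest.outputs.append(str(per_path))

    summary = pd.DataFrame()
    if not per_rec.empty:
        metric_cols = [
            c for c in per_rec.columns
            if c not in {"label", "condition", "timepoint", "index"} and pd.api.types.is_numeric_dtype(per_rec[c])
        ]
        g = per_rec.groupby(["condition", "timepoint"])[metric_cols]
        summary = g.agg(["mean", "sem", "count"])
        summary.columns = ["_".join(col) for col in summary.columns]
        summary = summary.reset_index().fillna(0.0)
        sum_path = out / "longitudinal_summary.csv"
        summary.to_csv(sum_path, index=False)
        manifest.outputs.append(str(sum_path))

    manifest.finished_at = time.time()
    manifest.completed = ok
    manifest.write(out / "manifest.json")
    manifest.outputs.append(str(out / "manifest.json"))
    if not ok:
        raise RuntimeError("pipeline completed partially; see manifest")
    return manifest, summary
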