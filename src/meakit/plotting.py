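"""Figure exports: raster/array-rate panels, connectivity maps, response grids."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import SpikeTrainSet
from .funconn import FunctionalGraph
from .netbursts import array_firing_rate
from .stimresp import ResponseMap


def raster_with_rate(spike_set: SpikeTrainSet, bin_s: float = 0.025, path: str | Path | None = None):
    """Raster plot (spike times per channel) over the array firing rate."""
    fig, (ax_r, ax_f) = plt.subplots(
        2, 1, sharex=True, figsize=(10, 6), height_ratios=[3, 1], constrained_layout=True
    )
    ax_r.plot(spike_set.times, spike_set.channels, ",k", markersize=0.5)
    ax_r.set_ylabel("channel")
    rate = array_firing_rate(spike_set, bin_s)
    t = (np.arange(rate.size) + 0.5) * bin_s
    ax_f.plot(t, rate, lw=0.7, color="tab:blue")
    ax_f.set_xlabel("time (s)")
    ax_f.set_ylabel("array rate (spk/s)")
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def connectivity_map(graph: FunctionalGraph, spike_set: SpikeTrainSet, path: str | Path | None = None):
    """Nodes at electrode positions, links colored by correlation weight."""
    fig, ax = plt.subplots(figsize=(7, 7), constrained_layout=True)
    pos = spike_set.geometry.positions()
    cmap = plt.get_cmap("viridis")
    for u, v, d in graph.graph.edges(data=True):
        w = d.get("weight", 0.0)
        ax.plot(*zip(pos[u], pos[v]), color=cmap(w), lw=0.5, alpha=0.6)
    nodes = sorted(graph.nodes)
    if nodes:
        ax.plot(pos[nodes, 0], pos[nodes, 1], "o", color="gold", ms=3, mec="k", mew=0.2)
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"{graph.n_nodes} nodes, {graph.n_links} links")
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def response_grid(response_map: ResponseMap, spike_set: SpikeTrainSet, path: str | Path | None = None):
    """Per-latency-bin heatmaps of evoked response over the electrode grid."""
    geom = spike_set.geometry
    n_bins = response_map.n_bins
    fig, axes = plt.subplots(1, n_bins, figsize=(3 * n_bins, 3), constrained_layout=True)
    axes = np.atleast_1d(axes)
    vmax = max(abs(response_map.response).max(), 1e-9)
    for b, ax in enumerate(axes):
        img = response_map.response[:, b].reshape(geom.n_rows, geom.n_cols)
        ax.imshow(img, cmap="RdBu_r", vmin=-vmax, vmax=vmax, origin="lower")
        lo = response_map.latency_edges[b] * 1000
        hi = response_map.latency_edges[b + 1] * 1000
        ax.set_title(f"{lo:g}-{hi:g} ms", fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
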