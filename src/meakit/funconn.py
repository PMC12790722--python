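"""Functional connectivity from pairwise spike-train cross-correlation.

Spike trains of active channels are binned into count vectors; for each
pair the correlation index is the maximum Pearson correlation over lags up
to ``max_lag`` (in bin steps).  Thresholding the matrix yields an
undirected functional graph whose node and link counts summarize network
connectivity before/after a perturbation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import SpikeTrainSet, ValidationError
from .spikemetrics import DEFAULT_MIN_RATE, detect_active_channels, mean_firing_rate

logger = logging.getLogger(__name__)

DEFAULT_CORR_BIN = 0.05  # s
DEFAULT_MAX_LAG = 0.2  # s
DEFAULT_THRESHOLD = 0.3


@dataclass
class CorrelationMatrix:
    """Symmetric lag-maximized Pearson correlation over active channels."""

    channels: np.ndarray  # ordered active channel ids
    values: np.ndarray  # (n, n) symmetric, unit diagonal
    bin: float
    max_lag: float

    def __post_init__(self) -> None:
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValidationError("correlation matrix shape does not match channel list")


@dataclass
class FunctionalGraph:
    """Thresholded correlation graph: nodes are channels with >= 1 link."""

    graph: nx.Graph
    threshold: float
    bin: float
    max_lag: float

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def links(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()


def _binned_counts(spike_set: SpikeTrainSet, channels: np.ndarray, bin_s: float) -> np.ndarray:
    n_bins = int(np.ceil(spike_set.duration / bin_s))
    lookup = -np.ones(spike_set.geometry.n_channels, dtype=int)
    lookup[channels] = np.arange(channels.size)
    row = lookup[spike_set.channels]
    keep = row >= 0
    col = np.minimum((spike_set.times[keep] / bin_s).astype(int), n_bins - 1)
    counts = np.zeros((channels.size, n_bins))
    np.add.at(counts, (row[keep], col), 1.0)
    return counts


def _lagged_pearson_max(counts: np.ndarray, max_lag_bins: int) -> np.ndarray:
    """Max-over-lags Pearson correlation between rows of a count matrix.

    For each lag the overlapping segments are standardized exactly, so the
    result at every lag is a true Pearson coefficient.  Zero-variance rows
    correlate 0 with everything (and 1 with themselves by convention).
    """
    n, T = counts.shape
    best = np.full((n, n), -np.inf)
    zero_var = counts.std(axis=1) == 0
    if zero_var.any():
        logger.info("%d channel(s) with zero-variance counts; correlations set to 0", int(zero_var.sum()))
    for lag in range(max_lag_bins + 1):
        a = counts[:, : T - lag] if lag else counts
        b = counts[:, lag:] if lag else counts
        za = a - a.mean(axis=1, keepdims=True)
        zb = b - b.mean(axis=1, keepdims=True)
        sa = za.std(axis=1)
        sb = zb.std(axis=1)
        denom = np.outer(sa, sb) * a.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(denom > 0, za @ zb.T / denom, 0.0)
        np.maximum(best, c, out=best)  # x[t] vs y[t+lag]
        np.maximum(best, c.T, out=best)  # y[t] vs x[t+lag]
    best[zero_var, :] = 0.0
    best[:, zero_var] = 0.0
    np.fill_diagonal(best, 1.0)
    return np.clip(best, -1.0, 1.0)


def pairwise_correlation(
    spike_set: SpikeTrainSet,
    bin_s: float = DEFAULT_CORR_BIN,
    max_lag: float = DEFAULT_MAX_LAG,
    min_rate: float = DEFAULT_MIN_RATE,
) -> CorrelationMatrix:
    """Lag-maximized Pearson correlation matrix over active channels."""
    if bin_s <= 0 or max_lag < 0:
        raise ValidationError("bin and max_lag must be positive")
    rates = mean_firing_rate(spike_set)
    active = detect_active_channels(rates, min_rate)
    if active.size < 2:
        raise ValidationError("need at least two active channels for correlation")
    counts = _binned_counts(spike_set, active, bin_s)
    max_lag_bins = int(round(max_lag / bin_s))
    values = _lagged_pearson_max(counts, max_lag_bins)
    return CorrelationMatrix(channels=active, values=values, bin=bin_s, max_lag=max_lag)


def surrogate_threshold_matrix(
    spike_set: SpikeTrainSet,
    bin_s: float = DEFAULT_CORR_BIN,
    max_lag: float = DEFAULT_MAX_LAG,
    n_surrogates: int = 20,
    dither: float = 0.5,
    percentile: float = 95.0,
    min_rate: float = DEFAULT_MIN_RATE,
    seed: int = 0,
) -> np.ndarray:
    """Per-pair significance threshold from spike-time-dithered surrogates.

    Each surrogate adds uniform jitter of +-``dither`` seconds to every
    spike (wrapping at the recording boundaries), destroying fine temporal
    alignment while keeping rates; the per-pair threshold is the given
    percentile of the surrogate correlation distribution.
    """
    rng = np.random.default_rng(seed)
    rates = mean_firing_rate(spike_set)
    active = detect_active_channels(rates, min_rate)
    max_lag_bins = int(round(max_lag / bin_s))
    vals = []
    for _ in range(n_surrogates):
        jittered = np.mod(spike_set.times + rng.uniform(-dither, dither, spike_set.n_events), spike_set.duration)
        surr = SpikeTrainSet(spike_set.channels, jittered, spike_set.duration, spike_set.geometry, validate=False)
        counts = _binned_counts(surr, active, bin_s)
        vals.append(_lagged_pearson_max(counts, max_lag_bins))
    stack = np.stack(vals)
    thr = np.percentile(stack, percentile, axis=0)
    np.fill_diagonal(thr, np.inf)
    return thr


def build_graph(matrix: CorrelationMatrix, threshold: float | np.ndarray = DEFAULT_THRESHOLD) -> FunctionalGraph:
    """Threshold a correlation matrix into an undirected functional graph.

    ``threshold`` is either a scalar in (0, 1] or a per-pair matrix (e.g.
    from :func:`surrogate_threshold_matrix`).  Links are pairs with
    correlation >= threshold; nodes are the endpoints of at least one link.
    """
    if np.isscalar(threshold) and not 0 < threshold <= 1:
        raise ValidationError("threshold must lie in (0, 1]")
    g = nx.Graph()
    vals = matrix.values
    n = len(matrix.channels)
    thr = threshold if np.isscalar(threshold) else np.asarray(threshold)
    iu = np.triu_indices(n, k=1)
    tvals = thr if np.isscalar(thr) else thr[iu]
    hit = vals[iu] >= tvals
    for i, j, w in zip(iu[0][hit], iu[1][hit], vals[iu][hit]):
        g.add_edge(int(matrix.channels[i]), int(matrix.channels[j]), weight=float(w))
    scalar_thr = float(threshold) if np.isscalar(threshold) else float("nan")
    return FunctionalGraph(graph=g, threshold=scalar_thr, bin=matrix.bin, max_lag=matrix.max_lag)


def compare_conditions(pre: FunctionalGraph, post: FunctionalGraph) -> dict:
    """Node/link deltas between two conditions (e.g. before/after a drug).

    Both graphs must have been built with identical parameters.
    """
    same = pre.bin == post.bin and pre.max_lag == post.max_lag
    if np.isnan(pre.threshold) != np.isnan(post.threshold) or (
        not np.isnan(pre.threshold) and pre.threshold != post.threshold
    ):
        same = False
    if not same:
        raise ValidationError("graphs were built with different parameters")
    gained = post.links - pre.links
    lost = pre.links - post.links
    return {
        "pre_nodes": pre.n_nodes,
        "post_nodes": post.n_nodes,
        "pre_links": pre.n_links,
        "post_links": post.n_links,
        "delta_nodes": post.n_nodes - pre.n_nodes,
        "delta_links": post.n_links - pre.n_links,
        "rel_delta_nodes": (post.n_nodes - pre.n_nodes) / pre.n_nodes if pre.n_nodes else float("nan"),
        "rel_delta_links": (post.n_links - pre.n_links) / pre.n_links if pre.n_links else float("nan"),
        "gained_links": gained,
        "lost_links": lost,
    }
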