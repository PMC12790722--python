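"""Shared fixtures: small synthetic recordings generated at test time."""

import numpy as np
import pytest

from meakit.core import GridGeometry
from meakit import synthdata as sd


@pytest.fixture(scope="session")
def geometry16():
    return GridGeometry(n_rows=16, n_cols=16, pitch=60.0)


@pytest.fixture(scope="session")
def background16(geometry16):
    """Poisson background, 16x16 grid, 60 s, log-normal rates."""
    rates = sd.lognormal_rate_map(geometry16, seed=101)
    return sd.generate_background(geometry16, 60.0, rates, seed=102)


@pytest.fixture(scope="session")
def burst_recording(geometry16):
    """120 s recording with planted propagating network bursts + truth."""
    rates = sd.lognormal_rate_map(geometry16, seed=201)
    base = sd.generate_background(geometry16, 120.0, rates, seed=202)
    rec, truth = sd.generate_network_bursts(base, nb_rate=5.0, seed=203)
    return rec, truth


@pytest.fixture(scope="session")
def correlated_recording(geometry16):
    """300 s recording with 20 planted correlated channel pairs + truth."""
    rng = np.random.default_rng(301)
    chans = rng.choice(geometry16.n_channels, size=40, replace=False)
    pairs = [(int(chans[2 * i]), int(chans[2 * i + 1])) for i in range(20)]
    base = sd.generate_background(geometry16, 300.0, 2.0, seed=302)
    rec, truth = sd.plant_correlations(base, pairs, jitter=0.002, copy_prob=0.7, seed=303)
    return rec, truth


@pytest.fixture(scope="session")
def sweep_table():
    """The 9-ratio, 3-seed E/I sweep at the standard scaled-down run length.

    Session-scoped: one ~90 s computation shared by every test that needs
    the sweep profile.
    """
    from meakit import eisim

    return eisim.ei_sweep(reps=3, seed=1)
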