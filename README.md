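# meakit

Spike-train analysis for high-density microelectrode array (HD-MEA)
recordings of cortical cultures, built to characterize how the
excitatory/inhibitory (E/I) composition of a network shapes its activity.

Neuronal cultures grown on 4,096-channel (64x64) HD-MEA chips develop
spontaneous activity whose structure — single-channel bursts, array-wide
network bursts (NBs), functional connectivity, and responses to electrical
stimulation — depends strongly on the fraction of inhibitory
(GABAergic, chiefly parvalbumin-positive) neurons.  `meakit` provides the
complete computational chain for this kind of study:

- **`meakit.spikemetrics`** — per-channel metrics: mean firing rate (MFR),
  fixed-ISI-threshold burst detection, mean burst rate (MBR) and duration
  (MBD), percentage of bursting electrodes, and the fraction of "random"
  spikes outside any burst.
- **`meakit.netbursts`** — network-burst detection on the binned array
  firing rate (mean + k·SD threshold with a channel-participation
  requirement), NB rate (NBR) / duration (NBD), and centre-of-activity
  trajectories (CATs): the spike-count-weighted centroid
  CA(t) = Σᵢ nᵢ(t)·pᵢ / Σᵢ nᵢ(t) tracked through each burst.
- **`meakit.funconn`** — functional connectivity: lag-maximized Pearson
  cross-correlation between binned spike counts of active channels,
  thresholded into an undirected graph whose node and link counts are
  compared across conditions (e.g. before/after a GABA_A antagonist).
- **`meakit.stimresp`** — evoked responses: per-channel spike counts in
  5–150 ms latency bins after each pulse versus duration-matched pre-pulse
  baselines, averaged over 25 pulse repetitions with bootstrap confidence
  intervals; global response curves, the dispersion index (mean distance
  of significantly responsive channels from the stimulation site), and
  evoked-NB detection under multi-channel stimulation.
- **`meakit.eisim`** — a 1,000-neuron Izhikevich spiking network
  (regular-spiking excitatory, fast-spiking inhibitory neurons) with
  conduction delays, STDP, and a configurable E/I ratio; the Instantaneous
  Network Firing (INF) metric counts population firing events, and
  `ei_sweep` maps INF against the E/I ratio.
- **`meakit.synthdata`** — synthetic recordings with known ground truth
  (Poisson background, radially propagating planted NBs, planted pairwise
  correlations, planted stimulus-response kernels), so that every detection
  stage can be validated without external data.  It also carries the
  culture-mixture arithmetic: a mix of a 7 %-inhibitory and an
  80 %-inhibitory population at 80:20 or 50:50 contains 21.6 % or 43.5 %
  inhibitory neurons.
- **`meakit.io` / `meakit.cli` / `meakit.pipeline`** — CSV/HDF5 recording
  interchange, the `meakit` command line, and a batch pipeline producing
  longitudinal summary tables (metric × timepoint × condition,
  mean ± SEM).

## Worked example

```python
import numpy as np
from meakit.core import GridGeometry
from meakit import synthdata as sd, netbursts as nb

geometry = GridGeometry(n_rows=16, n_cols=16, pitch=60.0)
rates = sd.lognormal_rate_map(geometry, seed=201)
base = sd.generate_background(geometry, duration=120.0, rate_map=rates, seed=202)
rec, truth = sd.generate_network_bursts(base, nb_rate=5.0, seed=203)

bursts = nb.detect_network_bursts(rec)
print(f"planted {len(truth.planted_nb_times)} NBs, detected {len(bursts)}")
print(f"NBR {nb.network_burst_rate(bursts, rec.duration):.2f}/min, "
      f"NBD {nb.network_burst_duration(bursts):.3f}s")

errs = []
for t0, (ox, oy) in zip(truth.planted_nb_times, truth.planted_nb_origin):
    window = nb.NetworkBurst(t0, t0 + 0.4, frozenset(), 0.0)
    cat = nb.center_of_activity_trajectory(rec, window)
    errs.append(np.hypot(cat.origin[0] - ox, cat.origin[1] - oy))
print(f"median CAT origin error: {np.median(errs):.0f} um "
      f"({np.median(errs) / geometry.pitch:.1f} pitches)")
```

prints

```
planted 10 NBs, detected 10
NBR 5.00/min, NBD 0.310s
median CAT origin error: 46 um (0.8 pitches)
```

All ten planted network bursts are recovered (NBR matches the planted
5/min), the detected burst duration reflects the planted ~0.3 s barrage
plus its propagation tail, and across bursts the first point of the
centre-of-activity trajectory lands within about one electrode pitch of
the planted origin.

The same chain runs from the shell:

```sh
meakit synth bursts --config cfg.yaml --seed 1 --out rec.h5
meakit netbursts --in rec.h5 --out nbs.csv --cat cats.json
meakit connectivity --in rec.h5 --threshold 0.3 --out graph.json
meakit eisim sweep --reps 3 --seed 1 --out sweep.csv
```

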