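# Methods

This note documents the models, statistics and numerical choices behind
`meakit`, in the order data flows through the package.

## Data model

A recording is an event table of (channel, time) pairs on a regular
electrode lattice.  Times are double-precision seconds in `[0, duration)`;
no acquisition-clock grid is imposed, since spike-sorted event times from
different systems arrive at different resolutions.  Channel ids are
row-major over the grid; the default geometry is the 64x64 = 4,096-channel
HD-MEA layout with a 60 um pitch (the pitch is a convention — analyses
that depend on physical distance take the geometry as an explicit input).

## Per-channel metrics

Mean firing rate is spike count over recording duration.  A channel is
*active* when its rate is at least `min_rate` (default 0.1 Hz) and it has
fired at least once.  Bursts are maximal runs of same-channel spikes with
every inter-spike interval at most `max_isi` (default 100 ms) containing
at least `min_spikes` spikes (default 5) — the fixed-ISI-threshold
detector that is standard MEA practice.  Adaptive (log-ISI) detectors are
deliberately out of scope.  Spikes outside every burst are *random
spikes*; by construction burst spikes + random spikes = total spikes on
every channel, a conservation law the tests assert.  The percentage of
bursting electrodes is computed over active channels (a flag switches the
denominator to the whole grid).

## Network bursts and centre-of-activity trajectories

The array firing rate is binned at 25 ms.  A bin is part of a network
burst (NB) when (a) the array rate exceeds mean + 3 SD of the binned rate
and (b) at least 20 % of the active channels fire in the bin.  Maximal
supra-threshold runs closer than 100 ms are merged.  NB rate is bursts
per minute; NB duration is the mean (optionally median) of end - start.
All four parameters are conventions exposed in configuration; none is
canonical in the literature, and the synthetic fixtures are used to show
the defaults recover planted bursts with recall >= 0.9 and a
false-positive rate <= 0.2/min on pure Poisson activity.

Within one NB the centre of activity at time bin t (default 5 ms) is the
spike-count-weighted centroid of electrode positions,
CA(t) = Σᵢ nᵢ(t) pᵢ / Σᵢ nᵢ(t).  Each point is a convex combination of
electrode positions and therefore lies inside the grid hull; empty bins
are skipped.  The trajectory origin is the CA of the first non-empty bin.
Because detected NB boundaries are quantized to the 25 ms detection bin,
a detected burst's first 5 ms bin can precede the physical onset and
contain only background spikes; when scoring origin recovery against
planted ground truth the package therefore evaluates the CAT on the known
burst window and summarizes the error as a median over bursts.

## Functional connectivity

Active channels' spike trains are binned at 50 ms; for each pair the
correlation index is the maximum Pearson correlation over integer-bin
lags up to 200 ms, each lag computed exactly on the overlapping segments.
Zero-variance channels correlate 0 by convention (logged).  Links are
pairs at or above a threshold (default 0.3); nodes are endpoints of at
least one link.  Because the field does not agree on a single index, a
surrogate-based alternative is provided (spike-time dithering, 20
surrogates, per-pair 95th-percentile threshold); the absolute threshold
is the default and the one the tests calibrate: on fixtures with planted
correlations (copy probability 0.7, 2 ms jitter) the default recovers
>= 80 % of planted links with <= 5 % false links.  Graph comparison across
conditions requires identical construction parameters and reports
node/link counts, deltas, and gained/lost link sets.

## Stimulation responses

For each pulse, channel and latency bin (default edges 5, 10, 20, 40, 60,
100, 150 ms post-pulse) the response statistic is the spike count in the
bin minus the count in a window of the same width immediately before the
pulse.  The width-matched baseline keeps the statistic integer-valued;
an earlier rate-scaled 145 ms baseline was rejected because sparse bins
with zero post-stimulus spikes but a nonzero scaled baseline produce
constant negative differences and a degenerate (point-mass) bootstrap
interval, inflating the false-positive rate fourfold.  Means are taken
over the pulse repetitions (25 in the standard protocol) and percentile
bootstrap confidence intervals (default 1,000 resamples, alpha = 0.05)
are formed by resampling pulses; a cell is significant when its CI
excludes zero, signed by the mean.  Measured cell-wise type-I error under
a null stimulus is ~0.04, within the 1.5-alpha design bound.  Spikes on
stimulated channels within 2 ms of a pulse are blanked (artifact
convention).  No multiple-testing correction is applied by default (the
per-cell CI is the reported statistic); a Benjamini-Hochberg option would
be a natural extension.

The global response curve sums positive significant responses per latency
bin and normalizes to 1.  The dispersion index is, per latency bin, the
mean Euclidean distance of positively significant channels from the
nearest stimulated channel; a pairwise-distance mode (mean distance among
the responsive channels themselves) is available, since both readings of
"spread of responses" appear in practice.  Evoked-NB analysis reruns the
NB detector and attributes to each pulse any NB starting within 1 s.

## Izhikevich E/I network and the INF metric

The simulator implements the self-organizing recurrent network built on
Izhikevich's two-variable neuron: dv/dt = 0.04v² + 5v + 140 - u + I,
du/dt = a(bv - u), spike at v >= 30 with reset v <- c, u <- u + d.
Excitatory neurons use regular-spiking constants (a 0.02, b 0.2, c -65,
d 8), inhibitory neurons fast-spiking constants (a 0.1, b 0.2, c -65,
d 2).  Each neuron makes 100 random outgoing synapses (no self-contacts);
inhibitory neurons target excitatory neurons only.  Excitatory conduction
delays are uniform integers in 1-20 ms, inhibitory delays 1 ms.  Initial
weights are +6 / -5 with a +10 cap.  External drive kicks one uniformly
chosen neuron by 20 mV every millisecond.  Integration is at dt = 1 ms
with two 0.5 ms half-steps of the voltage equation (the customary scheme
for this model); the voltage is clamped at the +30 mV spike peak, and
non-finite state aborts the run with diagnostics.

STDP acts on excitatory weights only, in the batched-derivative
formulation this network family uses: each neuron carries LTP/LTD traces
set to A+ = 0.1 / A- = 0.12 at its spikes and decaying with tau = 20 ms;
when a spike arrives at a synapse the derivative loses the postsynaptic
LTD trace, and when the postsynaptic neuron fires the derivative gains
the presynaptic LTP trace evaluated at the arrival time (conduction
delays enter the pairing via a trace-history ring).  Once per second each
weight moves by its accumulated derivative plus a constant +0.01 drift
and is clipped to [0, cap]; the derivative is then shrunk by 0.9.  A
first implementation using plain un-batched pair updates (no drift) left
the weight distribution essentially at its initial value on
minutes-long runs and produced no strong population events; the batched
form develops the bimodal weight distribution and synchronized population
firing this model family is known for, which is the phenomenon under
study.  With STDP disabled, weights are exactly constant.

Instantaneous Network Firing (INF) summarizes population events: spike
counts in 10 ms bins, an *event* being a maximal run of bins whose count
exceeds phi x N (N = network size), counted once at its peak; the INF
rate is events per minute of scored time.  A run whose network-mean
firing rate exceeds 300 Hz sustained over a full second (normal
synchronized runs average under 20 Hz) is declared saturated: integration
stops there and the run is scored on the simulated portion, which bounds
the cost of pathological runaway states without changing their verdict —
a continuously super-threshold raster scores as a single long event
either way.  The default phi is 0.1: an
event requires >= 10 % of the network firing within a single 10 ms bin.
A stricter phi = 0.25 was considered and rejected because at the
desk-scale run lengths used here (60 s plasticity warmup + 120 s scored)
peak bin counts reach only ~20 % of the network even at the most
synchronized E/I ratio, so the sweep profile would be identically zero;
phi = 0.1 cleanly separates the synchronized regimes from asynchronous
ones.  The maximal-run rule deliberately scores a saturated,
continuously super-threshold network as a single long event, so runaway
activity does not masquerade as a high event rate.

The E/I sweep simulates ratios 900:100 through 100:900 (step 100) of a
1,000-neuron network, three seeds per ratio, and reports mean +- SD INF
rate and the argmax ratio.  Run lengths (60 s + 120 s) are a desk-scale
choice; synchrony is still strengthening at the fully excitatory-biased
ratios at this length, but the ordering of the profile — an interior
maximum in the 500-800 excitatory range with both extremes near zero —
is already stable across seeds.  Two failure modes shape the extremes:
with too little inhibition the asynchronous high-rate state drives
runaway depression that prunes the excitatory weights (little
synchrony), and with too little excitation the network cannot sustain
recurrent activity at all.

## Synthetic-data generator

The generator is a statistical fixture, not a culture model: it draws
spikes from prescribed point processes so that each analysis stage can be
scored against known ground truth.

- *Background*: independent homogeneous Poisson trains; per-channel rates
  drawn log-normally with median 0.5 Hz (sigma 1), so ~5 % of channels
  fall below the 0.1 Hz activity criterion and the active-channel split
  is exercised.  No rate distribution is canonical for cultures; this is
  a convention.
- *Network bursts*: at quasi-regular planted times, a random origin and a
  random 60 % of channels are chosen; each recruited channel fires one
  deterministic wavefront spike at onset latency distance/speed (default
  50 um/ms, within the range reported for culture-wide burst propagation)
  followed by a 100 Hz Poisson barrage for 0.3 s.  The wavefront spike
  makes the onset prescribed by the radial-latency model observable at
  5 ms CAT resolution; without it the origin would not be a recoverable
  ground truth.  Durations default to 300 s recordings.
- *Correlations*: source spikes are copied to the target channel with a
  given probability and Gaussian jitter, yielding a near-zero-lag
  correlation of known strength.
- *Stimulation*: baseline Poisson firing plus a per-channel rate
  modulation kernel (distance from the nearest stimulated channel x
  latency, evaluated on a 1 ms grid); negative kernels thin baseline
  spikes, with net-negative rates clipped at zero.  Ground-truth flags
  mark channels whose expected count change is at least 0.5 spikes per
  pulse.
- *E/I scenarios*: a fixture mapping from excitatory fraction to planted
  NB rate (a smooth bump peaking at intermediate mixtures) lets pipeline
  tests reproduce the qualitative culture-comparison shape.  This mapping
  is a test contract, not a biological claim.

What the generator does **not** emulate: refractoriness, rate
non-stationarity, spike-sorting errors, electrode noise and cross-talk,
spatially structured background correlations, and adaptation of burst
shapes over development.  Passing the recovery tests therefore
demonstrates correctness of the analysis chain under the stated
statistical assumptions, not performance on real recordings.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (numpy `default_rng`);
equal seeds give byte-identical outputs, and derived seeds are folded
below 2^31.  Tests run on 16x16 (256-channel) grids with 60-300 s
recordings, 100-seed null ensembles, and the full 27-simulation E/I
sweep; the complete suite runs in a few minutes on one CPU.
`scripts/acceptance.py --seed N --out results.json` recomputes the E/I
sweep from scratch and writes the excitatory count of the INF-maximizing
ratio.

## Known limitations

- Burst/NB detection parameters are conventions; absolute NBR/NBD values
  from real recordings depend on them and are only comparable within a
  fixed configuration.
- The correlation index ignores inhibitory (negative) coupling by
  construction (links are thresholded from above only).
- The bootstrap CI is per-cell; family-wise error over 4,096 channels x
  7 bins is not controlled by default.
- The Izhikevich network is not topographic: it has no spatial layout,
  so simulated rasters exercise the rate/burst metrics but not CAT or
  dispersion analyses.
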