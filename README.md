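# mosaicnet

Network-activity and functional-connectivity analysis for multielectrode
array (MEA) and in vivo limbic-system recordings, built for studies that
compare two groups of animals or cultures — for example a genetically
mosaic condition against littermate controls. It is aimed at
electrophysiologists who start from sorted spike times and continuous LFP
traces and want the standard battery of network metrics with planted-truth
synthetic data to validate every stage.

## What it computes

* **Spike metrics** — mean firing rate (MFR), burst detection in two
  dialects (*slice*: ≥ 3 spikes with ISI < 100 ms; *multiwell*: 50 ms
  ISI to open, 50 ms to extend, 100 ms inter-burst merge), mean bursting
  rate (MBR), mean burst duration (MBD), percentage of spikes in bursts
  (PSB), network bursts (≥ 50% of a well's channels bursting together),
  and the inclusion filters (electrodes > 0.1 Hz, ≥ 20 active channels;
  units within 2–100 Hz).
* **Synchronization index (SI)** — spike phase by linear interpolation,
  φ(t, n) = 2πn + 2π·(t − t_n)/(t_{n+1} − t_n), on 1-ms bins; pairwise
  phase-locking matrix; SI = (λ_max − λ̄_surr)/(N − λ̄_surr) ∈ [0, 1] from
  its largest eigenvalue, with an optional circular-shift surrogate
  normalisation and a cross-correlogram variant.
* **LFP analysis** — 1–120 Hz band-pass, 3-Hz notch, downsampling to
  500 Hz; band separation (δ 1–4, θ 4–8, α 8–12, β 12–25, γ 25–100 Hz)
  by 5th-order Butterworth filters; Welch band power; hard-threshold LFP
  events (+70/−40 µV, 10-ms refractory, 1-s maximum).
* **Functional connectivity** — Welch magnitude-squared coherence
  γ(x, y) = |PSD(x, y)|² / (PSD(x, x)·PSD(y, y)), band-averaged, reduced
  from electrodes to 8 region × hemisphere nodes, and screened by a
  non-parametric permutation test with amplitude-adjusted Fourier
  transform (AAFT) surrogates: an edge survives when its original
  strength beats the surrogate strength in more than 9950 of 10000 draws
  (a scaled 1000/995 desk profile is provided). Differential connectomes
  contrast the retained edge sets of two groups.
* **E/I classification** — depolarized/hyperpolarized state durations
  from mean waveforms, Ward clustering into putative excitatory and
  inhibitory units with an unclassified outlier class, and per-region
  count and firing-rate ratios.
* **Synthetic data** — Poisson and common-parent (jittered-copy) spike
  trains, LFP networks with planted band-limited coherent components,
  bimodal waveform populations, and full two-group experiments with
  known per-region rate scalings and sidecar ground truth.

## A worked example

```python
from mosaicnet import synchronization_index
from mosaicnet.synthetic import SynthConfig, gen_synchronous_trains

for jitter in (0.0, 5.0, 50.0):
    cfg = SynthConfig(seed=3, duration_s=60.0, n_channels=10,
                      base_rates_hz=5.0, sync_jitter_ms=jitter)
    res = synchronization_index(gen_synchronous_trains(cfg))
    print(f"jitter {jitter:4.0f} ms -> SI = {res.si:.3f}")
```

prints

```
jitter    0 ms -> SI = 1.000
jitter    5 ms -> SI = 0.972
jitter   50 ms -> SI = 0.530
```

With zero jitter every channel carries the same parent train, all phases
lock and the index is exactly 1; increasing jitter degrades phase
alignment and the index falls toward the level of independent Poisson
activity (below 0.2 for unrelated trains). The
`examples/` directory holds one short script per capability (spike
metrics, synchronization, LFP bands and events, connectivity with
surrogate selection, E/I classification, and the end-to-end two-group
pipeline); each prints its numbers with a line on what they mean.

A thin CLI mirrors the library (`mosaicnet simulate|spikes|sync|lfp|
connect|classify|report`); the pipeline driver `run_pipeline` persists
every intermediate table with a provenance block (config hash, versions,
seeds) and reproduces its report byte-identically under a fixed
configuration.

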