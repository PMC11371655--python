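# Methods

This note documents the models, estimators and numerical choices behind
`mosaicnet`, and what the synthetic-data generators do and do not emulate.

## Scope and data model

The package analyses two kinds of input: per-channel spike-time tables
(sorted units or threshold crossings, seconds) and multi-channel continuous
LFP traces (microvolts, with a sampling rate and a channel → region ×
hemisphere map). Spike sorting itself is out of scope — the pipeline starts
from sorted units or detected spikes. All times are seconds internally; all
intervals are half-open `[start, end)` except burst spans, whose boundaries
are themselves spike times and are therefore inclusive.

## Spike detection and filtering

Three acquisition dialects are supported: *slice* (300 Hz first-order
Butterworth high-pass, fixed −80/−90 µV threshold), *invivo* (300–6000 Hz
band-pass) and *multiwell* (100 Hz high-pass + 3500 Hz low-pass, ±4.5 SD
threshold). The hardware these dialects mirror applies analog (causal)
filters; we use zero-phase forward–backward digital filtering instead so
that detected spike times are not latency-shifted — a deliberate deviation,
documented here, that matters only for absolute-latency analyses. Threshold
crossings collapse to one spike per suprathreshold excursion, taken at the
excursion extremum, with a 1-ms dead time (configurable; the choice is a
convention, the sources are silent on it). The −80 vs −90 µV choice
("depending on noise") is automated as: −80 µV unless the trace SD exceeds
a configurable cutoff (default 15 µV), then −90 µV.

## Burst and network-burst rules

Two dialects:

* **slice** — a burst is a maximal run of ≥ 3 consecutive spikes whose
  inter-spike intervals are all *strictly below* 100 ms. The strictness is
  a literal reading of "lower than"; an ISI of exactly 100 ms breaks the
  run. `BurstDialect(strict_isi=False)` selects the inclusive reading.
* **multiwell** — a burst opens on an ISI ≤ 50 ms, extends while ISIs stay
  ≤ 50 ms, and bursts whose end-to-start gap is under the 100-ms
  inter-burst interval merge. Merge order is not specified by the rule's
  three parameters; merging is applied after initial burst closure in one
  left-to-right accumulation pass, which is already the fix-point. Spike
  counts of merged bursts are recounted over the merged interval.

Burst statistics: MBR in bursts/min, MBD the mean of (last − first spike
time), PSB the percentage of spikes inside bursts (missing, not zero, for a
silent channel). A network burst is a maximal interval in which at least
50% of a well's channels have an ongoing burst; bursts touching
end-to-start count as overlapping.

Inclusion filters: electrodes firing strictly above 0.1 Hz count as active;
a recording with fewer than 20 active channels is flagged as discarded (the
data is kept so the flag can be inspected). Sorted units with average rates
outside [2, 100] Hz are excluded.

## Synchronization index

The instantaneous phase of a spike train on a regular 1-ms grid is

φ(t, n) = 2πn + 2π·(t − t_n)/(t_{n+1} − t_n),  t_n ≤ t < t_{n+1},

so phase advances exactly 2π per spike; bins outside the first/last spike
are invalid. Pairwise synchrony is the phase-locking value
|⟨e^{i(φ_i−φ_j)}⟩| over bins valid on both channels. The global SI is the
eigenvalue-based index

SI = (λ_max − λ̄_surr) / (N − λ̄_surr), clipped to [0, 1],

with λ_max the largest eigenvalue of the N×N phase-locking matrix and
λ̄_surr the mean largest eigenvalue over surrogate matrices obtained by
circularly time-shifting each channel's phase series (each by an
independent uniform offset; 100 surrogates by default, seeded). With no
surrogates, the normalisation falls back to λ̄_surr = 1, which gives SI = 0
for an identity matrix and SI = 1 for full synchrony. The eigenvalue
construction is the standard reading of an "identify clusters of locally
synchronized neurons" index with range [0, 1]; the exact aggregation used
upstream of this package is not published, so both the fallback and the
surrogate-normalised forms are exposed. Per-channel participation in the
dominant synchronous cluster is reported as the leading-eigenvector weights.

A cross-correlogram variant (`xcorr_sync_index`) bins trains (10-ms bins,
±100-ms lags by default — conventions, exposed as parameters), takes the
maximum of the normalised cross-correlogram per pair, and aggregates with
the same eigenvalue construction. Silent channels yield missing entries.

## LFP processing

In vivo wideband signals are band-passed to 1–120 Hz (5th-order
Butterworth, zero-phase), notched with a 3-Hz-wide IIR notch at the line
frequency (default 50 Hz, the power grid of the emulated recordings;
override for 60-Hz mains) and downsampled to 500 Hz with a polyphase
anti-aliasing resampler. Band separation uses zero-phase 5th-order
Butterworth band-passes at δ 1–4, θ 4–8, α 8–12, β 12–25, γ 25–100 Hz.
Band power is the mean Welch PSD over the band (2-s Hann windows, 50%
overlap — chosen so the δ band has ≥ 2 cycles per window; configurable).

LFP events are detected on 150-Hz low-passed traces (Chebyshev type I,
4th order, 0.5 dB ripple — the type and ripple are common acquisition
defaults, the source specifies only "Chebyshev, fourth order") with a hard
double threshold: an event opens above +70 µV or below −40 µV, closes on
return within thresholds or at the 1-s maximum duration, and new events
are blocked for the 10-ms refractory period. A sustained suprathreshold
plateau therefore splits into consecutive 1-s events separated by
refractory gaps.

## Coherence connectivity and the surrogate permutation test

Edge strength between two channels is the Welch magnitude-squared
coherence γ(x,y) = |PSD(x,y)|² / (PSD(x,x)·PSD(y,y)), averaged over the
band. Electrode-level matrices are reduced to region level (4 areas × 2
hemispheres) by averaging strengths over electrode pairs spanning the two
regions (self-pairs excluded; within-region entries average the distinct
unordered pairs).

Edges are screened with a non-parametric permutation test. Each draw
replaces *every* electrode with an independent AAFT surrogate —
Gaussianize by rank, randomize Fourier phases, remap the original sorted
amplitudes — which preserves the amplitude distribution exactly and the
power spectrum approximately while destroying temporal and cross-channel
alignment. The electrode coherence matrix and its region reduction are
recomputed per draw, and an edge is retained when the original strength is
≥ the surrogate strength in more than `retain_count` of `n_surrogates`
draws (defaults 9950 / 10000). Two caveats are intrinsic to the published
rule and surfaced in logs rather than silently resolved:

* the retention sentence, read literally, keeps edges whose surrogates
  *beat* the original — the inverse of a significance test. The
  significance reading is the default; `literal_reading=True` selects the
  literal one.
* 9950/10000 corresponds to a nominal p < 0.005 although the test is
  annotated p < 0.05. The printed counts are followed.

A scaled desk profile (`SurrogateParams.fast()`: 1000 surrogates,
retain > 995) keeps the same nominal level at ~10× less compute and is
what the test suite and the acceptance script use. The surrogate loop
runs on a fast path — batched AAFT draws in single precision and
band-restricted windowed DFTs via matrix products — that is verified
against `scipy.signal.coherence` to 1e-12 in the tests. Differential
connectomes are plain set differences of retained edges between groups.

## E/I classification

Each unit's mean waveform is summarised by the duration of its depolarized
state (width of the trough at half-minimum) and hyperpolarized state
(width of the after-peak at half-maximum), with sub-sample interpolation of
the crossing points; trough-to-peak time is computed as an auxiliary
feature because the state-duration definition admits more than one reading.
Ward agglomerative clustering (2 clusters) on the standardized feature pair
assigns classes; the narrow-spiking cluster is labelled inhibitory
(standard extracellular convention — the upstream description does not say
which cluster is which). Units whose Mahalanobis distance to both cluster
covariances exceeds the χ²(2) quantile at 0.975 stay unclassified
(configurable; the criterion for "unclassified" is not published).
Two safeguards keep the 2-cluster model honest: a Ward split that peels
off a tiny cluster (< max(3, 5%) of units) is treated as outliers and the
remainder re-clustered, and if the two centroids are closer than 2 pooled
within-cluster SDs the sample is treated as a single (excitatory)
population rather than fabricating an inhibitory class. Classification is
deterministic and order-invariant. Ratio reports exclude unclassified
units and leave ratios missing (never infinite) when a denominator group
is empty.

## Synthetic data: what it emulates, and what it does not

The generators plant known ground truth for every stage:

* **Poisson trains** — independent homogeneous Poisson spiking at
  configured rates; the null model for "uncoordinated" activity.
* **Common-parent synchrony** — one parent Poisson train copied to every
  channel, each spike kept with probability `sync_participation` and
  jittered by N(0, `sync_jitter_ms`). Jittered spikes falling outside the
  recording are clipped to the interval so counts are conserved at full
  participation. This is a stand-in model chosen because the SI operates on
  spike-phase alignment; no quantitative synchrony-generating model is
  published for the recordings it emulates, so its parameters are not
  calibrated to them. A coupled-oscillator model was considered and
  rejected as needlessly complex for what the tests must establish
  (monotonicity and fixed points, not biophysics).
* **LFP networks** — white noise per channel plus, per configured band
  component, one realisation of band-passed white noise (the same
  5th-order Butterworth as the analysis side, so planted and measured
  bands align) shared across its coupled channel set.
* **Waveforms** — biphasic Gaussian-lobe templates whose state durations
  are drawn from two Gaussians (excitatory 0.50/0.90 ms, inhibitory
  0.25/0.45 ms) separated by `sep` pooled SDs, with light measurement
  noise; inhibitory rates are lognormally faster.
* **Two-group experiments** — a control group at base rates and a mosaic
  group with per-region rate scalings, defaulting to 0.84/0.53/0.56/0.69
  in CA1/Amy/ERC/PRC — the mean-firing-rate reductions reported for the
  mosaic condition — over the default montage of 30 electrodes (3–4 per
  region per hemisphere), with optional extra synchrony or extra shared
  LFP components for the mosaic group. Ground truth is returned alongside
  and written as a sidecar table when persisted.

The generators reproduce the *statistical structure* the analyses are
sensitive to, not the biology: no refractoriness, rate nonstationarity,
oscillatory spiking, volume conduction, electrode geometry or 1/f LFP
background. Passing tests therefore demonstrate that the estimators
recover planted structure under their own assumptions — not that real
recordings satisfy those assumptions.

## Problem sizes and numerics

Test and demonstration runs use desk-scale sizes chosen once: 30–300 s
recordings, 2–30 channels, 1000-surrogate permutation profiles, 10-seed
grids for monotonicity properties. The null calibration of the permutation
test uses 20 independent white-noise pairs; its false-edge rate is compared
against the nominal 5% level. Numerical conventions: coherence and PLV are
clipped to [0, 1]; eigendecomposition uses the symmetric solver; missing
pairwise entries (no common valid bins, silent channels) propagate as
missing and are treated as zero locking in the eigenvalue step; AAFT
requires ≥ 64 samples and non-constant input; Welch estimation requires at
least two windows (a single window makes coherence identically 1).

## Known limitations

* The SI aggregation and the cross-correlation synchrony variant follow
  standard constructions where the upstream publications delegate details
  to references; both are flagged as selectable rather than silently fixed.
* PSB can be computed pooled across channels (default) or per-channel
  averaged; the upstream convention is unknown, both are available.
* The permutation test treats sessions as one concatenated record;
  per-session testing with aggregation is possible but not the default.
* Group-level statistics are deliberately limited to descriptive
  mean ± SEM and a two-sample t-test; the full hypothesis-testing battery
  around the published figures is out of scope.
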