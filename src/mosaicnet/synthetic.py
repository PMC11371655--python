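"""Synthetic spike trains, LFPs, waveforms and two-group experiments.

Every downstream stage is testable without external recordings: the
generators here emulate the statistical structure of limbic-system MEA
data — Poisson-like spiking with region-specific rate differences between
a mosaic and a control group, tunable pairwise spike synchrony via a
common-parent (copy-with-jitter) process, band-limited LFP oscillations
with planted cross-channel coherence, and bimodal spike-waveform width
distributions for excitatory and inhibitory populations.  Ground truth is
returned (and written as a sidecar table when persisted) so tests read the
planted parameters rather than re-deriving them.

Default conditions mirror the emulated study design: 30 electrodes over 4
limbic regions (CA1, amygdala, entorhinal and perirhinal cortex) in both
hemispheres (3-4 electrodes per region per hemisphere), 10-minute
sessions, LFPs at 500 Hz, and mosaic-group rate scalings of 0.84 / 0.53 /
0.56 / 0.69 in CA1 / Amy / ERC / PRC (the observed 16 / 47 / 44 / 31 %
mean-firing-rate reductions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    BandSpec,
    HEMISPHERES,
    LFPRecord,
    REGIONS,
    SpikeTrain,
    SpikeTrainSet,
    UnitTable,
)
from .lfp import band_filter_array

__all__ = [
    "LFPBandComponent",
    "SynthConfig",
    "default_region_map",
    "gen_poisson_trains",
    "gen_synchronous_trains",
    "gen_lfp_network",
    "gen_unit_waveforms",
    "gen_two_group_experiment",
    "TwoGroupExperiment",
]

#: Mosaic-group multiplicative rate factors per region (1 - observed MFR reduction).
MOSAIC_RATE_SCALE = {"CA1": 0.84, "Amy": 0.53, "ERC": 0.56, "PRC": 0.69}


def default_region_map(n_channels: int = 30) -> dict[str, tuple[str, str]]:
    """Channel -> (region, hemisphere) covering 4 regions x 2 hemispheres.

    Channels are dealt round-robin over the eight region-hemisphere slots,
    which for the default 30 channels gives 3-4 electrodes per slot.
    """
    slots = [(r, h) for h in HEMISPHERES for r in REGIONS]
    return {f"ch{i:02d}": slots[i % len(slots)] for i in range(n_channels)}


@dataclass(frozen=True)
class LFPBandComponent:
    """A band-limited oscillation shared by a set of channels."""

    band: BandSpec
    amplitude_uv: float
    channels: tuple[str, ...]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic recordings.

    ``base_rates_hz`` may be a scalar (shared by all channels) or one rate
    per channel.  ``sync_jitter_ms`` and ``sync_participation`` control the
    common-parent synchrony generator; ``group_rate_scale`` the mosaic
    group's per-region rate factors; ``lfp_bands`` the planted coherent LFP
    components.
    """

    seed: int = 0
    duration_s: float = 600.0
    n_channels: int = 30
    base_rates_hz: float | tuple[float, ...] = 5.0
    sync_jitter_ms: float = 5.0
    sync_participation: float = 1.0
    region_map: dict[str, tuple[str, str]] | None = None
    group_rate_scale: dict[str, float] = field(
        default_factory=lambda: dict(MOSAIC_RATE_SCALE)
    )
    lfp_bands: tuple[LFPBandComponent, ...] = ()
    noise_sd_uv: float = 10.0
    fs_hz: float = 500.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0.0 <= self.sync_participation <= 1.0:
            raise ValueError("sync_participation must lie in [0, 1]")
        if self.sync_jitter_ms < 0:
            raise ValueError("sync_jitter_ms must be non-negative")
        for ch, r in zip(self.channel_ids(), self.rates()):
            if r < 0:
                raise ValueError(f"channel {ch}: negative rate {r} Hz")
        for comp in self.lfp_bands:
            if comp.band.f_hi >= self.fs_hz / 2:
                raise ValueError(
                    f"band {comp.band.name} exceeds Nyquist at fs={self.fs_hz} Hz"
                )

    def channel_ids(self) -> list[str]:
        if self.region_map is not None:
            return list(self.region_map)
        return [f"ch{i:02d}" for i in range(self.n_channels)]

    def rates(self) -> np.ndarray:
        r = np.broadcast_to(
            np.asarray(self.base_rates_hz, dtype=float), (len(self.channel_ids()),)
        )
        return r.copy()

    def resolved_region_map(self) -> dict[str, tuple[str, str]]:
        return self.region_map or default_region_map(self.n_channels)


def _meta_for(config: SynthConfig, ch: str) -> dict[str, str | None]:
    rm = config.resolved_region_map()
    if ch in rm:
        region, hemi = rm[ch]
        return {"region": region, "hemisphere": hemi}
    return {"region": None, "hemisphere": None}


def gen_poisson_trains(
    config: SynthConfig, rate_scale: dict[str, float] | None = None
) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains at the configured rates.

    ``rate_scale`` optionally multiplies each channel's rate by its
    region's factor (used for the mosaic group).
    """
    rng = np.random.default_rng(config.seed)
    rm = config.resolved_region_map()
    trains = []
    for ch, rate in zip(config.channel_ids(), config.rates()):
        if rate_scale is not None:
            region = rm[ch][0] if ch in rm else None
            if region is not None:
                if region not in rate_scale:
                    raise ValueError(f"region {region!r} missing from rate scale map")
                rate = rate * rate_scale[region]
        n = rng.poisson(rate * config.duration_s)
        t = np.sort(rng.uniform(0.0, config.duration_s, size=n))
        t = np.unique(t)  # ties have probability zero but would break the container
        trains.append(
            SpikeTrain(ch, t, config.duration_s, **_meta_for(config, ch))
        )
    return SpikeTrainSet(trains, config.duration_s)


def gen_synchronous_trains(config: SynthConfig) -> SpikeTrainSet:
    """Common-parent synchronous trains (copy with jitter).

    One parent Poisson train at the mean base rate is copied to every
    channel; each copied spike is kept with probability
    ``sync_participation`` and jittered by N(0, sync_jitter_ms).  Jittered
    spikes falling outside [0, duration) are clipped to the interval so
    spike counts are conserved at participation 1.  Zero jitter and full
    participation reproduce the parent on all channels.
    """
    if len(config.channel_ids()) < 2:
        raise ValueError("need at least 2 channels for a synchronous set")
    rng = np.random.default_rng(config.seed)
    T = config.duration_s
    parent_rate = float(np.mean(config.rates()))
    n = rng.poisson(parent_rate * T)
    parent = np.unique(np.sort(rng.uniform(0.0, T, size=n)))
    jit = config.sync_jitter_ms / 1000.0
    eps = 1e-9
    trains = []
    for ch in config.channel_ids():
        keep = rng.uniform(size=parent.size) < config.sync_participation
        t = parent[keep]
        if jit > 0 and t.size:
            t = t + rng.normal(0.0, jit, size=t.size)
            t = np.clip(t, 0.0, T - eps)
        t = np.unique(np.sort(t))
        trains.append(SpikeTrain(ch, t, T, **_meta_for(config, ch)))
    return SpikeTrainSet(trains, T)


def gen_lfp_network(config: SynthConfig) -> LFPRecord:
    """Multi-channel LFP: white noise plus planted shared band components.

    Each configured :class:`LFPBandComponent` is one realisation of
    band-passed white noise (the same 5th-order Butterworth used by the
    analysis side, so planted and measured bands align), scaled to the
    requested RMS amplitude and added to every channel in its coupled set;
    those channels therefore share elevated true coherence only inside
    that band.
    """
    rng = np.random.default_rng(config.seed)
    ids = config.channel_ids()
    n = int(round(config.duration_s * config.fs_hz))
    data = rng.normal(0.0, config.noise_sd_uv, size=(len(ids), n))
    for comp in config.lfp_bands:
        shared = band_filter_array(rng.standard_normal(n), config.fs_hz, comp.band)
        rms = np.sqrt(np.mean(shared**2))
        if rms > 0:
            shared = shared * (comp.amplitude_uv / rms)
        for ch in comp.channels:
            if ch not in ids:
                raise ValueError(f"coupled channel {ch!r} not in configuration")
            data[ids.index(ch)] += shared
    rm = config.resolved_region_map()
    meta = pd.DataFrame(
        {
            "channel_id": ids,
            "region": [rm[c][0] if c in rm else None for c in ids],
            "hemisphere": [rm[c][1] if c in rm else None for c in ids],
        }
    )
    return LFPRecord(data, config.fs_hz, meta)


def _biphasic_waveform(
    depol_ms: float, hyperpol_ms: float, fs: float, n_samples: int, rng
) -> np.ndarray:
    """Trough + after-peak template with the given half-extremum widths."""
    t = np.arange(n_samples) / fs * 1000.0  # ms
    sig_d = depol_ms / 2.355  # FWHM -> Gaussian sigma
    sig_h = hyperpol_ms / 2.355
    t_trough = 0.25 * t[-1]
    # place the peak far enough that the two lobes barely overlap
    t_peak = t_trough + 2.0 * sig_d + 2.0 * sig_h + 0.1
    w = -100.0 * np.exp(-0.5 * ((t - t_trough) / sig_d) ** 2)
    w += 40.0 * np.exp(-0.5 * ((t - t_peak) / sig_h) ** 2)
    w += rng.normal(0.0, 0.5, size=n_samples)  # light measurement noise
    return w


def gen_unit_waveforms(
    n_exc: int,
    n_inh: int,
    sep: float,
    seed: int = 0,
    fs_hz: float = 30000.0,
    waveform_ms: float = 6.0,
) -> UnitTable:
    """Unit table with bimodal waveform-width populations and truth labels.

    Depolarized- and hyperpolarized-state durations are drawn from two
    Gaussians (broad-spiking excitatory: 0.50 / 0.90 ms; narrow-spiking
    inhibitory: 0.25 / 0.45 ms) whose means are separated by ``sep`` pooled
    SDs on each feature.  Firing rates are lognormal, inhibitory units
    faster on average, as in cortical recordings.
    """
    if sep <= 0:
        raise ValueError("sep must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(waveform_ms / 1000.0 * fs_hz))
    mu = {"excitatory": (0.50, 0.90), "inhibitory": (0.25, 0.45)}
    sd_d = (mu["excitatory"][0] - mu["inhibitory"][0]) / sep
    sd_h = (mu["excitatory"][1] - mu["inhibitory"][1]) / sep
    rows, wfs = [], []
    regions = list(REGIONS)
    counts = [("excitatory", n_exc), ("inhibitory", n_inh)]
    k = 0
    for label, n_units in counts:
        for _ in range(n_units):
            d = max(rng.normal(mu[label][0], sd_d), 0.05)
            h = max(rng.normal(mu[label][1], sd_h), 0.05)
            wfs.append(_biphasic_waveform(d, h, fs_hz, n_samples, rng))
            rate_mu = np.log(5.0) if label == "excitatory" else np.log(12.0)
            rows.append(
                {
                    "unit_id": f"u{k:03d}",
                    "region": regions[k % len(regions)],
                    "hemisphere": HEMISPHERES[k % 2],
                    "rate_hz": float(np.exp(rng.normal(rate_mu, 0.4))),
                    "truth_label": label,
                }
            )
            k += 1
    table = pd.DataFrame(rows, columns=["unit_id", "region", "hemisphere", "rate_hz", "truth_label"])
    return UnitTable(table, np.asarray(wfs), fs_hz)


@dataclass
class TwoGroupExperiment:
    """A matched control / mosaic synthetic experiment with ground truth."""

    control_spikes: SpikeTrainSet
    mosaic_spikes: SpikeTrainSet
    control_lfp: LFPRecord
    mosaic_lfp: LFPRecord
    ground_truth: pd.DataFrame


def gen_two_group_experiment(
    config: SynthConfig,
    mosaic_synchrony: bool = False,
    mosaic_extra_bands: tuple[LFPBandComponent, ...] = (),
) -> TwoGroupExperiment:
    """Control vs mosaic experiment with planted group differences.

    The control group fires at the base rates; the mosaic group at base
    rates scaled per region by ``config.group_rate_scale``.  With
    ``mosaic_synchrony`` the mosaic spikes come from the common-parent
    generator (emulating hypersynchrony); ``mosaic_extra_bands`` adds
    shared LFP components only to the mosaic group (hyperconnectivity).
    Per-channel ground truth (true rates for both groups) is returned as a
    table.
    """
    rm = config.resolved_region_map()
    covered = {r for r, _ in rm.values()}
    if set(REGIONS) - covered:
        raise ValueError(f"region map must cover all of {REGIONS}, missing {set(REGIONS) - covered}")
    for region in covered:
        if region not in config.group_rate_scale:
            raise ValueError(f"region {region!r} missing from group_rate_scale")

    seeds = np.random.SeedSequence(config.seed).generate_state(4)
    ctrl_cfg = replace(config, seed=int(seeds[0]) % (2**31))
    mos_cfg = replace(config, seed=int(seeds[1]) % (2**31))
    control = gen_poisson_trains(ctrl_cfg)
    if mosaic_synchrony:
        scaled = tuple(
            r * config.group_rate_scale[rm[c][0]]
            for c, r in zip(config.channel_ids(), config.rates())
        )
        mosaic = gen_synchronous_trains(replace(mos_cfg, base_rates_hz=scaled))
    else:
        mosaic = gen_poisson_trains(mos_cfg, rate_scale=config.group_rate_scale)

    lfp_ctrl = gen_lfp_network(replace(config, seed=int(seeds[2]) % (2**31)))
    lfp_mos = gen_lfp_network(
        replace(
            config,
            seed=int(seeds[3]) % (2**31),
            lfp_bands=tuple(config.lfp_bands) + tuple(mosaic_extra_bands),
        )
    )

    truth_rows = []
    for ch, rate in zip(config.channel_ids(), config.rates()):
        region, hemi = rm[ch]
        truth_rows.append(
            {
                "channel_id": ch,
                "region": region,
                "hemisphere": hemi,
                "true_rate_control_hz": rate,
                "true_rate_mosaic_hz": rate * config.group_rate_scale[region],
            }
        )
    return TwoGroupExperiment(
        control, mosaic, lfp_ctrl, lfp_mos, pd.DataFrame(truth_rows)
    )
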