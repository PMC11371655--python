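"""Spike detection and spike-train statistics.

Covers spike-band filtering (three acquisition dialects), threshold spike
detection, mean firing rate, burst detection in the slice and multiwell
dialects, network bursts, and the inclusion filters for active electrodes
and unit firing rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (
    Burst,
    BurstDialect,
    NetworkBurst,
    SpikeStats,
    SpikeTrain,
    SpikeTrainSet,
    UnitTable,
)

__all__ = [
    "filter_spike_band",
    "choose_fixed_threshold",
    "detect_spikes",
    "mean_firing_rate",
    "detect_bursts",
    "burst_stats",
    "detect_network_bursts",
    "filter_active_electrodes",
    "filter_units_by_rate",
]

# (high-pass Hz, low-pass Hz or None, Butterworth order) per acquisition dialect
_SPIKE_BANDS = {
    "slice": (300.0, None, 1),
    "invivo": (300.0, 6000.0, 3),
    "multiwell": (100.0, 3500.0, 2),
}


def filter_spike_band(trace: np.ndarray, fs: float, dialect: str = "slice") -> np.ndarray:
    """Restrict a raw trace to the spike band of the given dialect.

    slice: 300 Hz first-order high-pass; invivo: 300-6000 Hz band-pass;
    multiwell: 100 Hz high-pass plus 3500 Hz low-pass.  Filtering is
    zero-phase (forward-backward) so spike times are not latency-shifted,
    a deliberate digital stand-in for the analog acquisition filters.
    """
    if dialect not in _SPIKE_BANDS:
        raise ValueError(f"unknown dialect {dialect!r}")
    hp, lp, order = _SPIKE_BANDS[dialect]
    nyq = fs / 2.0
    if lp is not None and lp >= nyq:
        raise ValueError(
            f"sampling rate {fs} Hz too low for the {dialect} band (needs > {2 * lp} Hz)"
        )
    if hp >= nyq:
        raise ValueError(f"sampling rate {fs} Hz too low for a {hp} Hz high-pass")
    trace = np.asarray(trace, dtype=float)
    if lp is None:
        sos = signal.butter(order, hp, btype="highpass", fs=fs, output="sos")
    else:
        sos = signal.butter(order, [hp, lp], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, trace)


def choose_fixed_threshold(
    trace: np.ndarray,
    quiet_uv: float = -80.0,
    noisy_uv: float = -90.0,
    noise_sd_cutoff_uv: float = 15.0,
) -> float:
    """Pick the fixed detection threshold depending on the noise level.

    Uses ``quiet_uv`` unless the trace standard deviation exceeds
    ``noise_sd_cutoff_uv``, in which case the more conservative ``noisy_uv``
    is used.
    """
    return noisy_uv if float(np.std(trace)) > noise_sd_cutoff_uv else quiet_uv


def detect_spikes(
    trace: np.ndarray,
    fs: float,
    mode: str = "fixed",
    threshold: float = -80.0,
    dead_time_ms: float = 1.0,
    channel_id: str = "ch0",
    **train_meta,
) -> SpikeTrain:
    """Threshold crossing detection on a spike-band trace.

    ``fixed`` mode detects negative-going crossings of ``threshold`` (uV,
    negative).  ``sd`` mode detects crossings of +-``threshold`` * SD(trace)
    in either polarity.  Each suprathreshold excursion yields one spike at
    its extremum; excursions within ``dead_time_ms`` of the previous spike
    are discarded.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    if mode == "fixed":
        if threshold >= 0:
            raise ValueError("fixed-mode threshold must be negative (uV)")
        above = trace <= threshold
    elif mode == "sd":
        if threshold <= 0:
            raise ValueError("sd-mode threshold must be a positive SD multiple")
        lim = threshold * float(np.std(trace))
        above = np.abs(trace) >= lim if lim > 0 else np.zeros(trace.shape, bool)
    else:
        raise ValueError(f"unknown detection mode {mode!r}")

    # run boundaries: indices where excursions start / end
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive

    dead = dead_time_ms / 1000.0
    times = []
    last = -np.inf
    for s, e in zip(run_starts, run_ends):
        seg = trace[s:e]
        idx = s + int(np.argmax(np.abs(seg)))
        t = idx / fs
        if t - last >= dead:
            times.append(t)
            last = t
    duration = len(trace) / fs
    return SpikeTrain(
        channel_id=channel_id,
        times_s=np.asarray(times),
        duration_s=duration,
        **train_meta,
    )


def mean_firing_rate(spike_set: SpikeTrainSet) -> tuple[pd.Series, float]:
    """Per-channel firing rate (Hz) and their unweighted mean."""
    if len(spike_set) == 0:
        raise ValueError("cannot compute MFR of an empty spike-train set")
    rates = pd.Series(
        {tr.channel_id: tr.rate_hz for tr in spike_set}, name="mfr_hz", dtype=float
    )
    return rates, float(rates.mean())


def _slice_bursts(train: SpikeTrain, d: BurstDialect) -> list[Burst]:
    t = train.times_s
    if t.size < d.min_spikes:
        return []
    isi_max = d.isi_max_ms / 1000.0
    isis = np.diff(t)
    ok = isis < isi_max if d.strict_isi else isis <= isi_max
    bursts = []
    i = 0
    n = ok.size
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            n_spk = j - i + 1  # run of ISIs [i, j) spans spikes i..j
            if n_spk >= d.min_spikes:
                bursts.append(Burst(train.channel_id, float(t[i]), float(t[j]), n_spk))
            i = j
        else:
            i += 1
    return bursts


def _multiwell_bursts(train: SpikeTrain, d: BurstDialect) -> list[Burst]:
    t = train.times_s
    if t.size < 2:
        return []
    isi_start = d.isi_start_ms / 1000.0
    isi_end = d.isi_end_ms / 1000.0
    ibi_min = d.ibi_min_ms / 1000.0
    isis = np.diff(t)
    raw: list[tuple[int, int]] = []  # spike index ranges, inclusive
    i = 0
    while i < isis.size:
        if isis[i] <= isi_start:
            j = i + 1
            while j < isis.size and isis[j] <= isi_end:
                j += 1
            raw.append((i, j))  # spikes i..j
            i = j + 1
        else:
            i += 1
    raw = [(a, b) for a, b in raw if b - a + 1 >= d.min_spikes]
    if not raw:
        return []
    # merge bursts whose end-to-start gap is below the inter-burst interval;
    # a single left-to-right accumulation reaches the fixpoint
    merged: list[list[int]] = [list(raw[0])]
    for a, b in raw[1:]:
        if t[a] - t[merged[-1][1]] < ibi_min:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        n_spk = int(np.sum((t >= t[a]) & (t <= t[b])))
        out.append(Burst(train.channel_id, float(t[a]), float(t[b]), n_spk))
    return out


def detect_bursts(train: SpikeTrain, dialect: BurstDialect) -> list[Burst]:
    """Detect bursts on one spike train.

    Slice dialect: maximal runs of at least ``min_spikes`` spikes whose
    consecutive ISIs are all below ``isi_max_ms``.  Multiwell dialect: a
    burst opens on an ISI <= ``isi_start_ms``, extends while ISIs stay
    <= ``isi_end_ms``, and bursts separated by less than ``ibi_min_ms`` are
    merged.  Burst start/end are the first/last spike times; spike counts of
    merged bursts are recounted over the merged interval.
    """
    if dialect.name == "slice":
        return _slice_bursts(train, dialect)
    return _multiwell_bursts(train, dialect)


def burst_stats(bursts: list[Burst], train: SpikeTrain) -> SpikeStats:
    """Burst-rate statistics for one train.

    MBR in bursts/minute, MBD the mean burst duration in seconds, and PSB
    the percentage of the train's spikes lying inside a burst (boundary
    spikes included, as burst boundaries are themselves spike times).  PSB
    is missing for a silent train, MBD for a burst-free one.
    """
    mbr = len(bursts) / (train.duration_s / 60.0)
    mbd = float(np.mean([b.duration_s for b in bursts])) if bursts else None
    if train.n_spikes == 0:
        psb = None
    else:
        in_burst = np.zeros(train.n_spikes, dtype=bool)
        for b in bursts:
            in_burst |= (train.times_s >= b.start_s) & (train.times_s <= b.end_s)
        psb = 100.0 * float(in_burst.sum()) / train.n_spikes
    return SpikeStats(mfr_hz=train.rate_hz, mbr_per_min=mbr, mbd_s=mbd, psb_pct=psb)


def detect_network_bursts(
    spike_set: SpikeTrainSet,
    dialect: BurstDialect | None = None,
    fraction: float = 0.5,
) -> list[NetworkBurst]:
    """Detect network bursts per well.

    A network burst is a maximal interval in which at least ``fraction`` of
    the well's channels have an ongoing single-channel burst.  Bursts are
    treated as closed intervals, so bursts meeting end-to-start still count
    as overlapping.
    """
    if dialect is None:
        dialect = BurstDialect.multiwell_dialect()
    out: list[NetworkBurst] = []
    for well, wset in spike_set.by_well().items():
        n = len(wset)
        if n == 0:
            raise ValueError(f"well {well!r} has no channels")
        need = int(np.ceil(fraction * n - 1e-12))
        events = []  # (time, delta, channel); starts sort before ends at ties
        intervals = []
        for tr in wset:
            for b in detect_bursts(tr, dialect):
                events.append((b.start_s, 0, tr.channel_id))
                events.append((b.end_s, 1, tr.channel_id))
                intervals.append((b.start_s, b.end_s, tr.channel_id))
        events.sort()
        count = 0
        nb_start = None
        for t, kind, _ch in events:
            if kind == 0:
                count += 1
                if count == need and nb_start is None:
                    nb_start = t
            else:
                count -= 1
                if count == need - 1 and nb_start is not None:
                    chans = frozenset(
                        c for s, e, c in intervals if s <= t and e >= nb_start
                    )
                    out.append(NetworkBurst(well, nb_start, t, chans))
                    nb_start = None
    return out


def filter_active_electrodes(
    spike_set: SpikeTrainSet, min_rate_hz: float = 0.1, min_channels: int = 20
) -> SpikeTrainSet:
    """Keep channels firing strictly above ``min_rate_hz``.

    If fewer than ``min_channels`` channels survive, the returned set carries
    ``flagged_discarded=True`` (the recording as a whole fails inclusion) but
    is not an error.
    """
    kept = [tr for tr in spike_set if tr.rate_hz > min_rate_hz]
    return SpikeTrainSet(
        kept, spike_set.duration_s, flagged_discarded=len(kept) < min_channels
    )


def filter_units_by_rate(
    units: UnitTable, lo_hz: float = 2.0, hi_hz: float = 100.0
) -> UnitTable:
    """Retain units with average firing rate in [lo_hz, hi_hz] inclusive."""
    r = units.table["rate_hz"].to_numpy(dtype=float)
    return units.subset((r >= lo_hz) & (r <= hi_hz))
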