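"""LFP preprocessing, band decomposition, band power and event detection.

Band separation uses zero-phase 5th-order Butterworth band-passes at the
canonical bands (delta 1-4, theta 4-8, alpha 8-12, beta 12-25, gamma 25-100
Hz).  In vivo wideband signals are band-passed to 1-120 Hz, notched (3 Hz
width) at the line frequency and downsampled to 500 Hz.  LFP events are
detected on 150 Hz low-passed traces (4th-order Chebyshev type I) with a
hard double threshold (+70 / -40 uV), a 10-ms refractory period and a 1-s
maximum event duration.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import BandSpec, DEFAULT_BANDS, LFPEvent, LFPRecord

__all__ = [
    "preprocess_invivo",
    "band_filter",
    "band_filter_array",
    "band_power",
    "welch_psd",
    "detect_lfp_events",
]


def band_filter_array(
    x: np.ndarray, fs: float, band: BandSpec, order: int = 5
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of one or more traces (last axis)."""
    if band.f_hi >= fs / 2.0:
        raise ValueError(
            f"band {band.name} ({band.f_lo}-{band.f_hi} Hz) exceeds Nyquist ({fs / 2} Hz)"
        )
    sos = signal.butter(order, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def band_filter(lfp: LFPRecord, band: BandSpec, order: int = 5) -> LFPRecord:
    """Band-limit every channel of a record with a 5th-order Butterworth."""
    return LFPRecord(
        band_filter_array(lfp.data, lfp.fs_hz, band, order=order),
        lfp.fs_hz,
        lfp.channel_meta.copy(),
    )


def preprocess_invivo(
    raw: LFPRecord,
    line_freq_hz: float = 50.0,
    notch_width_hz: float = 3.0,
    target_fs_hz: float = 500.0,
    lfp_band: BandSpec = BandSpec("lfp", 1.0, 120.0),
) -> LFPRecord:
    """Standard in vivo LFP preprocessing.

    Band-pass to the LFP range (1-120 Hz), notch out line noise with a
    ``notch_width_hz``-wide filter, and anti-alias downsample to
    ``target_fs_hz`` (500 Hz).
    """
    fs = raw.fs_hz
    if fs < 2 * lfp_band.f_hi:
        raise ValueError(
            f"sampling rate {fs} Hz below twice the LFP band edge ({lfp_band.f_hi} Hz)"
        )
    x = band_filter_array(raw.data, fs, lfp_band, order=5)
    b, a = signal.iirnotch(line_freq_hz, line_freq_hz / notch_width_hz, fs=fs)
    x = signal.filtfilt(b, a, x, axis=-1)
    if target_fs_hz != fs:
        frac = Fraction(target_fs_hz / fs).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return LFPRecord(x, target_fs_hz, raw.channel_meta.copy())


def welch_psd(
    x: np.ndarray, fs: float, window_s: float = 2.0, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD (uV^2/Hz) with Hann windows; traces along the last axis."""
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap * nperseg))
    n = np.asarray(x).shape[-1]
    if n < nperseg + (nperseg - noverlap):
        raise ValueError(
            f"record too short for Welch estimation: {n} samples < 2 windows of {nperseg}"
        )
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, axis=-1)


def band_power(
    lfp: LFPRecord, band: BandSpec, window_s: float = 2.0, overlap: float = 0.5
) -> np.ndarray:
    """Mean Welch PSD over the band, per channel (uV^2/Hz)."""
    freqs, psd = welch_psd(lfp.data, lfp.fs_hz, window_s, overlap)
    sel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if not np.any(sel):
        raise ValueError(f"no PSD bins inside band {band.name}")
    return psd[..., sel].mean(axis=-1)


def band_power_table(
    lfp: LFPRecord,
    bands: dict[str, BandSpec] | None = None,
    window_s: float = 2.0,
    overlap: float = 0.5,
):
    """Band power of every channel for every band, as ``{band: array}``."""
    bands = bands or DEFAULT_BANDS
    return {name: band_power(lfp, b, window_s, overlap) for name, b in bands.items()}


def _lowpass_events_filter(fs: float, cutoff_hz: float, order: int, ripple_db: float):
    if fs < 2 * cutoff_hz:
        raise ValueError(f"sampling rate {fs} Hz too low for a {cutoff_hz} Hz low-pass")
    return signal.cheby1(order, ripple_db, cutoff_hz, btype="lowpass", fs=fs, output="sos")


def detect_lfp_events(
    trace: np.ndarray,
    fs: float,
    hi_uv: float = 70.0,
    lo_uv: float = -40.0,
    refractory_ms: float = 10.0,
    max_duration_s: float = 1.0,
    lowpass_hz: float = 150.0,
    cheby_order: int = 4,
    ripple_db: float = 0.5,
    channel_id: str = "ch0",
    prefiltered: bool = False,
) -> list[LFPEvent]:
    """Hard-threshold LFP event detection.

    The raw trace is low-passed at ``lowpass_hz`` (Chebyshev type I, 4th
    order, zero-phase) unless ``prefiltered``.  An event opens when the
    signal exceeds ``hi_uv`` or drops below ``lo_uv``, closes when it
    returns within the thresholds or reaches ``max_duration_s``, and new
    events are blocked for ``refractory_ms`` after each close.  ``peak_uv``
    is the signed sample of largest magnitude within the event.
    """
    if fs < 300:
        raise ValueError(f"sampling rate {fs} Hz below the 300 Hz minimum")
    x = np.asarray(trace, dtype=float)
    if not prefiltered:
        sos = _lowpass_events_filter(fs, lowpass_hz, cheby_order, ripple_db)
        x = signal.sosfiltfilt(sos, x)
    above = (x > hi_uv) | (x < lo_uv)
    max_len = int(round(max_duration_s * fs))
    refr = int(round(refractory_ms / 1000.0 * fs))

    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)

    events: list[LFPEvent] = []
    allowed_from = 0
    for rs, re_ in zip(run_starts, run_ends):
        start = max(rs, allowed_from)
        while start < re_:
            end = min(re_, start + max_len)
            seg = x[start:end]
            peak = float(seg[np.argmax(np.abs(seg))])
            events.append(
                LFPEvent(channel_id, start / fs, (end - start) / fs, peak)
            )
            allowed_from = end + refr
            start = end + refr
    return events
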