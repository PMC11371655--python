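"""Spike filtering, detection, burst rules and inclusion filters."""

import numpy as np
import pytest

from mosaicnet import (
    BurstDialect,
    burst_stats,
    detect_bursts,
    detect_network_bursts,
    detect_spikes,
    filter_active_electrodes,
    filter_spike_band,
    filter_units_by_rate,
    mean_firing_rate,
)
from mosaicnet.synthetic import SynthConfig, gen_poisson_trains, gen_unit_waveforms

from conftest import make_set, make_train

SLICE = BurstDialect.slice_dialect()
MULTI = BurstDialect.multiwell_dialect()


# ---------------------------------------------------------------------- filters
def _sine(f, fs, dur=2.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * f * t)


def test_slice_highpass_rejects_low_frequency():
    fs = 7000.0
    out = filter_spike_band(_sine(10, fs), fs, "slice")
    assert np.sqrt(np.mean(out**2)) < 0.05 * np.sqrt(0.5)


def test_invivo_bandpass_passes_1khz_within_3db():
    fs = 20000.0
    out = filter_spike_band(_sine(1000, fs, 1.0), fs, "invivo")
    # ignore filtfilt edge transients
    core = out[2000:-2000]
    gain = np.sqrt(np.mean(core**2)) / np.sqrt(0.5)
    assert 10 ** (-3 / 20) < gain < 10 ** (3 / 20)


def test_zero_trace_stays_zero():
    out = filter_spike_band(np.zeros(5000), 7000.0, "slice")
    assert np.allclose(out, 0.0)


def test_bandpass_rejected_when_fs_too_low():
    with pytest.raises(ValueError, match="too low"):
        filter_spike_band(np.zeros(1000), 7000.0, "invivo")


# ---------------------------------------------------------------- spike detection
def test_flat_trace_yields_no_spikes():
    tr = detect_spikes(np.zeros(7000), 7000.0, threshold=-80.0)
    assert tr.n_spikes == 0


def test_three_isolated_deflections_three_spikes():
    fs = 7000.0
    x = np.zeros(int(fs))
    for c in (1000, 3000, 5000):
        x[c - 3 : c + 4] = -120.0
    tr = detect_spikes(x, fs, threshold=-80.0)
    assert tr.n_spikes == 3
    assert np.allclose(tr.times_s, np.array([1000, 3000, 5000]) / fs, atol=4 / fs)


def test_sd_mode_matches_brute_force_crossing_scan(rng):
    fs = 7000.0
    x = rng.normal(0, 10, size=int(2 * fs))
    k = 4.5
    tr = detect_spikes(x, fs, mode="sd", threshold=k, dead_time_ms=1.0)
    # brute force: per-sample scan of excursions beyond +-k*SD with dead time
    lim = k * np.std(x)
    above = np.abs(x) >= lim
    times = []
    last = -np.inf
    i = 0
    while i < len(x):
        if above[i]:
            j = i
            while j < len(x) and above[j]:
                j += 1
            idx = i + int(np.argmax(np.abs(x[i:j])))
            t = idx / fs
            if t - last >= 1e-3:
                times.append(t)
                last = t
            i = j
        else:
            i += 1
    assert np.allclose(tr.times_s, times)


def test_fixed_mode_invariant_to_small_offset(rng):
    fs = 7000.0
    x = rng.normal(0, 5, size=int(fs))
    x[::500] = -120.0
    a = detect_spikes(x, fs, threshold=-80.0)
    b = detect_spikes(x + 3.0, fs, threshold=-80.0)
    assert np.array_equal(a.times_s, b.times_s)


def test_nonfinite_trace_rejected():
    with pytest.raises(ValueError, match="non-finite"):
        detect_spikes(np.array([0.0, np.nan, 0.0]), 7000.0)


# ------------------------------------------------------------------------- MFR
def test_mfr_arithmetic():
    s = make_set([np.arange(100) * 0.1, np.arange(20) * 0.5 + 0.01], duration=10.0)
    per, avg = mean_firing_rate(s)
    assert per.iloc[0] == pytest.approx(10.0)
    assert per.iloc[1] == pytest.approx(2.0)
    assert avg == pytest.approx(6.0)


def test_mfr_of_poisson_set_within_3se():
    cfg = SynthConfig(seed=7, duration_s=100.0, n_channels=50, base_rates_hz=10.0)
    _, avg = mean_firing_rate(gen_poisson_trains(cfg))
    se = np.sqrt(10.0 / 100.0 / 50)  # SD of the mean rate estimate
    assert abs(avg - 10.0) < 3 * se


def test_mfr_empty_set_rejected():
    with pytest.raises(ValueError):
        mean_firing_rate(make_set([]))


# ----------------------------------------------------------------------- bursts
@pytest.mark.parametrize(
    "times, n_bursts",
    [
        ([0.0, 0.05, 0.10], 1),  # 3 spikes, ISIs below the bound
        ([0.0, 0.05], 0),  # fewer than 3 consecutive spikes
        (np.arange(10) * 0.2, 0),  # 200-ms ISIs are not below 100 ms
        ([0.0, 0.1, 0.2], 0),  # exactly 100 ms: strict bound breaks the run
    ],
)
def test_slice_burst_rule(times, n_bursts):
    bursts = detect_bursts(make_train(times), SLICE)
    assert len(bursts) == n_bursts


def test_slice_burst_span_and_count():
    bursts = detect_bursts(make_train([0.0, 0.05, 0.10]), SLICE)
    (b,) = bursts
    assert b.n_spikes == 3
    assert b.start_s == 0.0
    assert b.end_s == pytest.approx(0.10)
    assert b.duration_s == pytest.approx(0.10)


def test_multiwell_merges_close_bursts():
    # two 3-spike bursts separated by 80 ms end-to-start (< 100 ms IBI)
    t = [0.0, 0.04, 0.08, 0.16, 0.20, 0.24]
    bursts = detect_bursts(make_train(t), MULTI)
    assert len(bursts) == 1
    assert bursts[0].n_spikes == 6
    # separated by 150 ms: stays two bursts
    t2 = [0.0, 0.04, 0.08, 0.23, 0.27, 0.31]
    assert len(detect_bursts(make_train(t2), MULTI)) == 2


def _brute_slice(times, d):
    """Independent per-spike state machine for the slice rule."""
    out = []
    cur = [times[0]] if len(times) else []
    for a, b in zip(times[:-1], times[1:]):
        isi = b - a
        ok = isi < d.isi_max_ms / 1000.0 if d.strict_isi else isi <= d.isi_max_ms / 1000.0
        if ok:
            cur.append(b)
        else:
            if len(cur) >= d.min_spikes:
                out.append((cur[0], cur[-1], len(cur)))
            cur = [b]
    if len(cur) >= d.min_spikes:
        out.append((cur[0], cur[-1], len(cur)))
    return out


def _brute_multiwell(times, d):
    start, end, ibi = d.isi_start_ms / 1e3, d.isi_end_ms / 1e3, d.ibi_min_ms / 1e3
    raw = []
    i = 0
    while i < len(times) - 1:
        if times[i + 1] - times[i] <= start:
            j = i + 1
            while j < len(times) - 1 and times[j + 1] - times[j] <= end:
                j += 1
            if j - i + 1 >= d.min_spikes:
                raw.append([times[i], times[j]])
            i = j + 1
        else:
            i += 1
    changed = True
    while changed:
        changed = False
        for k in range(len(raw) - 1):
            if raw[k + 1][0] - raw[k][1] < ibi:
                raw[k][1] = raw[k + 1][1]
                del raw[k + 1]
                changed = True
                break
    return [
        (a, b, int(np.sum((np.asarray(times) >= a) & (np.asarray(times) <= b))))
        for a, b in raw
    ]


@pytest.mark.parametrize("dialect, oracle", [(SLICE, _brute_slice), (MULTI, _brute_multiwell)])
def test_burst_detector_equals_brute_force(dialect, oracle, rng):
    for _ in range(1000):
        n = rng.integers(0, 40)
        times = np.sort(rng.uniform(0, 5.0, size=n))
        times = np.unique(times)
        tr = make_train(times)
        got = [(b.start_s, b.end_s, b.n_spikes) for b in detect_bursts(tr, dialect)]
        want = oracle(list(times), dialect)
        assert got == pytest.approx(want)


def test_bursts_disjoint_and_isis_satisfy_rule(rng):
    for _ in range(200):
        times = np.unique(np.sort(rng.uniform(0, 5.0, size=rng.integers(5, 60))))
        tr = make_train(times)
        bursts = detect_bursts(tr, SLICE)
        for b1, b2 in zip(bursts[:-1], bursts[1:]):
            assert b1.end_s < b2.start_s
        for b in bursts:
            inside = times[(times >= b.start_s) & (times <= b.end_s)]
            assert len(inside) == b.n_spikes >= SLICE.min_spikes
            assert np.all(np.diff(inside) < SLICE.isi_max_ms / 1000.0)


def test_burst_stats_arithmetic():
    # six 3-spike bursts in 60 s, every spike inside a burst
    times = np.concatenate([[b, b + 0.05, b + 0.10] for b in np.arange(6) * 10.0])
    tr = make_train(times, duration=60.0)
    st = burst_stats(detect_bursts(tr, SLICE), tr)
    assert st.mbr_per_min == pytest.approx(6.0)
    assert st.psb_pct == pytest.approx(100.0)
    assert st.mbd_s == pytest.approx(0.10)


def test_psb_conservation_on_random_trains(rng):
    for _ in range(50):
        times = np.unique(np.sort(rng.uniform(0, 20.0, size=120)))
        tr = make_train(times, duration=20.0)
        bursts = detect_bursts(tr, SLICE)
        in_bursts = sum(
            int(np.sum((times >= b.start_s) & (times <= b.end_s))) for b in bursts
        )
        st = burst_stats(bursts, tr)
        assert st.psb_pct == pytest.approx(100.0 * in_bursts / len(times))


def test_psb_missing_for_silent_train():
    tr = make_train([], duration=10.0)
    st = burst_stats([], tr)
    assert st.psb_pct is None


# --------------------------------------------------------------- network bursts
def _bursty(offset):
    return np.concatenate([[offset, offset + 0.03, offset + 0.06, offset + 0.09]])


def test_network_burst_at_half_of_channels():
    # 6 of 12 channels burst in overlap: exactly the 50% threshold
    chans = [_bursty(1.0) if i < 6 else np.array([5.0]) for i in range(12)]
    s = make_set(chans, duration=10.0, well="w1")
    nbs = detect_network_bursts(s, MULTI, fraction=0.5)
    assert len(nbs) == 1
    assert len(nbs[0].participating_channels) == 6


def test_no_network_burst_below_half():
    chans = [_bursty(1.0) if i < 5 else np.array([5.0]) for i in range(12)]
    s = make_set(chans, duration=10.0, well="w1")
    assert detect_network_bursts(s, MULTI, fraction=0.5) == []


def test_silent_well_has_no_network_bursts():
    s = make_set([np.array([])] * 4, duration=10.0, well="w1")
    assert detect_network_bursts(s, MULTI) == []


# ------------------------------------------------------------- inclusion filters
def test_active_electrode_rate_strictly_above_cutoff():
    # 1 spike in 10 s = 0.1 Hz exactly: excluded by the strict inequality
    s = make_set([[1.0], [1.0, 2.0]], duration=10.0)
    out = filter_active_electrodes(s, min_rate_hz=0.1, min_channels=1)
    assert out.channel_ids == ["ch01"]


def test_set_flagged_when_fewer_than_min_channels():
    s = make_set([np.arange(10) * 0.5 + 0.1 for _ in range(19)], duration=10.0)
    out = filter_active_electrodes(s, min_rate_hz=0.1, min_channels=20)
    assert out.flagged_discarded
    assert len(out) == 19


def test_all_channels_retained_when_active():
    s = make_set([np.arange(10) + 0.5 for _ in range(30)], duration=11.0)
    out = filter_active_electrodes(s, min_rate_hz=0.1, min_channels=20)
    assert not out.flagged_discarded
    assert len(out) == 30


def test_unit_rate_inclusion_bounds():
    units = gen_unit_waveforms(5, 0, sep=4.0, seed=0)
    units.table["rate_hz"] = [0.5, 2.0, 50.0, 100.0, 150.0]
    kept = filter_units_by_rate(units, 2.0, 100.0)
    assert list(kept.table["rate_hz"]) == [2.0, 50.0, 100.0]
    units.table["rate_hz"] = [1.9, 101.0, 50.0, 50.0, 50.0]
    assert len(filter_units_by_rate(units, 2.0, 100.0)) == 3
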