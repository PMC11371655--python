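"""Coherence, region reduction, AAFT surrogates and permutation selection."""

import numpy as np
import pytest
from scipy.signal import coherence as scipy_coherence
from scipy.signal import lfilter, welch

from mosaicnet import (
    DEFAULT_BANDS,
    RegionConnectivity,
    SurrogateParams,
    aaft_surrogate,
    band_strength,
    differential_connectome,
    electrode_band_strengths,
    permutation_select,
    reduce_to_regions,
    welch_coherence,
)
from mosaicnet.containers import CoherenceSpectrum
from mosaicnet.synthetic import LFPBandComponent, SynthConfig, gen_lfp_network

from conftest import make_lfp

BETA = DEFAULT_BANDS["beta"]


# ------------------------------------------------------------------- coherence
def test_signal_with_itself_coherence_one(rng):
    x = lfilter([1], [1, -0.5, 0.3], rng.standard_normal(30000))
    spec = welch_coherence(x, x, 500.0)
    assert np.allclose(spec.gamma, 1.0, atol=1e-9)


def test_independent_noise_coherence_near_bias_level(rng):
    fs = 500.0
    n = int(61 * fs)  # ~60 Welch windows at 2 s / 50 %
    spec = welch_coherence(rng.standard_normal(n), rng.standard_normal(n), fs)
    assert spec.gamma.mean() < 0.1


def test_additive_noise_gives_half_coherence(rng):
    fs = 500.0
    x = rng.standard_normal(int(240 * fs))
    y = x + rng.standard_normal(x.size)  # SNR 1 in power at every frequency
    spec = welch_coherence(x, y, fs)
    assert spec.gamma.mean() == pytest.approx(0.5, abs=0.05)


def test_single_window_rejected(rng):
    with pytest.raises(ValueError, match="Welch window"):
        welch_coherence(rng.standard_normal(1000), rng.standard_normal(1000), 500.0)


def test_fast_path_matches_scipy_coherence(rng):
    fs = 500.0
    data = rng.standard_normal((3, int(30 * fs)))
    rec = make_lfp(data, fs)
    m = electrode_band_strengths(rec, BETA)
    f, g = scipy_coherence(
        data[0], data[2], fs=fs, window="hann", nperseg=1000, noverlap=500
    )
    sel = (f >= BETA.f_lo) & (f <= BETA.f_hi)
    assert m[0, 2] == pytest.approx(g[sel].mean(), abs=1e-12)


# ---------------------------------------------------------------- band strength
def test_band_strength_of_constant_spectra():
    freqs = np.linspace(0, 250, 501)
    for c in (1.0, 0.3):
        spec = CoherenceSpectrum(freqs, np.full(501, c), ("a", "b"))
        assert band_strength(spec, BETA) == pytest.approx(c)


def test_band_strength_equals_recount(rng):
    freqs = np.linspace(0, 250, 501)
    gamma = rng.uniform(size=501)
    spec = CoherenceSpectrum(freqs, gamma, ("a", "b"))
    sel = (freqs >= 12) & (freqs <= 25)
    assert band_strength(spec, BETA) == pytest.approx(gamma[sel].mean())


# ------------------------------------------------------------- region reduction
def _mapping_8(ids):
    labels = ["CA1-L", "CA1-R", "Amy-L", "Amy-R", "ERC-L", "ERC-R", "PRC-L", "PRC-R"]
    return {c: labels[i % 8] for i, c in enumerate(ids)}


def test_constant_strengths_reduce_to_constant():
    ids = [f"e{i}" for i in range(16)]
    m = np.full((16, 16), 0.4)
    np.fill_diagonal(m, 1.0)
    conn = reduce_to_regions(m, _mapping_8(ids), ids, BETA)
    off = conn.strength.copy()
    assert np.allclose(off, 0.4)


def test_region_reduction_equals_brute_force(rng):
    ids = [f"e{i}" for i in range(16)]
    mapping = _mapping_8(ids)
    a = rng.uniform(size=(16, 16))
    m = (a + a.T) / 2
    conn = reduce_to_regions(m, mapping, ids, BETA)
    for ai, la in enumerate(conn.labels):
        for bi, lb in enumerate(conn.labels):
            vals = []
            for i, ci in enumerate(ids):
                for j, cj in enumerate(ids):
                    if i == j:
                        continue
                    if mapping[ci] == la and mapping[cj] == lb:
                        if la == lb and i > j:
                            continue  # unordered within-region pairs
                        vals.append(m[i, j])
            assert conn.strength[ai, bi] == pytest.approx(np.mean(vals))


def test_unmapped_electrode_rejected():
    ids = ["e0", "e1"]
    with pytest.raises(ValueError, match="without region mapping"):
        reduce_to_regions(np.eye(2), {"e0": "CA1-L"}, ids, BETA)


def test_block_matrix_elevates_only_its_region_pair():
    ids = [f"e{i}" for i in range(8)]
    mapping = {c: ("R1" if i < 4 else "R2") for i, c in enumerate(ids)}
    m = np.full((8, 8), 0.1)
    m[:4, 4:] = m[4:, :4] = 0.9  # only the cross-region block is strong
    np.fill_diagonal(m, 1.0)
    conn = reduce_to_regions(m, mapping, ids, BETA)
    i1, i2 = conn.labels.index("R1"), conn.labels.index("R2")
    assert conn.strength[i1, i2] == pytest.approx(0.9)
    assert conn.strength[i1, i1] == pytest.approx(0.1)


# ------------------------------------------------------------------------- AAFT
def test_aaft_preserves_amplitude_distribution_exactly(rng):
    x = rng.standard_normal(512) ** 3  # heavy-tailed
    s = aaft_surrogate(x, seed=0)
    assert np.array_equal(np.sort(s), np.sort(x))
    assert not np.array_equal(s, x)


def test_aaft_seeds_give_distinct_surrogates(rng):
    x = rng.standard_normal(256)
    s1, s2 = aaft_surrogate(x, seed=1), aaft_surrogate(x, seed=2)
    assert not np.array_equal(s1, s2)
    assert np.array_equal(np.sort(s1), np.sort(s2))


def test_aaft_constant_input_rejected():
    with pytest.raises(ValueError, match="constant"):
        aaft_surrogate(np.ones(128), seed=0)


def test_aaft_short_input_rejected(rng):
    with pytest.raises(ValueError, match="too short"):
        aaft_surrogate(rng.standard_normal(32), seed=0)


def test_aaft_preserves_spectrum_of_ar2(rng):
    x = lfilter([1], [1, -0.9, 0.4], rng.standard_normal(4096))
    s = aaft_surrogate(x, seed=3)
    _, p1 = welch(x, nperseg=256)
    _, p2 = welch(s, nperseg=256)
    assert np.corrcoef(p1, p2)[0, 1] > 0.8


# ------------------------------------------------------------ permutation select
def test_duplicated_pair_always_retained(rng):
    fs = 500.0
    x = rng.standard_normal(int(60 * fs))
    rec = make_lfp(np.vstack([x, x]), fs)
    params = SurrogateParams(n_surrogates=1000, retain_count=995, seed=0)
    conn = permutation_select(rec, {"e0": "R1", "e1": "R2"}, BETA, params)
    assert conn.surrogate_counts[0, 1] == 1000
    assert conn.retained[0, 1]


def test_literal_reading_inverts_retention(rng):
    fs = 500.0
    x = rng.standard_normal(int(30 * fs))
    rec = make_lfp(np.vstack([x, x]), fs)
    params = SurrogateParams(
        n_surrogates=200, retain_count=190, seed=0, literal_reading=True
    )
    conn = permutation_select(rec, {"e0": "R1", "e1": "R2"}, BETA, params)
    assert not conn.retained[0, 1]


def test_zero_retain_count_keeps_every_edge(rng):
    fs = 500.0
    rec = make_lfp(rng.standard_normal((2, int(20 * fs))), fs)
    params = SurrogateParams(n_surrogates=8, retain_count=0, seed=0)
    conn = permutation_select(rec, {"e0": "R1", "e1": "R2"}, BETA, params)
    assert conn.retained[0, 1]


def test_planted_band_component_detected_only_in_its_band(rng):
    cfg = SynthConfig(
        seed=21,
        duration_s=120.0,
        n_channels=2,
        region_map={"a": ("CA1", "L"), "b": ("CA1", "R")},
        lfp_bands=(LFPBandComponent(BETA, 20.0, ("a", "b")),),
        noise_sd_uv=10.0,
    )
    rec = gen_lfp_network(cfg)
    mapping = {"a": "R1", "b": "R2"}
    params = SurrogateParams.fast(seed=1)
    in_beta = permutation_select(rec, mapping, BETA, params)
    in_delta = permutation_select(rec, mapping, DEFAULT_BANDS["delta"], params)
    assert in_beta.retained[0, 1]
    assert not in_delta.retained[0, 1]


def test_surrogate_counts_deterministic_under_seed(rng):
    fs = 500.0
    rec = make_lfp(rng.standard_normal((2, int(20 * fs))), fs)
    params = SurrogateParams(n_surrogates=50, retain_count=45, seed=7)
    c1 = permutation_select(rec, {"e0": "R1", "e1": "R2"}, BETA, params)
    c2 = permutation_select(rec, {"e0": "R1", "e1": "R2"}, BETA, params)
    assert np.array_equal(c1.surrogate_counts, c2.surrogate_counts)


# ---------------------------------------------------------------- differential
def _conn(edges, labels=("R1", "R2", "R3")):
    n = len(labels)
    retained = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        i, j = labels.index(a), labels.index(b)
        retained[i, j] = retained[j, i] = True
    return RegionConnectivity(
        band=BETA, labels=list(labels), strength=np.eye(n), retained=retained
    )


def test_identical_adjacency_gives_empty_differential():
    d = differential_connectome(_conn([("R1", "R2")]), _conn([("R1", "R2")]))
    assert d.over_edges == frozenset() and d.under_edges == frozenset()


def test_one_extra_edge_appears_in_over_only():
    d = differential_connectome(_conn([("R1", "R2"), ("R2", "R3")]), _conn([("R1", "R2")]))
    assert d.over_edges == frozenset({("R2", "R3")})
    assert d.under_edges == frozenset()


def test_disjoint_adjacencies_set_arithmetic():
    d = differential_connectome(
        _conn([("R1", "R2")]), _conn([("R2", "R3"), ("R1", "R3")])
    )
    assert len(d.over_edges) == 1 and len(d.under_edges) == 2


def test_label_mismatch_rejected():
    with pytest.raises(ValueError, match="share band and region labels"):
        differential_connectome(_conn([]), _conn([], labels=("A", "B", "C")))
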