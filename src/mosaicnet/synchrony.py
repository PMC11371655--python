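"""Spike-phase synchrony and the global synchronization index (SI).

The instantaneous phase of a spike train is defined on a regular time grid
(1-ms bins by default) by linear interpolation between spikes:

    phi(t, n) = 2*pi*n + 2*pi * (t - t_n) / (t_{n+1} - t_n)

for t between spikes n and n+1, so the phase advances by exactly 2*pi per
spike.  Pairwise synchrony is the phase-locking value |<exp(i(phi_i -
phi_j))>| over the bins where both channels have a defined phase.  The
global SI is derived from the largest eigenvalue of the pairwise matrix:

    SI = (lambda_max - lambda_surr) / (N - lambda_surr)

clipped to [0, 1], where lambda_surr is the mean largest eigenvalue over
surrogate matrices obtained by circularly time-shifting each channel's
phase series (destroying alignment while preserving each channel's phase
dynamics).  With no surrogates the fallback normalisation lambda_surr = 1
is used, giving SI = 0 for an identity matrix and SI = 1 for full
synchrony.  A cross-correlogram variant of the pairwise matrix is provided
for binned spike counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .containers import SpikeTrain, SpikeTrainSet, SyncResult

__all__ = [
    "PhaseSeries",
    "spike_phase",
    "pairwise_phase_sync",
    "global_sync_index",
    "synchronization_index",
    "xcorr_sync_index",
]


@dataclass
class PhaseSeries:
    """Unwrapped spike phase of one channel on a regular bin grid."""

    channel_id: str
    t_grid: np.ndarray
    phi: np.ndarray
    valid_mask: np.ndarray


def spike_phase(train: SpikeTrain, bin_ms: float = 1.0) -> PhaseSeries:
    """Instantaneous phase of a spike train on ``bin_ms`` bins.

    Bins outside the span [first spike, last spike] have no defined phase
    and are masked invalid.  Requires at least two spikes.
    """
    t = train.times_s
    if t.size < 2:
        raise ValueError(
            f"channel {train.channel_id}: phase undefined with {t.size} spikes"
        )
    bin_s = bin_ms / 1000.0
    n_bins = int(round(train.duration_s / bin_s))
    grid = (np.arange(n_bins) + 0.5) * bin_s
    # piecewise-linear interpolation of the spike index: exactly
    # 2*pi*n + 2*pi*(t - t_n)/(t_{n+1} - t_n) between spikes n and n+1
    phi = 2.0 * np.pi * np.interp(grid, t, np.arange(t.size, dtype=float))
    valid = (grid >= t[0]) & (grid <= t[-1])
    return PhaseSeries(train.channel_id, grid, phi, valid)


def _plv_matrix(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Phase-locking matrix from per-channel phasors and validity masks.

    ``Z`` holds exp(i*phi) with zeros at invalid bins, ``M`` the boolean
    masks.  Pairs with no common valid bins get NaN.
    """
    Mf = M.astype(float)
    counts = Mf @ Mf.T
    num = Z @ Z.conj().T
    with np.errstate(invalid="ignore", divide="ignore"):
        plv = np.abs(num) / counts
    plv[counts == 0] = np.nan
    np.fill_diagonal(plv, 1.0)
    return np.clip(plv, 0.0, 1.0, out=plv)


def pairwise_phase_sync(phases: list[PhaseSeries]) -> np.ndarray:
    """Pairwise phase-locking values over common valid bins.

    Entry (i, j) = |mean exp(i*(phi_i - phi_j))| over bins valid on both
    channels; symmetric with unit diagonal; NaN where a pair shares no bins.
    """
    if len(phases) < 2:
        raise ValueError("need at least two channels")
    n_bins = {p.phi.size for p in phases}
    if len(n_bins) != 1:
        raise ValueError("phase series must share one bin grid")
    M = np.vstack([p.valid_mask for p in phases])
    Z = np.vstack([np.exp(1j * p.phi) for p in phases]) * M
    return _plv_matrix(Z, M)


def _lambda_max(pairwise: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    m = np.nan_to_num(pairwise, nan=0.0)
    w, v = np.linalg.eigh(m)
    return float(w[-1]), w[::-1], np.abs(v[:, -1])


def global_sync_index(
    pairwise: np.ndarray, surrogate_lambdas: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray, float, float]:
    """SI from a pairwise synchrony matrix.

    Returns (si, eigenvalues, participation, lambda_max, lambda_surr).
    ``surrogate_lambdas`` are largest eigenvalues of surrogate matrices;
    when omitted the fallback normalisation (lambda_max - 1)/(N - 1) is
    used.  Missing (NaN) entries are treated as zero locking.
    """
    pairwise = np.asarray(pairwise, dtype=float)
    if pairwise.ndim != 2 or pairwise.shape[0] != pairwise.shape[1]:
        raise ValueError("pairwise matrix must be square")
    if not np.allclose(
        np.nan_to_num(pairwise), np.nan_to_num(pairwise.T), atol=1e-9
    ):
        raise ValueError("pairwise matrix must be symmetric")
    n = pairwise.shape[0]
    lam, eigs, part = _lambda_max(pairwise)
    lam_surr = 1.0 if surrogate_lambdas is None else float(np.mean(surrogate_lambdas))
    denom = n - lam_surr
    si = (lam - lam_surr) / denom if denom > 0 else 0.0
    return float(np.clip(si, 0.0, 1.0)), eigs, part, lam, lam_surr


def synchronization_index(
    spike_set: SpikeTrainSet,
    bin_ms: float = 1.0,
    n_surrogates: int = 0,
    seed: int | None = None,
) -> SyncResult:
    """Phase-based global SI of a spike-train set.

    Channels with fewer than two spikes cannot carry a phase and are
    dropped.  With ``n_surrogates > 0`` the index is normalised by the mean
    largest eigenvalue of circularly time-shifted surrogates.
    """
    usable = [tr for tr in spike_set if tr.n_spikes >= 2]
    if len(usable) < 2:
        raise ValueError("need at least two channels with >= 2 spikes")
    phases = [spike_phase(tr, bin_ms) for tr in usable]
    M = np.vstack([p.valid_mask for p in phases])
    Z = np.vstack([np.exp(1j * p.phi) for p in phases]) * M
    pairwise = _plv_matrix(Z, M)

    surr_lams = None
    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        n_bins = Z.shape[1]
        surr_lams = np.empty(n_surrogates)
        for s in range(n_surrogates):
            shifts = rng.integers(0, n_bins, size=Z.shape[0])
            Zs = np.vstack([np.roll(Z[i], shifts[i]) for i in range(Z.shape[0])])
            Ms = np.vstack([np.roll(M[i], shifts[i]) for i in range(M.shape[0])])
            surr_lams[s], _, _ = _lambda_max(_plv_matrix(Zs, Ms))
    si, eigs, part, lam, lam_surr = global_sync_index(pairwise, surr_lams)
    return SyncResult(
        si=si,
        pairwise=pairwise,
        eigenvalues=eigs,
        method="phase",
        channel_ids=[tr.channel_id for tr in usable],
        participation=part,
        lambda_max=lam,
        surrogate_lambda_mean=lam_surr,
    )


def xcorr_sync_index(
    spike_set: SpikeTrainSet,
    bin_ms: float = 10.0,
    max_lag_ms: float = 100.0,
    n_surrogates: int = 0,
    seed: int | None = None,
) -> SyncResult:
    """Cross-correlation variant of the synchrony matrix and SI.

    Trains are binned at ``bin_ms``, mean-subtracted, and each pairwise
    entry is the maximum of the normalised cross-correlogram within
    +-``max_lag_ms``.  Silent (empty) channels give missing entries.  The
    SI aggregation is the same eigenvalue construction as the phase method.
    """
    if len(spike_set) < 2:
        raise ValueError("need at least two channels")
    bin_s = bin_ms / 1000.0
    n_bins = int(round(spike_set.duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    X = np.vstack([np.histogram(tr.times_s, bins=edges)[0] for tr in spike_set]).astype(
        float
    )
    X -= X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(X**2, axis=1))
    max_lag = int(round(max_lag_ms / bin_ms))
    n_ch = X.shape[0]

    def _pairwise(Xm: np.ndarray) -> np.ndarray:
        pw = np.full((n_ch, n_ch), np.nan)
        np.fill_diagonal(pw, 1.0)
        for i in range(n_ch):
            if norms[i] == 0:
                continue
            for j in range(i + 1, n_ch):
                if norms[j] == 0:
                    continue
                cc = _signal.correlate(Xm[i], Xm[j], mode="full")
                mid = n_bins - 1
                window = cc[mid - max_lag : mid + max_lag + 1]
                val = np.max(np.abs(window)) / (norms[i] * norms[j])
                pw[i, j] = pw[j, i] = min(val, 1.0)
        return pw

    pairwise = _pairwise(X)
    surr_lams = None
    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        surr_lams = np.empty(n_surrogates)
        for s in range(n_surrogates):
            shifts = rng.integers(0, n_bins, size=n_ch)
            Xs = np.vstack([np.roll(X[i], shifts[i]) for i in range(n_ch)])
            surr_lams[s], _, _ = _lambda_max(_pairwise(Xs))
    si, eigs, part, lam, lam_surr = global_sync_index(pairwise, surr_lams)
    return SyncResult(
        si=si,
        pairwise=pairwise,
        eigenvalues=eigs,
        method="xcorr",
        channel_ids=spike_set.channel_ids,
        participation=part,
        lambda_max=lam,
        surrogate_lambda_mean=lam_surr,
    )
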