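"""Putative excitatory/inhibitory classification of sorted units.

Each unit's mean extracellular waveform is summarised by the durations of
its depolarized state (width of the trough at half-minimum) and its
hyperpolarized state (width of the after-peak at half-maximum), both in
ms.  Units are split by Ward hierarchical clustering on the standardized
feature pair into two groups; the narrow-spiking cluster (shorter
durations) is labelled inhibitory, the broad-spiking one excitatory, and
units far from both cluster centroids — Mahalanobis distance beyond a
configurable quantile — stay unclassified.  The trough-to-peak time is
also computed as an auxiliary feature since the state-duration definition
admits more than one reading in the literature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.cluster import AgglomerativeClustering

from .containers import EIRatioReport, UnitTable

__all__ = [
    "WaveformError",
    "waveform_features",
    "extract_features",
    "cluster_ei",
    "ei_ratio",
]


class WaveformError(ValueError):
    """The waveform lacks the trough/after-peak structure needed for features."""


def _half_width_ms(x: np.ndarray, peak_idx: int, fs: float) -> float:
    """Width (ms) of the excursion around ``peak_idx`` at half its height.

    Crossing points are linearly interpolated between samples; if the
    waveform never returns to half height before the array edge, the edge
    is used.
    """
    half = x[peak_idx] / 2.0
    sgn = np.sign(x[peak_idx])
    y = sgn * x  # make the excursion positive
    h = sgn * half
    left = float(peak_idx)
    for i in range(peak_idx, 0, -1):
        if y[i - 1] < h <= y[i]:
            left = (i - 1) + (h - y[i - 1]) / (y[i] - y[i - 1])
            break
        left = float(i - 1)
    right = float(peak_idx)
    for i in range(peak_idx, len(y) - 1):
        if y[i] >= h > y[i + 1]:
            right = i + (y[i] - h) / (y[i] - y[i + 1])
            break
        right = float(i + 1)
    return (right - left) / fs * 1000.0


def waveform_features(waveform: np.ndarray, fs: float) -> tuple[float, float, float]:
    """(depol_ms, hyperpol_ms, trough_to_peak_ms) of a mean spike waveform.

    The depolarized-state duration is the trough width at half-minimum; the
    hyperpolarized-state duration is the after-peak width at half-maximum.
    Raises :class:`WaveformError` when there is no negative trough or no
    positive peak after it.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 5 or np.ptp(w) == 0:
        raise WaveformError("flat or too-short waveform")
    trough = int(np.argmin(w))
    if w[trough] >= 0:
        raise WaveformError("no negative trough")
    after = w[trough + 1 :]
    if after.size == 0 or np.max(after) <= 0:
        raise WaveformError("no positive after-peak")
    peak = trough + 1 + int(np.argmax(after))
    depol = _half_width_ms(w, trough, fs)
    hyperpol = _half_width_ms(w, peak, fs)
    t2p = (peak - trough) / fs * 1000.0
    return depol, hyperpol, t2p


def extract_features(units: UnitTable) -> UnitTable:
    """Add depol_ms / hyperpol_ms / trough_to_peak_ms columns to a unit table.

    Units whose waveform lacks the required structure get NaN features and
    will be labelled unclassified downstream.
    """
    out = units.copy()
    feats = []
    for w in out.waveforms:
        try:
            feats.append(waveform_features(w, out.fs_hz))
        except WaveformError:
            feats.append((np.nan, np.nan, np.nan))
    f = np.asarray(feats)
    out.table["depol_ms"] = f[:, 0]
    out.table["hyperpol_ms"] = f[:, 1]
    out.table["trough_to_peak_ms"] = f[:, 2]
    return out


def cluster_ei(
    units: UnitTable,
    outlier_quantile: float = 0.975,
    linkage: str = "ward",
    min_separation: float = 2.0,
) -> UnitTable:
    """Label units excitatory / inhibitory / unclassified.

    Agglomerative clustering (2 clusters, Ward linkage by default) on the
    standardized (depol_ms, hyperpol_ms) pair; the cluster with the shorter
    mean durations is inhibitory (narrow-spiking convention).  Units whose
    Mahalanobis distance to both cluster centroids exceeds the chi-square
    quantile at ``outlier_quantile`` are unclassified, as are units without
    features.  If the two centroids are closer than ``min_separation``
    pooled within-cluster SDs the population is treated as a single
    (excitatory) class rather than fabricating a split.
    """
    if "depol_ms" not in units.table.columns:
        units = extract_features(units)
    out = units.copy()
    feats = out.table[["depol_ms", "hyperpol_ms"]].to_numpy(dtype=float)
    ok = np.all(np.isfinite(feats), axis=1)
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 classifiable units, got {int(ok.sum())}")
    X = feats[ok]
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate features: all units identical along an axis")
    Xs = (X - X.mean(axis=0)) / sd

    # isolate gross outliers first: a Ward split that peels off a tiny cluster
    # is an outlier, not a cell class; re-cluster the remainder
    active = np.ones(len(Xs), dtype=bool)
    for _ in range(5):
        idx = np.flatnonzero(active)
        cl_try = AgglomerativeClustering(n_clusters=2, linkage=linkage).fit_predict(
            Xs[idx]
        )
        sizes = np.bincount(cl_try, minlength=2)
        min_size = max(3, int(0.05 * len(idx)))
        if sizes.min() >= min_size or len(idx) - sizes.min() < 10:
            break
        active[idx[cl_try == int(np.argmin(sizes))]] = False
    idx = np.flatnonzero(active)
    cl = np.full(len(Xs), -1)
    cl[idx] = AgglomerativeClustering(n_clusters=2, linkage=linkage).fit_predict(Xs[idx])

    centroids = np.vstack([Xs[cl == k].mean(axis=0) for k in (0, 1)])
    within = np.sqrt(
        np.mean(
            np.concatenate(
                [np.sum((Xs[cl == k] - centroids[k]) ** 2, axis=1) for k in (0, 1)]
            )
        )
    )
    sep = np.linalg.norm(centroids[0] - centroids[1]) / max(within, 1e-12)

    labels = np.full(len(out.table), "unclassified", dtype=object)
    if sep < min_separation:
        # centroids closer than min_separation pooled SDs: a single population
        lab_ok = np.full(len(Xs), "excitatory", dtype=object)
        lab_ok[cl == -1] = "unclassified"
        labels[ok] = lab_ok
    else:
        # narrow-spiking cluster -> inhibitory
        mean_dur = [feats[ok][cl == k].sum(axis=1).mean() for k in (0, 1)]
        name = {int(np.argmin(mean_dur)): "inhibitory", int(np.argmax(mean_dur)): "excitatory"}
        # assign by Mahalanobis distance to the cluster covariances; units far
        # from both clusters stay unclassified
        cut = chi2.ppf(outlier_quantile, df=2)
        d2 = np.full((len(Xs), 2), np.inf)
        for k in (0, 1):
            pts = Xs[cl == k]
            cov = np.cov(pts.T) if len(pts) > 2 else np.eye(2)
            cov = cov + 1e-9 * np.eye(2)
            inv = np.linalg.inv(cov)
            diff = Xs - centroids[k]
            d2[:, k] = np.einsum("ij,jk,ik->i", diff, inv, diff)
        lab_ok = np.where(cl >= 0, [name.get(k, "unclassified") for k in cl], "unclassified")
        lab_ok = np.asarray(lab_ok, dtype=object)
        near = np.argmin(d2, axis=1)
        peeled = cl == -1
        lab_ok[peeled & (np.min(d2, axis=1) <= cut)] = [
            name[int(k)] for k in near[peeled & (np.min(d2, axis=1) <= cut)]
        ]
        lab_ok[np.min(d2, axis=1) > cut] = "unclassified"
        labels[ok] = lab_ok
    out.table["label"] = labels
    return out


def _group_mean(rates: pd.Series) -> float | None:
    return float(rates.mean()) if len(rates) else None


def ei_ratio(units: UnitTable, by_region: bool = True) -> dict[str, EIRatioReport]:
    """E/I counts, group-mean firing rates and their ratios, per region.

    Unclassified units are excluded.  Ratios whose denominator group is
    empty are missing (``None``), never infinite.  The pooled report is
    available under the key ``"all"``.
    """
    if "label" not in units.table.columns:
        raise ValueError("units must be labelled first (run cluster_ei)")
    t = units.table
    reports: dict[str, EIRatioReport] = {}
    regions = list(dict.fromkeys(t["region"].dropna())) if by_region else []
    for region in regions + ["all"]:
        sub = t if region == "all" else t[t["region"] == region]
        exc = sub[sub["label"] == "excitatory"]
        inh = sub[sub["label"] == "inhibitory"]
        n_e, n_i = len(exc), len(inh)
        mfr_e = _group_mean(exc["rate_hz"])
        mfr_i = _group_mean(inh["rate_hz"])
        reports[region] = EIRatioReport(
            region=region,
            n_exc=n_e,
            n_inh=n_i,
            count_ratio=(n_e / n_i) if n_i else None,
            mfr_exc_hz=mfr_e,
            mfr_inh_hz=mfr_i,
            mfr_ratio=(mfr_e / mfr_i) if (mfr_i and mfr_e is not None) else None,
        )
    return reports
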