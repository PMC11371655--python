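"""Core data containers shared across the analysis stages.

All times are in seconds, voltages in microvolts, rates in hertz, and all
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

REGIONS = ("CA1", "Amy", "ERC", "PRC")
HEMISPHERES = ("L", "R")

#: The eight region x hemisphere labels used for the reduced connectome,
#: ordered region-major ("CA1-L", "CA1-R", "Amy-L", ...).
REGION_LABELS = tuple(f"{r}-{h}" for r in REGIONS for h in HEMISPHERES)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one channel (or sorted unit)."""

    channel_id: str
    times_s: np.ndarray
    duration_s: float
    region: str | None = None
    hemisphere: str | None = None
    well: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if t.ndim != 1:
            raise ValueError("times_s must be one-dimensional")
        if t.size:
            if np.any(np.diff(t) < 0):
                raise ValueError(f"channel {self.channel_id}: spike times not sorted")
            if np.any(np.diff(t) == 0):
                raise ValueError(f"channel {self.channel_id}: duplicate spike times")
            if t[0] < 0 or t[-1] >= self.duration_s:
                raise ValueError(
                    f"channel {self.channel_id}: spike times outside [0, duration_s)"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)

    @property
    def rate_hz(self) -> float:
        return self.n_spikes / self.duration_s

    def isis_s(self) -> np.ndarray:
        """Interspike intervals, length ``n_spikes - 1``."""
        return np.diff(self.times_s)


@dataclass
class SpikeTrainSet:
    """A collection of spike trains sharing one recording duration.

    ``flagged_discarded`` marks a set that failed an inclusion filter (for
    example fewer than the minimum number of active channels); the data is
    kept so callers can inspect why.
    """

    trains: list[SpikeTrain]
    duration_s: float
    flagged_discarded: bool = False

    def __post_init__(self) -> None:
        for tr in self.trains:
            if tr.duration_s != self.duration_s:
                raise ValueError(
                    f"channel {tr.channel_id} duration {tr.duration_s} != set "
                    f"duration {self.duration_s}"
                )

    def __len__(self) -> int:
        return len(self.trains)

    def __iter__(self) -> Iterator[SpikeTrain]:
        return iter(self.trains)

    def __getitem__(self, i: int) -> SpikeTrain:
        return self.trains[i]

    @property
    def channel_ids(self) -> list[str]:
        return [tr.channel_id for tr in self.trains]

    def by_well(self) -> dict[str, "SpikeTrainSet"]:
        wells: dict[str, list[SpikeTrain]] = {}
        for tr in self.trains:
            wells.setdefault(tr.well or "", []).append(tr)
        return {
            w: SpikeTrainSet(trs, self.duration_s) for w, trs in sorted(wells.items())
        }


@dataclass(frozen=True)
class Burst:
    channel_id: str
    start_s: float
    end_s: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("burst end before start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class NetworkBurst:
    well: str
    start_s: float
    end_s: float
    participating_channels: frozenset[str]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class BurstDialect:
    """Parameters of one of the two burst-detection rules.

    The ``slice`` dialect requires at least ``min_spikes`` consecutive spikes
    with every ISI below ``isi_max_ms``.  The ``multiwell`` dialect opens a
    burst on an ISI <= ``isi_start_ms``, extends it while ISIs stay
    <= ``isi_end_ms``, and merges bursts whose end-to-start gap is below
    ``ibi_min_ms``.  ``strict_isi`` controls whether the slice ISI bound is a
    strict inequality (an ISI of exactly ``isi_max_ms`` breaks the burst).
    """

    name: str
    min_spikes: int = 3
    isi_max_ms: float = 100.0
    isi_start_ms: float = 50.0
    isi_end_ms: float = 50.0
    ibi_min_ms: float = 100.0
    strict_isi: bool = True

    def __post_init__(self) -> None:
        if self.name not in ("slice", "multiwell"):
            raise ValueError(f"unknown burst dialect {self.name!r}")
        if min(self.isi_max_ms, self.isi_start_ms, self.isi_end_ms, self.ibi_min_ms) <= 0:
            raise ValueError("all dialect durations must be positive")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be at least 2")

    @classmethod
    def slice_dialect(cls, **kw) -> "BurstDialect":
        return cls(name="slice", **kw)

    @classmethod
    def multiwell_dialect(cls, **kw) -> "BurstDialect":
        return cls(name="multiwell", **kw)


@dataclass(frozen=True)
class SpikeStats:
    """Per-train (or pooled) activity statistics.

    ``psb_pct`` is ``None`` when the train has no spikes (the percentage of
    spikes in bursts is then undefined, not zero).
    """

    mfr_hz: float
    mbr_per_min: float
    mbd_s: float | None
    psb_pct: float | None


@dataclass
class LFPRecord:
    """Multi-channel continuous signal with a shared sampling rate.

    ``data`` has shape ``(n_channels, n_samples)`` in microvolts.
    ``channel_meta`` is a DataFrame indexed like ``data`` rows with at least a
    ``channel_id`` column and optional ``region`` / ``hemisphere`` columns.
    """

    data: np.ndarray
    fs_hz: float
    channel_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_meta) != self.data.shape[0]:
            raise ValueError("channel_meta length does not match channel count")
        if "channel_id" not in self.channel_meta.columns:
            raise ValueError("channel_meta must have a channel_id column")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def channel_ids(self) -> list[str]:
        return [str(c) for c in self.channel_meta["channel_id"]]

    def channel(self, channel_id: str) -> np.ndarray:
        idx = self.channel_ids.index(str(channel_id))
        return self.data[idx]

    @classmethod
    def from_channels(
        cls,
        channels: dict[str, np.ndarray],
        fs_hz: float,
        regions: dict[str, str] | None = None,
        hemispheres: dict[str, str] | None = None,
    ) -> "LFPRecord":
        ids = list(channels)
        meta = pd.DataFrame({"channel_id": ids})
        if regions is not None:
            meta["region"] = [regions.get(c) for c in ids]
        if hemispheres is not None:
            meta["hemisphere"] = [hemispheres.get(c) for c in ids]
        return cls(np.vstack([channels[c] for c in ids]), fs_hz, meta)


@dataclass(frozen=True)
class BandSpec:
    """A named LFP frequency band ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges {self.f_lo}-{self.f_hi} Hz")


#: Canonical band definitions: delta 1-4, theta 4-8, alpha 8-12, beta 12-25,
#: gamma 25-100 Hz.
DEFAULT_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 25.0),
    "gamma": BandSpec("gamma", 25.0, 100.0),
}


@dataclass(frozen=True)
class LFPEvent:
    channel_id: str
    start_s: float
    duration_s: float
    peak_uv: float


@dataclass
class SyncResult:
    """Global synchronization index plus the pairwise matrix behind it.

    ``si`` lies in [0, 1]: 0 for random uncoordinated activity, 1 for fully
    synchronous activity.  ``participation`` holds the leading-eigenvector
    weight of each channel (how much it contributes to the dominant
    synchronous cluster).
    """

    si: float
    pairwise: np.ndarray
    eigenvalues: np.ndarray
    method: str
    channel_ids: list[str]
    participation: np.ndarray | None = None
    lambda_max: float | None = None
    surrogate_lambda_mean: float | None = None


@dataclass(frozen=True)
class CoherenceSpectrum:
    freqs: np.ndarray
    gamma: np.ndarray
    pair: tuple[str, str]


@dataclass(frozen=True)
class SurrogateParams:
    """Settings of the AAFT-surrogate permutation test.

    The defaults (10000 surrogates, retain when the original strength is the
    larger one in more than 9950 of them) follow the published counts; note
    that 9950/10000 corresponds to a nominal p < 0.005 even though the test is
    described as p < 0.05.  ``literal_reading=True`` selects the inverted
    literal reading of the retention sentence (keep edges whose surrogates
    beat the original); the default is the significance reading.
    """

    n_surrogates: int = 10000
    retain_count: int = 9950
    seed: int | None = None
    literal_reading: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.retain_count <= self.n_surrogates:
            raise ValueError("retain_count must be in [0, n_surrogates]")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be positive")

    @classmethod
    def fast(cls, seed: int | None = None, **kw) -> "SurrogateParams":
        """Scaled desk profile: 1000 surrogates, retain when > 995."""
        return cls(n_surrogates=1000, retain_count=995, seed=seed, **kw)


@dataclass
class RegionConnectivity:
    """Per-band region-level coherence matrix and retained adjacency."""

    band: BandSpec
    labels: list[str]
    strength: np.ndarray
    retained: np.ndarray | None = None
    surrogate_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.strength = np.asarray(self.strength, dtype=float)
        n = len(self.labels)
        if self.strength.shape != (n, n):
            raise ValueError("strength matrix does not match labels")
        if not np.allclose(self.strength, self.strength.T, equal_nan=True):
            raise ValueError("strength matrix must be symmetric")

    def edges(self) -> set[tuple[str, str]]:
        """Retained edges as sorted label pairs."""
        if self.retained is None:
            return set()
        out = set()
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if self.retained[i, j]:
                    out.add(tuple(sorted((self.labels[i], self.labels[j]))))
        return out


@dataclass(frozen=True)
class DifferentialConnectome:
    """Edges retained in one group but not the other (e.g. mosaic vs control)."""

    band: BandSpec
    over_edges: frozenset[tuple[str, str]]
    under_edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.over_edges & self.under_edges:
            raise ValueError("over and under edge sets must be disjoint")


class UnitTable:
    """Sorted units with mean waveforms, features, rates and E/I labels.

    ``table`` is a DataFrame with columns ``unit_id``, ``region``,
    ``hemisphere``, ``rate_hz``, and, once computed, ``depol_ms``,
    ``hyperpol_ms``, ``label`` and optionally ``truth_label``.  ``waveforms``
    holds one mean waveform per row, shape ``(n_units, n_samples)`` in uV.
    """

    def __init__(self, table: pd.DataFrame, waveforms: np.ndarray, fs_hz: float):
        waveforms = np.atleast_2d(np.asarray(waveforms, dtype=float))
        if len(table) != waveforms.shape[0]:
            raise ValueError("table length does not match waveform count")
        if fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        self.table = table.reset_index(drop=True)
        self.waveforms = waveforms
        self.fs_hz = float(fs_hz)

    def __len__(self) -> int:
        return len(self.table)

    def copy(self) -> "UnitTable":
        return UnitTable(self.table.copy(), self.waveforms.copy(), self.fs_hz)

    def subset(self, mask: Sequence[bool] | np.ndarray) -> "UnitTable":
        mask = np.asarray(mask, dtype=bool)
        return UnitTable(
            self.table.loc[mask].reset_index(drop=True),
            self.waveforms[mask],
            self.fs_hz,
        )


@dataclass(frozen=True)
class EIRatioReport:
    """Excitatory/inhibitory composition of one region.

    Ratios are ``None`` (missing) when their denominator group is empty.
    """

    region: str
    n_exc: int
    n_inh: int
    count_ratio: float | None
    mfr_exc_hz: float | None
    mfr_inh_hz: float | None
    mfr_ratio: float | None
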