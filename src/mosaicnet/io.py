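"""Reading and writing of the pipeline's on-disk formats.

Spike-train sets travel as long CSV (``channel, region, hemisphere, well,
t_s`` with a ``# duration_s=`` header line) or HDF5 (one group per
channel); LFP records as HDF5 (one dataset per channel with region /
hemisphere attributes and a file-level ``fs_hz``); unit tables as CSV
(waveform samples in ``wf_*`` columns) or HDF5; matrices as TSV; edge
lists as JSON; run configurations as YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import (
    LFPRecord,
    RegionConnectivity,
    SpikeTrain,
    SpikeTrainSet,
    UnitTable,
)

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_spike_hdf5",
    "read_spike_hdf5",
    "write_lfp_hdf5",
    "read_lfp_hdf5",
    "write_unit_csv",
    "read_unit_csv",
    "write_unit_hdf5",
    "read_unit_hdf5",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edges_json",
    "read_edges_json",
    "write_config_yaml",
    "read_config_yaml",
]

logger = logging.getLogger(__name__)

_NA = ""


def write_spike_csv(spike_set: SpikeTrainSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# duration_s={float(spike_set.duration_s)!r}\n")
        fh.write("channel,region,hemisphere,well,t_s\n")
        for tr in spike_set:
            meta = f"{tr.region or _NA},{tr.hemisphere or _NA},{tr.well or _NA}"
            if tr.n_spikes == 0:
                fh.write(f"{tr.channel_id},{meta},\n")
            for t in tr.times_s:
                fh.write(f"{tr.channel_id},{meta},{float(t)!r}\n")


def read_spike_csv(path: str | Path) -> SpikeTrainSet:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# duration_s="):
            raise ValueError(f"{path}: missing '# duration_s=' header line")
        duration = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, dtype={"channel": str}, float_precision="round_trip")
    trains = []
    for ch, grp in df.groupby("channel", sort=True):
        times = grp["t_s"].dropna().to_numpy(dtype=float)
        if times.size and np.any(np.diff(times) < 0):
            logger.warning("%s: channel %s has unsorted spike times; sorting", path, ch)
            times = np.sort(times)
        row = grp.iloc[0]

        def _get(col):
            v = row[col]
            return None if pd.isna(v) else str(v)

        trains.append(
            SpikeTrain(
                str(ch),
                times,
                duration,
                region=_get("region"),
                hemisphere=_get("hemisphere"),
                well=_get("well"),
            )
        )
    return SpikeTrainSet(trains, duration)


def write_spike_hdf5(spike_set: SpikeTrainSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["duration_s"] = spike_set.duration_s
        for tr in spike_set:
            g = f.create_group(tr.channel_id)
            g.create_dataset("times_s", data=tr.times_s)
            for k in ("region", "hemisphere", "well"):
                v = getattr(tr, k)
                if v is not None:
                    g.attrs[k] = v


def read_spike_hdf5(path: str | Path) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        if "duration_s" not in f.attrs:
            raise ValueError(f"{path}: missing duration_s attribute")
        duration = float(f.attrs["duration_s"])
        trains = []
        for ch in sorted(f):
            g = f[ch]
            trains.append(
                SpikeTrain(
                    ch,
                    g["times_s"][...],
                    duration,
                    region=g.attrs.get("region"),
                    hemisphere=g.attrs.get("hemisphere"),
                    well=g.attrs.get("well"),
                )
            )
    return SpikeTrainSet(trains, duration)


def write_lfp_hdf5(lfp: LFPRecord, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs_hz"] = lfp.fs_hz
        for i, ch in enumerate(lfp.channel_ids):
            d = f.create_dataset(ch, data=lfp.data[i])
            for col in ("region", "hemisphere"):
                if col in lfp.channel_meta.columns:
                    v = lfp.channel_meta.iloc[i][col]
                    if v is not None and not (isinstance(v, float) and np.isnan(v)):
                        d.attrs[col] = v


def read_lfp_hdf5(path: str | Path, assume_uv: bool = False) -> LFPRecord:
    with h5py.File(path, "r") as f:
        if "fs_hz" not in f.attrs:
            raise ValueError(f"{path}: missing fs_hz attribute on the file")
        fs = float(f.attrs["fs_hz"])
        ids = sorted(f)
        data = np.vstack([f[ch][...] for ch in ids])
        meta = pd.DataFrame(
            {
                "channel_id": ids,
                "region": [f[ch].attrs.get("region") for ch in ids],
                "hemisphere": [f[ch].attrs.get("hemisphere") for ch in ids],
            }
        )
    rms = float(np.sqrt(np.mean(data**2))) if data.size else 0.0
    if not assume_uv and 0 < rms < 0.05:
        logger.warning(
            "%s: RMS amplitude %.3g looks like mV rather than uV; pass "
            "assume_uv=True to silence this check",
            path,
            rms,
        )
    return LFPRecord(data, fs, meta)


_UNIT_COLS = ["unit_id", "region", "hemisphere", "rate_hz", "truth_label", "label",
              "depol_ms", "hyperpol_ms", "trough_to_peak_ms"]


def write_unit_csv(units: UnitTable, path: str | Path) -> None:
    df = units.table.copy()
    wf = pd.DataFrame(
        units.waveforms, columns=[f"wf_{i}" for i in range(units.waveforms.shape[1])]
    )
    out = pd.concat([df.reset_index(drop=True), wf], axis=1)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={float(units.fs_hz)!r}\n")
        out.to_csv(fh, index=False)


def read_unit_csv(path: str | Path) -> UnitTable:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs_hz="):
            raise ValueError(f"{path}: missing '# fs_hz=' header line")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    wf_cols = [c for c in df.columns if c.startswith("wf_")]
    wf = df[wf_cols].to_numpy(dtype=float)
    table = df[[c for c in df.columns if not c.startswith("wf_")]]
    return UnitTable(table, wf, fs)


def write_unit_hdf5(units: UnitTable, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs_hz"] = units.fs_hz
        f.create_dataset("waveforms", data=units.waveforms)
        str_t = h5py.string_dtype()
        for col in units.table.columns:
            v = units.table[col]
            if v.dtype.kind in "if":
                f.create_dataset(f"table/{col}", data=v.to_numpy())
            else:
                f.create_dataset(
                    f"table/{col}",
                    data=[("" if pd.isna(x) else str(x)) for x in v],
                    dtype=str_t,
                )


def read_unit_hdf5(path: str | Path) -> UnitTable:
    with h5py.File(path, "r") as f:
        if "fs_hz" not in f.attrs:
            raise ValueError(f"{path}: missing fs_hz attribute")
        fs = float(f.attrs["fs_hz"])
        wf = f["waveforms"][...]
        cols = {}
        for col in f["table"]:
            data = f[f"table/{col}"][...]
            if data.dtype.kind == "O" or data.dtype.kind == "S":
                cols[col] = [x.decode() if isinstance(x, bytes) else x for x in data]
                cols[col] = [None if x == "" else x for x in cols[col]]
            else:
                cols[col] = data
    df = pd.DataFrame(cols)
    ordered = [c for c in _UNIT_COLS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    return UnitTable(df[ordered], wf, fs)


def write_matrix_tsv(
    matrix: np.ndarray, labels: list[str], path: str | Path
) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_edges_json(conn: RegionConnectivity, path: str | Path, status: str = "retained") -> None:
    edges = [
        {"band": conn.band.name, "from": a, "to": b, "status": status}
        for a, b in sorted(conn.edges())
    ]
    with open(path, "w") as fh:
        json.dump({"band": conn.band.name, "edges": edges}, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_edges_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_config_yaml(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
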