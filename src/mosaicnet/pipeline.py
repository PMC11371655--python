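"""End-to-end pipeline driver: spikes -> bursts -> SI -> LFP bands ->
coherence -> surrogate selection -> E/I, on synthetic or user data.

The driver is deliberately thin plumbing over the analysis modules: it
sequences the stages, persists intermediate tables, and emits a
:class:`ReportBundle` whose group comparison is limited to descriptive
mean +- SEM and a two-sample t-test.  Re-running with an identical
configuration reproduces every table byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .containers import BurstDialect, DEFAULT_BANDS, SurrogateParams
from .connectivity import differential_connectome, permutation_select
from .io import read_lfp_hdf5, read_spike_csv
from .lfp import band_power
from .spikes import burst_stats, detect_bursts, filter_active_electrodes
from .synchrony import synchronization_index, xcorr_sync_index
from .synthetic import SynthConfig, gen_two_group_experiment

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    With ``control_spikes`` / ``mosaic_spikes`` (CSV) and optional LFP HDF5
    paths, the pipeline analyses user data; otherwise it simulates a
    two-group experiment from ``synth``.  Every random stage derives its
    seed from ``seed``.
    """

    seed: int = 0
    outdir: str | None = None
    control_spikes: str | None = None
    mosaic_spikes: str | None = None
    control_lfp: str | None = None
    mosaic_lfp: str | None = None
    dialect: str = "slice"
    bands: tuple[str, ...] = ("alpha", "beta", "gamma")
    si_method: str = "phase"
    si_surrogates: int = 0
    n_surrogates: int = 1000
    retain_count: int = 995
    min_rate_hz: float = 0.1
    min_channels: int = 20
    continue_on_missing: bool = False
    synth: SynthConfig = field(default_factory=SynthConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["lfp_bands"] = [
            {
                "band": [c.band.name, c.band.f_lo, c.band.f_hi],
                "amplitude_uv": c.amplitude_uv,
                "channels": list(c.channels),
            }
            for c in self.synth.lfp_bands
        ]
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    provenance: dict
    errors: list[str] = field(default_factory=list)


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        return wrapper

    return deco


def _spike_table(spike_set, dialect: BurstDialect) -> pd.DataFrame:
    rows = []
    for tr in spike_set:
        bursts = detect_bursts(tr, dialect)
        st = burst_stats(bursts, tr)
        rows.append(
            {
                "channel_id": tr.channel_id,
                "region": tr.region,
                "mfr_hz": st.mfr_hz,
                "mbr_per_min": st.mbr_per_min,
                "mbd_s": st.mbd_s,
                "psb_pct": st.psb_pct,
            }
        )
    return pd.DataFrame(rows)


def _group_summary(ctrl: pd.DataFrame, mos: pd.DataFrame) -> pd.DataFrame:
    from scipy.stats import ttest_ind

    rows = []
    for col in ("mfr_hz", "mbr_per_min", "mbd_s", "psb_pct"):
        a = ctrl[col].dropna().to_numpy(dtype=float)
        b = mos[col].dropna().to_numpy(dtype=float)
        p = float(ttest_ind(a, b).pvalue) if len(a) > 1 and len(b) > 1 else np.nan
        rows.append(
            {
                "metric": col,
                "control_mean": a.mean() if len(a) else np.nan,
                "control_sem": a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else np.nan,
                "mosaic_mean": b.mean() if len(b) else np.nan,
                "mosaic_sem": b.std(ddof=1) / np.sqrt(len(b)) if len(b) > 1 else np.nan,
                "p_ttest": p,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages and return the report bundle.

    Stage failures abort with the stage name unless the failure is a
    missing optional input and ``continue_on_missing`` is set, in which
    case the remaining stages still run and the error is recorded.
    """
    errors: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    rng_seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)

    # --- inputs -----------------------------------------------------------
    @_stage("load")
    def _load():
        if config.control_spikes and config.mosaic_spikes:
            ctrl = read_spike_csv(config.control_spikes)
            mos = read_spike_csv(config.mosaic_spikes)
            lfp_c = read_lfp_hdf5(config.control_lfp) if config.control_lfp else None
            lfp_m = read_lfp_hdf5(config.mosaic_lfp) if config.mosaic_lfp else None
            truth = None
        else:
            from dataclasses import replace

            exp = gen_two_group_experiment(
                replace(config.synth, seed=int(rng_seeds[0]))
            )
            ctrl, mos = exp.control_spikes, exp.mosaic_spikes
            lfp_c, lfp_m = exp.control_lfp, exp.mosaic_lfp
            truth = exp.ground_truth
        return ctrl, mos, lfp_c, lfp_m, truth

    ctrl, mos, lfp_c, lfp_m, truth = _load()
    if truth is not None:
        tables["ground_truth"] = truth

    # --- spike stages -----------------------------------------------------
    dialect = (
        BurstDialect.slice_dialect()
        if config.dialect == "slice"
        else BurstDialect.multiwell_dialect()
    )

    @_stage("spike_stats")
    def _spikes():
        out = {}
        for name, sset in (("control", ctrl), ("mosaic", mos)):
            filt = filter_active_electrodes(sset, config.min_rate_hz, config.min_channels)
            use = filt if len(filt) else sset
            out[name] = _spike_table(use, dialect)
            out[name]["set_flagged_discarded"] = filt.flagged_discarded
        return out

    spike_tables = _spikes()
    tables["spikes_control"] = spike_tables["control"]
    tables["spikes_mosaic"] = spike_tables["mosaic"]
    tables["group_summary"] = _group_summary(
        spike_tables["control"], spike_tables["mosaic"]
    )

    @_stage("synchronization")
    def _sync():
        rows = []
        for i, (name, sset) in enumerate((("control", ctrl), ("mosaic", mos))):
            fn = synchronization_index if config.si_method == "phase" else xcorr_sync_index
            res = fn(
                sset,
                n_surrogates=config.si_surrogates,
                seed=int(rng_seeds[1 + i]),
            )
            rows.append({"group": name, "si": res.si, "method": res.method,
                         "lambda_max": res.lambda_max, "n_channels": len(res.channel_ids)})
        return pd.DataFrame(rows)

    tables["synchronization"] = _sync()

    # --- LFP stages -------------------------------------------------------
    if lfp_c is None or lfp_m is None:
        msg = "LFP input missing: band power and connectivity stages skipped"
        if not config.continue_on_missing:
            raise RuntimeError(f"pipeline stage 'lfp' failed: {msg}")
        errors.append(msg)
    else:

        @_stage("band_power")
        def _power():
            rows = []
            for name, rec in (("control", lfp_c), ("mosaic", lfp_m)):
                for bname in config.bands:
                    p = band_power(rec, DEFAULT_BANDS[bname])
                    for ch, v in zip(rec.channel_ids, p):
                        rows.append(
                            {"group": name, "band": bname, "channel_id": ch,
                             "power_uv2_hz": v}
                        )
            return pd.DataFrame(rows)

        tables["band_power"] = _power()

        @_stage("connectivity")
        def _connect():
            rows = []
            for k, bname in enumerate(config.bands):
                band = DEFAULT_BANDS[bname]
                conns = {}
                for g, (name, rec) in enumerate((("control", lfp_c), ("mosaic", lfp_m))):
                    mapping = {
                        str(r.channel_id): f"{r.region}-{r.hemisphere}"
                        for r in rec.channel_meta.itertuples()
                    }
                    params = SurrogateParams(
                        n_surrogates=config.n_surrogates,
                        retain_count=config.retain_count,
                        seed=int(rng_seeds[3 + 2 * k + g] % (2**31)),
                    )
                    conns[name] = permutation_select(rec, mapping, band, params)
                diff = differential_connectome(conns["control"], conns["mosaic"])
                for a, b in sorted(diff.under_edges):
                    rows.append({"band": bname, "from": a, "to": b, "status": "over_in_mosaic"})
                for a, b in sorted(diff.over_edges):
                    rows.append({"band": bname, "from": a, "to": b, "status": "under_in_mosaic"})
                for name, conn in conns.items():
                    for a, b in sorted(conn.edges()):
                        rows.append({"band": bname, "from": a, "to": b, "status": f"retained_{name}"})
            return pd.DataFrame(rows, columns=["band", "from", "to", "status"])

        tables["connectivity_edges"] = _connect()

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": [int(s) for s in rng_seeds],
        "versions": {
            "mosaicnet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    return ReportBundle(tables=tables, provenance=provenance, errors=errors)


def write_report(bundle: ReportBundle, outdir: str | Path) -> None:
    """Persist every table as CSV plus a provenance JSON, deterministically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.12g")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(
            {**bundle.provenance, "errors": bundle.errors},
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
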