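"""End-to-end two-group analysis on a simulated mosaic-vs-control design.

The mosaic group's firing rates are scaled per region (CA1 0.84, Amy 0.53,
ERC 0.56, PRC 0.69 of control) and the pipeline recovers the planted
reductions, computes the SI per group and screens LFP connectivity.
"""

from mosaicnet import RunConfig, run_pipeline, write_report
from mosaicnet.synthetic import SynthConfig

cfg = RunConfig(
    seed=1,
    bands=("beta",),
    n_surrogates=200,
    retain_count=190,
    synth=SynthConfig(seed=1, duration_s=120.0, n_channels=16, base_rates_hz=5.0,
                      fs_hz=500.0),
    min_channels=8,
)
bundle = run_pipeline(cfg)

gs = bundle.tables["group_summary"].set_index("metric")
print("group comparison (mean +- SEM):")
for metric in ("mfr_hz", "mbr_per_min"):
    row = gs.loc[metric]
    print(
        f"  {metric}: control {row.control_mean:.2f}+-{row.control_sem:.2f}, "
        f"mosaic {row.mosaic_mean:.2f}+-{row.mosaic_sem:.2f}, p={row.p_ttest:.3g}"
    )
print("\nsynchronization:")
print(bundle.tables["synchronization"].to_string(index=False))

write_report(bundle, "scratch/example_report")
print("\nfull report written to scratch/example_report/ "
      f"(config hash {bundle.provenance['config_hash'][:12]})")
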