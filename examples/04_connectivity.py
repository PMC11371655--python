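"""Functional connectivity with AAFT-surrogate permutation selection.

Two channels share a planted beta-band component; a third is independent.
Welch coherence is reduced to named regions and each edge is screened
against 1000 amplitude-adjusted Fourier transform surrogates: an edge
survives only when the original band strength beats the surrogate
strength in more than 995 of 1000 draws.
"""

from mosaicnet import DEFAULT_BANDS, SurrogateParams, permutation_select
from mosaicnet.synthetic import LFPBandComponent, SynthConfig, gen_lfp_network

beta = DEFAULT_BANDS["beta"]
comp = LFPBandComponent(beta, amplitude_uv=20.0, channels=("ch00", "ch01"))
cfg = SynthConfig(
    seed=4,
    duration_s=120.0,
    n_channels=3,
    lfp_bands=(comp,),
    noise_sd_uv=10.0,
    region_map={"ch00": ("CA1", "L"), "ch01": ("Amy", "L"), "ch02": ("ERC", "L")},
)
rec = gen_lfp_network(cfg)
mapping = {"ch00": "CA1-L", "ch01": "Amy-L", "ch02": "ERC-L"}

conn = permutation_select(rec, mapping, beta, SurrogateParams.fast(seed=0))
print("beta-band region coherence (strength):")
for i, a in enumerate(conn.labels):
    for j in range(i + 1, len(conn.labels)):
        b = conn.labels[j]
        mark = "RETAINED" if conn.retained[i, j] else "discarded"
        print(
            f"  {a} - {b}: strength {conn.strength[i, j]:.3f}, "
            f"wins {conn.surrogate_counts[i, j]}/1000 -> {mark}"
        )
print(
    "\nOnly the pair sharing the planted beta component survives the\n"
    "permutation test; coherence between independent channels stays at the\n"
    "Welch bias level and is discarded."
)
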