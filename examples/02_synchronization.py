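"""Global synchronization index (SI) under varying spike-time jitter.

The SI is built from the spike-phase interpolation phi(t,n) = 2*pi*n +
2*pi*(t - t_n)/(t_{n+1} - t_n) on 1-ms bins, the pairwise phase-locking
matrix, and its largest eigenvalue: SI = (lambda_max - 1)/(N - 1) ranges
from 0 (uncoordinated) to 1 (fully synchronous).
"""

from mosaicnet import synchronization_index, xcorr_sync_index
from mosaicnet.synthetic import SynthConfig, gen_synchronous_trains

print("jitter_ms   SI(phase)   SI(xcorr)")
for jitter in (0.0, 2.0, 5.0, 20.0, 50.0):
    cfg = SynthConfig(
        seed=3, duration_s=60.0, n_channels=10, base_rates_hz=5.0,
        sync_jitter_ms=jitter, sync_participation=1.0,
    )
    spikes = gen_synchronous_trains(cfg)
    phase = synchronization_index(spikes).si
    xc = xcorr_sync_index(spikes).si
    print(f"{jitter:9.1f}   {phase:9.3f}   {xc:9.3f}")

print(
    "\nZero jitter copies one parent train to every channel: SI = 1 exactly.\n"
    "Increasing jitter destroys phase alignment and the SI falls toward the\n"
    "level of independent Poisson activity."
)
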