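import numpy as np
import pandas as pd
import pytest

from mosaicnet import LFPRecord, SpikeTrain, SpikeTrainSet


def make_train(times, duration=10.0, channel="ch0", **kw) -> SpikeTrain:
    return SpikeTrain(channel, np.asarray(times, dtype=float), duration, **kw)


def make_set(times_per_channel, duration=10.0, **kw) -> SpikeTrainSet:
    trains = [
        make_train(t, duration, channel=f"ch{i:02d}", **kw)
        for i, t in enumerate(times_per_channel)
    ]
    return SpikeTrainSet(trains, duration)


def make_lfp(data, fs=500.0, regions=None) -> LFPRecord:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    meta = pd.DataFrame({"channel_id": [f"e{i}" for i in range(data.shape[0])]})
    if regions is not None:
        meta["region"] = [r.split("-")[0] for r in regions]
        meta["hemisphere"] = [r.split("-")[1] for r in regions]
    return LFPRecord(data, fs, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
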