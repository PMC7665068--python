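import numpy as np
import pytest

from dgntrace import DGNModel, TrainConfig, synthesize_dataset
from dgntrace.sim import NoiseModel


@pytest.fixture(scope="session")
def small_trained():
    """A small DGN trained on easy (high-aSNR) photobleach data.

    Used for post-training functional checks; deliberately modest so the
    whole suite stays fast.
    """
    ds = synthesize_dataset("photobleach", s_max=10, n_traces=600,
                            n_frames=200, target_asnr=4.74, seed=42)
    res = DGNModel(ds).fit(TrainConfig(epochs=30, seed=7))
    return ds, res


@pytest.fixture(scope="session")
def sharp_trained():
    """A DGN trained on short, step-rich, nearly noiseless traces.

    A model trained only on long traces with slow bleaching never sees
    rapid staircases, and its decoding of very short traces inherits the
    temporal smoothing of that distribution; this corpus (16-frame traces,
    fast bleaching, bright fluorophores, no blinking, constant alpha)
    covers the regime the exact-decoding functional checks probe.
    """
    noise = NoiseModel(unit_intensity=10000.0, blink_rate=0.0)
    ds = synthesize_dataset("photobleach", s_max=10, n_traces=2000,
                            n_frames=16, target_asnr=25.0, seed=42,
                            noise=noise, bleach_rate=0.10)
    res = DGNModel(ds).fit(TrainConfig(epochs=30, seed=7, alpha_decay=0.0))
    return ds, res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
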