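import numpy as np
import pandas as pd
import pytest

from taskprio import simulate as sim
from taskprio.containers import TFRSet


@pytest.fixture(scope="session")
def montage_df():
    from taskprio.montage import load_montage

    return load_montage()


@pytest.fixture(scope="session")
def small_epochs():
    """16 balanced trials, full montage, default planted effects."""
    schedule = sim.make_schedule(1, 16, seed=11)
    return sim.simulate_epochs(schedule, sim.default_effect_spec(seed=12))


def constant_power_tfr(ipsi_value, contra_value, cue_side, pairs, freqs=(10.0,)):
    """TFRSet with spatially constant power: one hemisphere gets
    ``ipsi_value`` relative to ``cue_side``, the other ``contra_value``."""
    channels = [c for pair in pairs for c in pair]
    n_tr, n_f, n_t = 4, len(freqs), 12
    power = np.zeros((n_tr, len(channels), n_f, n_t))
    for pi, (left, right) in enumerate(pairs):
        li, ri = channels.index(left), channels.index(right)
        if cue_side == "left":
            power[:, li], power[:, ri] = ipsi_value, contra_value
        else:
            power[:, ri], power[:, li] = ipsi_value, contra_value
    meta = pd.DataFrame({
        "retrocue_side": [cue_side] * n_tr,
        "response_side": ["left", "right"] * (n_tr // 2),
    })
    tfr = TFRSet(
        power=power,
        freqs_hz=np.array(freqs),
        times_ms=np.arange(n_t) * 50.0,
        sfreq=20.0,
        channel_names=channels,
        is_db=False,
    )
    return tfr, meta
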