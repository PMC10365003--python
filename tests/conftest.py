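import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from ironmri import DecayParams, default_echo_train, simulate_decay


@pytest.fixture
def echo_train():
    """Liver-protocol schedule: 0.8, 1.8, ..., 9.8 ms."""
    return default_echo_train()


@pytest.fixture
def clean_series(echo_train):
    """Noiseless decay, K=500, T2*=5 ms."""
    return simulate_decay(echo_train, DecayParams(K=500, T2star=5.0))


def brute_spearman(x, y):
    """Independent oracle: Pearson correlation of hand-averaged ranks."""
    def avg_ranks(v):
        v = np.asarray(v, float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            # average of the positions the tied block occupies
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
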