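import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def naive_slpen(x, m, delta, gamma):
    """Brute-force slope-entropy reference: materialise every subsequence.

    Independent of the library implementation: pure-Python loops, an
    explicit per-subsequence difference vector, and a Counter histogram.
    Returns (histogram dict, entropy in bits).
    """
    x = list(map(float, x))
    n = len(x)
    assert n >= m

    def sym(d):
        if d > gamma:
            return 2
        if delta < d <= gamma:
            return 1
        if -delta <= d <= delta:
            return 0
        if -gamma <= d < -delta:
            return -1
        return -2

    counter = Counter()
    for i in range(n - m + 1):
        window = x[i : i + m]
        diffs = [window[j] - window[j + 1] for j in range(m - 1)]
        counter[tuple(sym(d) for d in diffs)] += 1
    k = len(counter)
    entropy = -sum((c / k) * math.log2(c / k) for c in counter.values())
    return dict(counter), entropy


@pytest.fixture
def worked_params():
    """Thresholds of the constant-plus-outlier worked example."""
    from slpen import SlpEnParams

    return SlpEnParams(m=4, delta=1e-3, gamma=0.2)


@pytest.fixture
def outlier_series():
    x = np.full(66, 1.0)
    x[33] = 2.0
    return x


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
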