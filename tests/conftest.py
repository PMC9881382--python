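import math
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from pressc import IntervalObservation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_right_censored_obs(times, censored):
    """Encode exactly-observed / right-censored data as degenerate intervals."""
    out = []
    for i, (t, c) in enumerate(zip(times, censored)):
        if c:
            out.append(IntervalObservation(f"s{i}", float(t), math.inf))
        else:
            out.append(IntervalObservation(f"s{i}", float(t) - 1e-9, float(t)))
    return out


@pytest.fixture
def right_censored_cohort(rng):
    """A 40-subject right-censored cohort with a real group effect."""
    n = 40
    grp = np.arange(n) < 20
    t = rng.exponential(np.where(grp, 1.3, 2.2), n).round(2) + 0.05
    cens = t > 4
    t = np.minimum(t, 4.0)
    return t, cens, grp, make_right_censored_obs(t, cens)
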