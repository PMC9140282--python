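import numpy as np
import pytest

from habit.trial_data import FATIGUE, HABITUATION, FlySession


def make_session(jumps, protocol=None, genotype="control", fly_id="f0",
                 day="day1", system="sys1", chamber=1):
    """Session with explicit jump prefix, padded with no-jumps to length."""
    protocol = protocol or HABITUATION
    padded = list(jumps) + [False] * (protocol.n_trials - len(jumps))
    return FlySession(
        fly_id=fly_id, genotype=genotype, day=day, system=system,
        chamber=chamber, protocol=protocol, jumps=tuple(padded),
    )


def ttc_oracle(jumps, k):
    """Exhaustive window-scan oracle for trials-to-criterion.

    Scans every window for the first run of k consecutive no-jumps and
    takes the last jump trial before it; independent of the streak-counting
    implementation under test.
    """
    n = len(jumps)
    starts = [i for i in range(n - k + 1) if not any(jumps[i:i + k])]
    if not starts:
        return n, True
    first = starts[0]
    prior = [t for t in range(first) if jumps[t]]
    return (prior[-1] + 1 if prior else 0), False


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def habituation_protocol():
    return HABITUATION


@pytest.fixture
def fatigue_protocol():
    return FATIGUE
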