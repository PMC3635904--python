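import numpy as np
import pandas as pd
import pytest

import kinesig as ks


@pytest.fixture(scope="session")
def default_session() -> ks.SessionRecord:
    """One generic subject, blocked slow/fast design, 100 trials/condition."""
    return ks.generate_session(
        ks.default_config(seed=11, design="blocked", trials_per_condition=100))


@pytest.fixture(scope="session")
def cohort_session() -> ks.SessionRecord:
    """Expert + novice, bag/no-bag contexts, blocked, 100 trials/condition."""
    return ks.generate_session(ks.cohort_config(seed=21,
                                                trials_per_condition=100))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def sequence_features(vmax: np.ndarray, amax: np.ndarray,
                      level: str = "slow", context: str = "simulation",
                      block: str = "b1") -> pd.DataFrame:
    """A minimal ordered feature table wrapping a (vmax, amax) sequence."""
    n = len(vmax)
    return pd.DataFrame({
        "trial_index": np.arange(1, n + 1),
        "vmax": vmax, "amax": amax,
        "speed_level": level, "context": context, "block": block,
    })
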