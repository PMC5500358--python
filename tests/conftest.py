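import numpy as np
import pandas as pd
import pytest

import worklife as wl
from worklife.states import FULL_STATES


@pytest.fixture(scope="session")
def toy_cohort():
    """Three persons with hand-enumerable spells, window [20, 30].

    p0: one sick-leave episode [24, 25).
    p1: sick [22, 23), rehab (voc) [26, 27.5), then dies at 29.
    p2: no registered benefit (employed throughout).
    """
    episodes = pd.DataFrame(
        [(0, 2, 24.0, 25.0),
         (1, 2, 22.0, 23.0), (1, 3, 26.0, 27.5), (1, 8, 29.0, 30.0)],
        columns=["person_id", "state", "start_age", "end_age"])
    windows = pd.DataFrame({"person_id": [0, 1, 2],
                            "entry_age": [20.0] * 3,
                            "exit_age": [30.0] * 3})
    return episodes, windows


@pytest.fixture(scope="session")
def toy_processed(toy_cohort):
    episodes, windows = toy_cohort
    return wl.episodes_to_process(episodes, windows, FULL_STATES)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-configured synthetic cohort, fixed seed."""
    return wl.generate_cohort(wl.default_config(800), seed=42)


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    co = small_cohort
    events, intervals = wl.episodes_to_process(co.episodes, co.windows)
    return co, events, intervals


def two_state_config(n=500, lam=0.08, horizon=(20.0, 32.0), seed=0):
    """Alive(1) -> dead(8) only, constant intensity, fixed window."""
    return wl.SimulationConfig(
        n_persons=n, baseline_intensities={(1, 8): lam},
        calendar_window=None, fixed_window=horizon,
        age_band_breaks=(), reepisode_prob=0.0, seed=seed)
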