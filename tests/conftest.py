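import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from scanpath_entropy import CohortConfig, default_layout, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return default_layout()


def make_labeled(labels, durations=None, participant="P01", scenario="A",
                 alignment="straight"):
    """Build a minimal labelled fixation table from a label sequence."""
    n = len(labels)
    durations = list(durations) if durations is not None else [300] * n
    starts = np.concatenate([[0], np.cumsum(np.array(durations[:-1]) + 50)]) if n else []
    return pd.DataFrame(
        {
            "participant": participant,
            "scenario": scenario,
            "alignment": alignment,
            "start_ms": starts,
            "duration_ms": durations,
            "end_ms": np.array(starts) + np.array(durations) if n else [],
            "pos_x": 0.0,
            "pos_y": 0.0,
            "aoi": list(labels),
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (6 participants, ~60 fixations/trial) for fast tests."""
    cfg = CohortConfig(n_participants=6, n_fix_mean=60.0, seed=7)
    fixations, truth = simulate_cohort(cfg)
    return cfg, fixations, truth


@pytest.fixture(scope="session")
def full_cohort():
    """The default study-sized cohort (21 x 3 x 3, ~120 fixations/trial)."""
    cfg = CohortConfig(seed=11)
    fixations, truth = simulate_cohort(cfg)
    return cfg, fixations, truth
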