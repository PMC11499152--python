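import numpy as np
import pandas as pd
import pytest

from gaze_dpa import SimulationConfig, assign_roles, generate_dataset
from gaze_dpa.gaze_io import default_layout


@pytest.fixture(scope="session")
def study_dataset():
    """Full study-scale dataset: 32 participants x 3 conditions x 20 items."""
    cfg = SimulationConfig(seed=1)
    trials, samples, participants = generate_dataset(cfg)
    return cfg, trials, samples, participants


@pytest.fixture(scope="session")
def study_roles(study_dataset):
    cfg, trials, samples, _ = study_dataset
    return assign_roles(samples, trials, default_layout())


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced dataset for fast end-to-end checks."""
    cfg = SimulationConfig(
        n_participants=8,
        n_items_per_condition=6,
        conditions=("positive", "negative"),
        true_onset_ms={"positive": 4600.0, "negative": 6300.0},
        sample_period_ms=50.0,
        seed=11,
    )
    trials, samples, participants = generate_dataset(cfg)
    return cfg, trials, samples, participants


@pytest.fixture(scope="session")
def small_roles(small_dataset):
    cfg, trials, samples, _ = small_dataset
    return assign_roles(samples, trials, default_layout())


def make_trial_counts(
    pattern: dict[float, tuple[int, int]],
    n_participants: int = 4,
    n_trials: int = 3,
) -> pd.DataFrame:
    """Hand-built per-trial bin counts, identical across trials/participants.

    ``pattern`` maps bin_start_ms -> (y_factual, y_illusory) per trial.
    """
    rows = []
    for p in range(n_participants):
        for t in range(n_trials):
            for bin_start, (yf, yi) in pattern.items():
                rows.append(
                    {
                        "participant_id": f"P{p}",
                        "trial_id": f"P{p}-T{t}",
                        "bin_start_ms": float(bin_start),
                        "y_factual": yf,
                        "y_illusory": yi,
                    }
                )
    return pd.DataFrame(rows)
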