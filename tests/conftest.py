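import numpy as np
import pandas as pd
import pytest

from afmeg import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """One 4-note pattern, short trials: quick but structurally complete."""
    return synthgen.SimulationConfig(
        n_subjects=4,
        sequence_patterns=((60, 62, 64, 65),),
        trials_per_block=8,
        trial_duration=12.0,
        af_free_trials=frozenset({1, 6}),
        ioi_noise_sd=20.0,
        seed=7,
    )


@pytest.fixture
def layout_grid():
    return synthgen.generate_sensor_layout(9, geometry="grid", spacing=1.0)


def make_events(onsets_by_trial, feedback=None, position=None, errors=None,
                subject=1, pattern=(60, 62, 64, 65)):
    """Build a minimal event table from explicit per-trial onset lists."""
    rows = []
    for trial, onsets in enumerate(onsets_by_trial, start=1):
        for k, onset in enumerate(onsets):
            L = len(pattern)
            pos = k % L + 1
            rows.append({
                "subject": subject, "block": 1, "trial": trial,
                "trial_in_block": trial, "pattern_id": 0,
                "keystroke_index": k, "onset_ms": float(onset),
                "pitch_played": pattern[k % L],
                "pitch_heard": pattern[k % L],
                "velocity": 64.0, "seq_position": pos,
                "position_class": "Bo" if pos in (1, L) else "In",
                "feedback": "NF", "is_error": False,
            })
    df = pd.DataFrame(rows)
    if feedback is not None:
        df["feedback"] = feedback
    if position is not None:
        df["position_class"] = position
    if errors is not None:
        df["is_error"] = errors
    return df


@pytest.fixture
def events_factory():
    return make_events
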