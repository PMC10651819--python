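import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from frailtykit import Cohort, default_paper_config, generate_cohort
from frailtykit.instrument import DEFAULT_DEFICIT_ITEMS

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def _deficit_rows(animal_id, timepoint, nonzero=None):
    """27 deficit rows, all zero except the given {item: score} overrides."""
    nonzero = nonzero or {}
    return [
        {"animal_id": animal_id, "timepoint": timepoint, "item": item,
         "score": float(nonzero.get(item, 0.0))}
        for item in DEFAULT_DEFICIT_ITEMS
    ]


def _trial_rows(animal_id, timepoint, test, values):
    return [
        {"animal_id": animal_id, "timepoint": timepoint, "test": test,
         "trial_index": i + 1, "value": float(v)}
        for i, v in enumerate(values)
    ]


@pytest.fixture()
def tiny_cohort() -> Cohort:
    """Three handcrafted animals with trial values whose criterion
    reductions are known by hand.

    a1: complete data at both timepoints; baseline panel should be
        ws=14, gft=14, td=116, vrw=3.0, fi=2/27, dbw=mean(-2%, -0.5/24.5%).
    a2: lacks activity trials at baseline (missing criterion).
    a3: died before endpoint (no endpoint measurements).
    """
    animals = pd.DataFrame(
        [
            {"animal_id": "a1", "sex": "female", "group": "adult", "alive_at_endpoint": True},
            {"animal_id": "a2", "sex": "female", "group": "old_vehicle",
             "alive_at_endpoint": True},
            {"animal_id": "a3", "sex": "male", "group": "old_vehicle",
             "alive_at_endpoint": False},
        ]
    )
    trials = []
    trials += _trial_rows("a1", "baseline", "walking_speed", [10, 14, 12])
    trials += _trial_rows("a1", "baseline", "grip_strength", [10, 12, 14, 16, 18])
    trials += _trial_rows("a1", "baseline", "endurance", [116])
    trials += _trial_rows("a1", "baseline", "activity", [2, 3, 4, 3])
    trials += _trial_rows("a1", "endpoint", "walking_speed", [11, 13, 12])
    trials += _trial_rows("a1", "endpoint", "grip_strength", [9, 11, 13, 15, 17])
    trials += _trial_rows("a1", "endpoint", "endurance", [100])
    trials += _trial_rows("a1", "endpoint", "activity", [2, 2, 3, 3])
    trials += _trial_rows("a2", "baseline", "walking_speed", [20, 21, 19])
    trials += _trial_rows("a2", "baseline", "grip_strength", [8, 8, 8, 8, 20])
    trials += _trial_rows("a2", "baseline", "endurance", [70])
    trials += _trial_rows("a2", "endpoint", "walking_speed", [18, 19, 17])
    trials += _trial_rows("a2", "endpoint", "grip_strength", [7, 8, 8, 8, 19])
    trials += _trial_rows("a2", "endpoint", "endurance", [60])
    trials += _trial_rows("a2", "endpoint", "activity", [1, 1, 1, 5])
    trials += _trial_rows("a3", "baseline", "walking_speed", [15, 16, 14])
    trials += _trial_rows("a3", "baseline", "grip_strength", [10, 10, 10, 10, 10])
    trials += _trial_rows("a3", "baseline", "endurance", [75])
    trials += _trial_rows("a3", "baseline", "activity", [0, 0, 0, 0])

    bodyweight = (
        [{"animal_id": "a1", "week": w, "weight_g": g}
         for w, g in [(1, 25.0), (2, 24.5), (3, 24.0), (13, 23.0)]]
        + [{"animal_id": "a2", "week": w, "weight_g": g}
           for w, g in [(1, 30.0), (2, 30.0), (3, 30.0), (13, 28.0)]]
        + [{"animal_id": "a3", "week": w, "weight_g": g}
           for w, g in [(1, 35.0), (2, 34.0), (3, 33.5), (6, 31.0)]]
    )
    deficits = (
        _deficit_rows("a1", "baseline",
                      {"alopecia": 1.0, "dermatitis": 0.5, "kyphosis": 0.5})
        + _deficit_rows("a1", "endpoint", {"alopecia": 1.0, "dermatitis": 1.0})
        + _deficit_rows("a2", "baseline", {"kyphosis": 0.5})
        + _deficit_rows("a2", "endpoint", {"kyphosis": 1.0, "tremor": 0.5})
        + _deficit_rows("a3", "baseline", {"tremor": 0.5})
    )
    return Cohort.from_frames(
        animals=animals,
        trials=pd.DataFrame(trials),
        bodyweight=pd.DataFrame(bodyweight),
        deficits=pd.DataFrame(deficits),
    )


@pytest.fixture(scope="session")
def default_config():
    return default_paper_config(seed=7)


@pytest.fixture(scope="session")
def sim_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture()
def zero_cv_config():
    """Noise-free study conditions: every animal exactly at its group mean."""
    config = default_paper_config(seed=3)
    for test in config.animal_cv:
        config.animal_cv[test] = 0.0
        config.trial_cv[test] = 0.0
    config.fi_cv = 0.0
    config.bw_start_cv = 0.0
    config.bw_step_cv = 0.0
    for sex in config.mortality:
        for group in config.mortality[sex]:
            config.mortality[sex][group] = 0.0
    return config


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
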