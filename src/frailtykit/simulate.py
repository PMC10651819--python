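"""Synthetic longitudinal cohort generator.

Emulates a two-timepoint (baseline/endpoint), two-sex, three-group
(adult, old_vehicle, old_pdx) aging-intervention cohort with the
statistical structure the downstream analysis assumes:

* per-animal latent "vigor": a single standard-normal factor that loads
  on every performance test and (negatively) on the frailty index, so
  criteria co-decline within animals and multi-marker positives occur;
* log-normal between-animal and within-animal (trial) noise for the
  performance tests, so the trial-summarization rules (best of 3,
  trimmed mean of 5, mean of 4) are genuinely exercised;
* frailty-index item scores drawn to match a noisy per-animal target
  index, quantized to the instrument's 0.5-point grid;
* a weekly body-weight geometric random walk with group-specific drift
  (old groups lose weight, adults gain);
* Bernoulli mortality between baseline and endpoint for the groups that
  lose animals; dead animals keep their baseline data, stop their
  weight series at the death week, and have no endpoint measurements.

The default configuration is calibrated to the reported group values of
the study the pipeline models (treadmill distances of roughly 70/75 m
for old females/males versus 116/126 m for adults, a 12.5% baseline and
16% endpoint strength deficit in old females, a ~28% endpoint strength
deficit in old males, old activity about two-thirds of adult, negative
old and positive adult weight drift, 90%/95% old-vehicle survival).
Dispersion parameters and absolute levels the study does not report are
realistic choices documented in the methods note.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from math import log, sqrt
from typing import Iterator

import numpy as np
import pandas as pd

from .cohort import Cohort, GROUPS, SEXES, TIMEPOINTS, TRIAL_COUNTS
from .errors import CohortValidationError
from .instrument import DEFAULT_DEFICIT_ITEMS

TESTS: tuple[str, ...] = tuple(TRIAL_COUNTS)

_GROUP_CODE = {"adult": "ad", "old_vehicle": "ov", "old_pdx": "px"}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, nested by sex → group (→ timepoint).

    ``means`` holds the *panel-level* target mean for each performance
    test (i.e. the expected value of the summarized criterion before
    trial-summarization bias, which is zero for the endurance single
    trial and negligible elsewhere). Identical config + seed always
    yields an identical cohort.
    """

    n: dict = field(default_factory=dict)             # sex → group → cohort size
    means: dict = field(default_factory=dict)         # test → sex → group → timepoint → mean
    fi_mean: dict = field(default_factory=dict)       # sex → group → timepoint → mean FI
    animal_cv: dict = field(default_factory=dict)     # test → between-animal CV
    trial_cv: dict = field(default_factory=dict)      # test → within-animal trial CV
    fi_cv: float = 0.0
    vigor_loading: float = 0.6
    bw_start_g: dict = field(default_factory=dict)    # sex → group → grams at week 1
    bw_start_cv: float = 0.0
    bw_drift_pct: dict = field(default_factory=dict)  # sex → group → %/week drift
    bw_step_cv: float = 0.0
    mortality: dict = field(default_factory=dict)     # sex → group → P(death before endpoint)
    n_weeks: int = 13
    death_week_range: tuple[int, int] = (5, 12)
    seed: int = 0

    def copy(self) -> "GeneratorConfig":
        return copy.deepcopy(self)

    def validate(self) -> None:
        for sex in SEXES:
            for group in GROUPS:
                if self.n.get(sex, {}).get(group) is None:
                    raise CohortValidationError(f"n missing for ({sex}, {group})")
                if self.n[sex][group] < 0:
                    raise CohortValidationError(f"n negative for ({sex}, {group})")
                for test in TESTS:
                    for tp in TIMEPOINTS:
                        m = self.mean_for(test, sex, group, tp)
                        if not m > 0:
                            raise CohortValidationError(
                                f"mean for {test} ({sex}, {group}, {tp}) must be > 0, got {m}"
                            )
                for tp in TIMEPOINTS:
                    fi = self.fi_for(sex, group, tp)
                    if not 0 <= fi <= 1:
                        raise CohortValidationError(
                            f"fi_mean for ({sex}, {group}, {tp}) must be in [0,1], got {fi}"
                        )
                if not self.bw_start_g[sex][group] > 0:
                    raise CohortValidationError(f"bw_start_g not positive for ({sex}, {group})")
                p = self.mortality[sex][group]
                if not 0 <= p <= 1:
                    raise CohortValidationError(
                        f"mortality for ({sex}, {group}) must be in [0,1], got {p}"
                    )
        for test in TESTS:
            if self.animal_cv[test] < 0 or self.trial_cv[test] < 0:
                raise CohortValidationError(f"CVs for {test} must be >= 0")
        if self.fi_cv < 0 or self.bw_start_cv < 0 or self.bw_step_cv < 0:
            raise CohortValidationError("CVs must be >= 0")
        if not 0 <= self.vigor_loading <= 1:
            raise CohortValidationError("vigor_loading must be in [0, 1]")
        if self.n_weeks < 2:
            raise CohortValidationError("n_weeks must be >= 2")

    def mean_for(self, test: str, sex: str, group: str, timepoint: str) -> float:
        return float(self.means[test][sex][group][timepoint])

    def fi_for(self, sex: str, group: str, timepoint: str) -> float:
        return float(self.fi_mean[sex][group][timepoint])


def _by_group(female: dict, male: dict) -> dict:
    return {"female": female, "male": male}


def default_paper_config(seed: int = 0) -> GeneratorConfig:
    """The calibrated study conditions (see module docstring)."""
    td = {  # treadmill distance to exhaustion, meters
        "female": {
            "adult": {"baseline": 116.0, "endpoint": 116.0},
            "old_vehicle": {"baseline": 70.0, "endpoint": 58.0},
            "old_pdx": {"baseline": 70.0, "endpoint": 67.0},
        },
        "male": {
            "adult": {"baseline": 126.0, "endpoint": 126.0},
            "old_vehicle": {"baseline": 75.0, "endpoint": 62.0},
            "old_pdx": {"baseline": 75.0, "endpoint": 72.0},
        },
    }
    gft = {  # combined-limb peak grip force, grams
        "female": {
            "adult": {"baseline": 250.0, "endpoint": 250.0},
            # 12.5% below adult at baseline, 16% below at endpoint
            "old_vehicle": {"baseline": 218.75, "endpoint": 210.0},
            "old_pdx": {"baseline": 218.75, "endpoint": 214.0},
        },
        "male": {
            "adult": {"baseline": 300.0, "endpoint": 300.0},
            # modest (non-significant) baseline gap, 28% below adult at endpoint
            "old_vehicle": {"baseline": 276.0, "endpoint": 216.0},
            "old_pdx": {"baseline": 276.0, "endpoint": 258.0},
        },
    }
    vrw = {  # voluntary wheel running, km/day; old ≈ 2/3 of adult throughout
        "female": {
            "adult": {"baseline": 6.0, "endpoint": 5.1},
            "old_vehicle": {"baseline": 4.0, "endpoint": 3.4},
            "old_pdx": {"baseline": 4.0, "endpoint": 3.4},
        },
        "male": {
            "adult": {"baseline": 5.4, "endpoint": 4.6},
            "old_vehicle": {"baseline": 3.6, "endpoint": 3.1},
            "old_pdx": {"baseline": 3.6, "endpoint": 3.1},
        },
    }
    ws = {  # best rotarod speed, rpm; no age effect, small treated-female gain
        "female": {
            "adult": {"baseline": 25.0, "endpoint": 25.0},
            "old_vehicle": {"baseline": 25.0, "endpoint": 24.0},
            "old_pdx": {"baseline": 25.0, "endpoint": 26.0},
        },
        "male": {
            "adult": {"baseline": 25.0, "endpoint": 25.0},
            "old_vehicle": {"baseline": 25.0, "endpoint": 24.0},
            "old_pdx": {"baseline": 25.0, "endpoint": 24.5},
        },
    }
    fi_mean = {
        "female": {
            "adult": {"baseline": 0.08, "endpoint": 0.09},
            "old_vehicle": {"baseline": 0.25, "endpoint": 0.31},
            "old_pdx": {"baseline": 0.25, "endpoint": 0.30},
        },
        "male": {
            "adult": {"baseline": 0.08, "endpoint": 0.09},
            "old_vehicle": {"baseline": 0.25, "endpoint": 0.31},
            # treated males started with a lower index than vehicle males
            "old_pdx": {"baseline": 0.19, "endpoint": 0.25},
        },
    }
    return GeneratorConfig(
        n=_by_group(
            {"adult": 15, "old_vehicle": 19, "old_pdx": 14},
            {"adult": 15, "old_vehicle": 19, "old_pdx": 14},
        ),
        means={"walking_speed": ws, "grip_strength": gft, "endurance": td, "activity": vrw},
        fi_mean=fi_mean,
        animal_cv={"walking_speed": 0.10, "grip_strength": 0.10,
                   "endurance": 0.25, "activity": 0.30},
        trial_cv={"walking_speed": 0.08, "grip_strength": 0.06,
                  "endurance": 0.10, "activity": 0.15},
        fi_cv=0.30,
        vigor_loading=0.6,
        bw_start_g=_by_group(
            {"adult": 24.0, "old_vehicle": 30.0, "old_pdx": 30.0},
            {"adult": 30.0, "old_vehicle": 38.0, "old_pdx": 38.0},
        ),
        bw_start_cv=0.07,
        bw_drift_pct=_by_group(
            {"adult": 0.25, "old_vehicle": -0.4, "old_pdx": -0.4},
            {"adult": 0.25, "old_vehicle": -0.4, "old_pdx": -0.4},
        ),
        bw_step_cv=0.008,
        mortality=_by_group(
            {"adult": 0.0, "old_vehicle": 0.10, "old_pdx": 0.0},
            {"adult": 0.0, "old_vehicle": 0.05, "old_pdx": 0.0},
        ),
        seed=seed,
    )


def _log_sigma(cv: float) -> float:
    """Log-scale sigma of a mean-one log-normal with coefficient of variation cv."""
    return sqrt(log(1.0 + cv * cv))


def _lognormal_factor(rng: np.random.Generator, sigma: float, z: float | None = None,
                      size: int | None = None) -> np.ndarray | float:
    """Mean-one log-normal multiplier; with z given, uses that normal deviate."""
    if sigma == 0.0:
        return np.ones(size) if size is not None else 1.0
    if z is None:
        z = rng.standard_normal(size) if size is not None else rng.standard_normal()
    return np.exp(sigma * z - 0.5 * sigma * sigma)


def _iter_cells(config: GeneratorConfig) -> Iterator[tuple[str, str]]:
    for sex in SEXES:
        for group in GROUPS:
            yield sex, group


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a full validated cohort from ``config`` (seed inside the config)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    loading = config.vigor_loading
    resid = sqrt(max(0.0, 1.0 - loading * loading))
    n_items = len(DEFAULT_DEFICIT_ITEMS)

    animal_rows, trial_rows, bw_rows, deficit_rows = [], [], [], []

    for sex, group in _iter_cells(config):
        for i in range(config.n[sex][group]):
            animal_id = f"{sex[0]}_{_GROUP_CODE[group]}_{i + 1:03d}"
            vigor = rng.standard_normal()
            # persistent per-test residuals: baseline and endpoint share them
            test_resid = {t: rng.standard_normal() for t in TESTS}
            fi_resid = rng.standard_normal()

            dead = rng.random() < config.mortality[sex][group]
            lo, hi = config.death_week_range
            death_week = int(rng.integers(lo, hi + 1)) if dead else None
            timepoints = ("baseline",) if dead else TIMEPOINTS

            for tp in timepoints:
                for test in TESTS:
                    z = loading * vigor + resid * test_resid[test]
                    latent = config.mean_for(test, sex, group, tp) * _lognormal_factor(
                        rng, _log_sigma(config.animal_cv[test]), z=z
                    )
                    k = TRIAL_COUNTS[test]
                    values = latent * np.atleast_1d(
                        _lognormal_factor(rng, _log_sigma(config.trial_cv[test]), size=k)
                    )
                    for j, v in enumerate(values, start=1):
                        trial_rows.append(
                            {"animal_id": animal_id, "timepoint": tp, "test": test,
                             "trial_index": j, "value": float(v)}
                        )
                # frailty-index target, negatively loaded on vigor
                z_fi = -loading * vigor + resid * fi_resid
                target = config.fi_for(sex, group, tp) * _lognormal_factor(
                    rng, _log_sigma(config.fi_cv), z=z_fi
                )
                scores = _deficit_scores(rng, float(np.clip(target, 0.0, 1.0)), n_items)
                for item, score in zip(DEFAULT_DEFICIT_ITEMS, scores):
                    deficit_rows.append(
                        {"animal_id": animal_id, "timepoint": tp, "item": item,
                         "score": float(score)}
                    )

            last_week = death_week if dead else config.n_weeks
            weight = config.bw_start_g[sex][group] * float(
                _lognormal_factor(rng, _log_sigma(config.bw_start_cv))
            )
            drift = 1.0 + config.bw_drift_pct[sex][group] / 100.0
            for week in range(1, last_week + 1):
                if week > 1:
                    step = drift * (1.0 + config.bw_step_cv * rng.standard_normal())
                    weight *= max(step, 0.5)  # guard against absurd negative steps
                bw_rows.append({"animal_id": animal_id, "week": week,
                                "weight_g": float(weight)})

            animal_rows.append({"animal_id": animal_id, "sex": sex, "group": group,
                                "alive_at_endpoint": not dead})

    return Cohort.from_frames(
        animals=pd.DataFrame(animal_rows, columns=["animal_id", "sex", "group",
                                                   "alive_at_endpoint"]),
        trials=pd.DataFrame(trial_rows, columns=["animal_id", "timepoint", "test",
                                                 "trial_index", "value"]),
        bodyweight=pd.DataFrame(bw_rows, columns=["animal_id", "week", "weight_g"]),
        deficits=pd.DataFrame(deficit_rows, columns=["animal_id", "timepoint", "item",
                                                     "score"]),
    )


def config_from_dict(data: dict | None) -> GeneratorConfig:
    """Build a config from a (possibly partial) nested mapping.

    Keys mirror the :class:`GeneratorConfig` fields; anything omitted
    falls back to :func:`default_paper_config`. This is the schema of
    the YAML files the CLI accepts.
    """
    config = default_paper_config()
    if not data:
        return config
    unknown = set(data) - set(config.__dataclass_fields__)
    if unknown:
        raise CohortValidationError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        current = getattr(config, key)
        if isinstance(current, dict) and isinstance(value, dict):
            setattr(config, key, _deep_merge(current, value))
        elif key == "death_week_range":
            setattr(config, key, tuple(value))
        else:
            setattr(config, key, value)
    config.validate()
    return config


def load_config(path) -> GeneratorConfig:
    """Load a YAML generator config (see :func:`config_from_dict`)."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise CohortValidationError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


def _deep_merge(base: dict, override: dict) -> dict:
    merged = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = value
    return merged


def _deficit_scores(rng: np.random.Generator, target_fi: float, n_items: int) -> np.ndarray:
    """Item scores realizing the target index on the instrument's 0.5 grid.

    The target is converted to a total of half-points ``s = round(54*fi)``
    and distributed mild-first (a moderately frail mouse accumulates many
    mild deficits before severe ones): all-mild while ``s <= n_items``,
    then severe deficits replace mild ones. Which items carry the
    deficits is drawn at random per assessment.
    """
    s = int(round(target_fi * n_items * 2))
    s = min(max(s, 0), n_items * 2)
    if s <= n_items:
        n_severe, n_mild = 0, s
    else:
        n_severe = s - n_items
        n_mild = n_items - n_severe
    scores = np.zeros(n_items)
    chosen = rng.choice(n_items, size=n_severe + n_mild, replace=False)
    scores[chosen[:n_severe]] = 1.0
    scores[chosen[n_severe:n_severe + n_mild]] = 0.5
    return scores
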