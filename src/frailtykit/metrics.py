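"""Reduce raw trials and weight series to per-animal criterion values.

The six frailty criteria, with abbreviations used throughout:

======  ===========================================  ==========
field   meaning                                      units
======  ===========================================  ==========
ws      best rotarod speed out of 3 trials           rpm
gft     trimmed mean of 5 grip trials                force (g)
td      treadmill distance to exhaustion             m
vrw     mean daily voluntary wheel distance (4 d)    km/day
fi      frailty index: deficit sum / 27              fraction
dbw     average weekly percent body-weight change    %/week
======  ===========================================  ==========
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, TIMEPOINTS
from .errors import CohortValidationError
from .instrument import VALID_SCORES

logger = logging.getLogger(__name__)

#: The six criterion columns of a criterion panel, in canonical order.
CRITERIA: tuple[str, ...] = ("ws", "gft", "td", "vrw", "fi", "dbw")

#: Body-weight windows (inclusive study weeks) used for dbw at each
#: assessment: baseline uses only pre-treatment weeks, endpoint the
#: whole study.
DEFAULT_BW_WINDOWS: dict[str, tuple[int, int]] = {
    "baseline": (1, 4),
    "endpoint": (1, 13),
}

PANEL_COLUMNS = ["animal_id", "timepoint", *CRITERIA]


def best_walking_speed(trials: Sequence[float]) -> float:
    """Best maximal rotarod speed (rpm) out of exactly three trials."""
    values = _checked_values("walking_speed", trials, 3)
    return float(np.max(values))


def trimmed_grip_strength(trials: Sequence[float]) -> float:
    """Mean grip force after dropping one highest and one lowest of 5 trials.

    With tied extremes exactly one occurrence of the maximum and one of
    the minimum are removed.
    """
    values = np.sort(_checked_values("grip_strength", trials, 5))
    return float(np.mean(values[1:-1]))


def mean_daily_activity(days: Sequence[float]) -> float:
    """Mean daily wheel-running distance (km/day) over 4 experimental days."""
    values = _checked_values("activity", days, 4)
    return float(np.mean(values))


def frailty_index(items: Mapping[str, float], n_items: int = 27) -> float:
    """Deficit-accumulation index: sum of item scores divided by the item count.

    Each of the ``n_items`` scores must be 0 (no deficit), 0.5 (mild) or
    1 (severe); the result lies in [0, 1], higher meaning frailer.
    """
    if len(items) != n_items:
        raise CohortValidationError(
            f"frailty index requires exactly {n_items} items, got {len(items)}"
        )
    scores = np.asarray(list(items.values()), dtype=float)
    invalid = [s for s in scores if s not in VALID_SCORES]
    if invalid:
        raise CohortValidationError(
            f"deficit score {invalid[0]!r} not in allowed set {{0, 0.5, 1}}"
        )
    return float(scores.sum() / n_items)


def avg_weekly_bw_change(
    weeks: Sequence[int],
    weights_g: Sequence[float],
    window: tuple[int, int] | None = None,
) -> float:
    """Average weekly percent change in body weight (%/week).

    The mean over consecutive recorded weeks of
    ``100 * (w[i+1] - w[i]) / w[i]``, restricted to ``window``
    (inclusive week range) when given. Fewer than two points in the
    window yields NaN with a warning rather than an error, since a
    missing criterion is an expected state for animals that died.
    """
    weeks_arr = np.asarray(weeks, dtype=float)
    w = np.asarray(weights_g, dtype=float)
    if weeks_arr.shape != w.shape:
        raise CohortValidationError("weeks and weights must have matching lengths")
    order = np.argsort(weeks_arr)
    weeks_arr, w = weeks_arr[order], w[order]
    if window is not None:
        lo, hi = window
        mask = (weeks_arr >= lo) & (weeks_arr <= hi)
        weeks_arr, w = weeks_arr[mask], w[mask]
    if len(w) < 2:
        logger.warning(
            "avg_weekly_bw_change: fewer than 2 weights in window %s; returning NaN",
            window,
        )
        return float("nan")
    pct = 100.0 * np.diff(w) / w[:-1]
    return float(np.mean(pct))


def delta_metric(baseline: float, endpoint: float) -> float:
    """Endpoint minus baseline; NaN if either is missing."""
    if baseline is None or endpoint is None:
        return float("nan")
    baseline, endpoint = float(baseline), float(endpoint)
    if np.isnan(baseline) or np.isnan(endpoint):
        return float("nan")
    return endpoint - baseline


def trapezoid_auc(times: Sequence[float], values: Sequence[float]) -> float:
    """Composite trapezoidal area under a longitudinal curve."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise CohortValidationError("times and values must have matching lengths")
    if len(t) < 2:
        raise CohortValidationError("AUC requires at least 2 points")
    if not np.all(np.diff(t) > 0):
        raise CohortValidationError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def build_criterion_panel(
    cohort: Cohort,
    timepoint: str,
    bw_windows: Mapping[str, tuple[int, int]] = DEFAULT_BW_WINDOWS,
) -> pd.DataFrame:
    """One criterion panel row per living animal at ``timepoint``.

    At baseline every animal is included; at endpoint only animals alive
    at the end of the study. Tests an animal did not perform propagate
    as NaN criteria (logged), never as errors, so a surviving animal is
    always classifiable.
    """
    if timepoint not in TIMEPOINTS:
        raise CohortValidationError(f"unknown timepoint {timepoint!r}")
    animals = cohort.animals
    if timepoint == "endpoint":
        animals = animals.loc[animals["alive_at_endpoint"]]

    reducers = {
        "ws": ("walking_speed", best_walking_speed),
        "gft": ("grip_strength", trimmed_grip_strength),
        "td": ("endurance", lambda v: float(v[0])),
        "vrw": ("activity", mean_daily_activity),
    }
    # pre-group the long tables once; per-animal full-table scans do not
    # scale to simulated cohorts of thousands of animals
    trials_tp = cohort.trials.loc[cohort.trials["timepoint"] == timepoint]
    trials_tp = trials_tp.sort_values(["animal_id", "test", "trial_index"])
    trial_map = {
        key: grp["value"].to_numpy(dtype=float)
        for key, grp in trials_tp.groupby(["animal_id", "test"], sort=False)
    }
    deficits_tp = cohort.deficits.loc[cohort.deficits["timepoint"] == timepoint]
    fi_map = {
        animal: frailty_index(dict(zip(grp["item"], grp["score"])),
                              n_items=len(cohort.deficit_items))
        for animal, grp in deficits_tp.groupby("animal_id", sort=False)
    }
    window = bw_windows.get(timepoint)
    bw_map = {
        animal: (grp["week"].to_numpy(), grp["weight_g"].to_numpy())
        for animal, grp in cohort.bodyweight.groupby("animal_id", sort=False)
    }

    rows = []
    for animal_id in animals["animal_id"]:
        row: dict[str, object] = {"animal_id": animal_id, "timepoint": timepoint}
        for crit, (test, reduce) in reducers.items():
            values = trial_map.get((animal_id, test))
            if values is None:
                logger.warning("animal %s: no %s trials at %s; %s set missing",
                               animal_id, test, timepoint, crit)
                row[crit] = float("nan")
            else:
                row[crit] = reduce(values)
        if animal_id not in fi_map:
            logger.warning("animal %s: no deficit scores at %s; fi set missing",
                           animal_id, timepoint)
            row["fi"] = float("nan")
        else:
            row["fi"] = fi_map[animal_id]
        if animal_id not in bw_map:
            logger.warning("animal %s: no body weights; dbw set missing", animal_id)
            row["dbw"] = float("nan")
        else:
            weeks, weights = bw_map[animal_id]
            row["dbw"] = avg_weekly_bw_change(weeks, weights, window=window)
        rows.append(row)
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    panel[list(CRITERIA)] = panel[list(CRITERIA)].astype(float)
    return panel


def _checked_values(test: str, values: Sequence[float], expected: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or len(arr) != expected:
        raise CohortValidationError(
            f"test {test!r} requires exactly {expected} values, got {arr.size}"
        )
    if np.isnan(arr).any() or (arr < 0).any():
        raise CohortValidationError(
            f"test {test!r} values must be non-negative reals, got {values!r}"
        )
    return arr
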