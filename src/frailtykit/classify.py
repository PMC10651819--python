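"""Frailty classification: percentile cutoffs, marker flags, categories,
and longitudinal transitions.

The reference distribution for each criterion is the sex-matched Old
cohort (vehicle- and treatment-assigned pooled) at baseline. Values are
first *oriented* so that lower always means frailer — criteria where a
higher value indicates frailty (the frailty index) are negated — and the
cutoff is the 20th percentile of the oriented reference values, computed
by linear interpolation between order statistics at index ``(n-1)*p``.
An animal is positive for a marker when its oriented value falls
strictly below the cutoff; three or more positive markers out of six
classify it as frail, exactly two as prefrail, one or zero as robust.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CohortValidationError
from .metrics import CRITERIA

logger = logging.getLogger(__name__)

LOWER = "lower_is_frailer"
HIGHER = "higher_is_frailer"

#: Default direction in which each criterion indicates frailty. A more
#: negative dbw means faster weight loss, hence lower_is_frailer.
DEFAULT_ORIENTATION: dict[str, str] = {
    "ws": LOWER,
    "gft": LOWER,
    "td": LOWER,
    "vrw": LOWER,
    "fi": HIGHER,
    "dbw": LOWER,
}

CATEGORIES: tuple[str, ...] = ("robust", "prefrail", "frail")

QUANTILE = 0.20
MIN_REFERENCE_N = 5

CUTOFF_COLUMNS = ["sex", "criterion", "cutoff", "orientation", "n_used"]


def _check_orientation(orientation: dict[str, str]) -> None:
    if set(orientation) != set(CRITERIA):
        raise CohortValidationError(
            f"orientation must cover exactly the criteria {CRITERIA}, got {sorted(orientation)}"
        )
    bad = {k: v for k, v in orientation.items() if v not in (LOWER, HIGHER)}
    if bad:
        raise CohortValidationError(f"invalid orientation directions: {bad}")


def orient(values: np.ndarray | float, direction: str) -> np.ndarray | float:
    """Map values onto the common frailer-is-lower scale."""
    if direction == LOWER:
        return values
    if direction == HIGHER:
        return -values
    raise CohortValidationError(f"unknown orientation {direction!r}")


def derive_cutoffs(
    reference_panels: pd.DataFrame,
    orientation: dict[str, str] = DEFAULT_ORIENTATION,
    quantile: float = QUANTILE,
    min_n: int = MIN_REFERENCE_N,
) -> pd.DataFrame:
    """Sex-specific per-criterion cutoffs from reference panels.

    ``reference_panels`` must carry a ``sex`` column in addition to the
    criterion columns, and should already be restricted to the intended
    reference population (Old animals at baseline for the primary rule).
    Cutoffs are stored on the oriented scale.
    """
    _check_orientation(orientation)
    if "sex" not in reference_panels.columns:
        raise CohortValidationError("reference panels must include a 'sex' column")
    rows = []
    for sex, grp in reference_panels.groupby("sex", sort=True):
        for crit in CRITERIA:
            values = grp[crit].to_numpy(dtype=float)
            values = values[~np.isnan(values)]
            if len(values) == 0:
                raise CohortValidationError(
                    f"cannot derive cutoff for sex {sex!r}, criterion {crit!r}: "
                    "all reference values missing"
                )
            if len(values) < min_n:
                raise CohortValidationError(
                    f"cannot derive cutoff for sex {sex!r}, criterion {crit!r}: "
                    f"only {len(values)} reference animals, need >= {min_n}"
                )
            oriented = orient(values, orientation[crit])
            cutoff = float(np.quantile(oriented, quantile, method="linear"))
            rows.append({"sex": sex, "criterion": crit, "cutoff": cutoff,
                         "orientation": orientation[crit], "n_used": len(values)})
    return pd.DataFrame(rows, columns=CUTOFF_COLUMNS)


def _cutoff_lookup(cutoffs: pd.DataFrame) -> dict[tuple[str, str], float]:
    return {(r.sex, r.criterion): r.cutoff for r in cutoffs.itertuples()}


def flag_positive(
    panel_row: pd.Series | dict,
    cutoffs: pd.DataFrame,
    orientation: dict[str, str] = DEFAULT_ORIENTATION,
) -> dict[str, bool]:
    """Positive-marker mapping for one animal's criterion panel.

    A marker is positive iff the oriented value is strictly below the
    sex-matched cutoff ("fell below the 20th percentile"); a value
    exactly at the cutoff is not positive, and a missing criterion is
    counted not-positive with a warning so the animal stays classifiable.
    """
    _check_orientation(orientation)
    row = dict(panel_row)
    sex = row.get("sex")
    lookup = _cutoff_lookup(cutoffs)
    if not any(key[0] == sex for key in lookup):
        raise CohortValidationError(
            f"no cutoffs available for sex {sex!r} (animal {row.get('animal_id')!r})"
        )
    markers: dict[str, bool] = {}
    for crit in CRITERIA:
        value = float(row[crit])
        if np.isnan(value):
            logger.warning("animal %s: criterion %s missing; marker counted negative",
                           row.get("animal_id"), crit)
            markers[crit] = False
            continue
        markers[crit] = bool(orient(value, orientation[crit]) < lookup[(sex, crit)])
    return markers


def classify(tally: int) -> str:
    """Category from the positive-marker count: >=3 frail, ==2 prefrail, <=1 robust."""
    if not isinstance(tally, (int, np.integer)) or not 0 <= int(tally) <= len(CRITERIA):
        raise CohortValidationError(
            f"tally must be an integer in 0..{len(CRITERIA)}, got {tally!r}"
        )
    tally = int(tally)
    if tally >= 3:
        return "frail"
    if tally == 2:
        return "prefrail"
    return "robust"


def classify_cohort(
    panels: pd.DataFrame,
    cutoffs: pd.DataFrame,
    orientation: dict[str, str] = DEFAULT_ORIENTATION,
) -> pd.DataFrame:
    """Marker flags, tally and category for every animal in ``panels``.

    ``panels`` must include a ``sex`` column (see
    :func:`frailtykit.report.attach_animal_metadata`).
    """
    records = []
    for _, row in panels.iterrows():
        markers = flag_positive(row, cutoffs, orientation)
        tally = int(sum(markers.values()))
        rec = {"animal_id": row["animal_id"], "timepoint": row["timepoint"]}
        rec.update({f"{c}_positive": markers[c] for c in CRITERIA})
        rec["tally"] = tally
        rec["category"] = classify(tally)
        records.append(rec)
    columns = ["animal_id", "timepoint", *(f"{c}_positive" for c in CRITERIA),
               "tally", "category"]
    out = pd.DataFrame(records, columns=columns)
    if len(out):
        out["tally"] = out["tally"].astype(int)
    return out


@dataclass
class TransitionMatrix:
    """Baseline→endpoint category flows plus animals lost before endpoint."""

    counts: pd.DataFrame   # 3x3, index=baseline category, columns=endpoint category
    lost: pd.Series        # per baseline category, animals with no endpoint class

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum() + self.lost.sum())

    def fraction_robust_declined(self) -> float:
        """Of baseline-robust animals classified at endpoint, fraction no longer robust."""
        robust = self.counts.loc["robust"]
        n = robust.sum()
        return float((robust["prefrail"] + robust["frail"]) / n) if n else float("nan")

    def fraction_improved(self) -> float:
        """Of baseline prefrail/frail animals classified at endpoint, fraction that improved."""
        improved = (self.counts.loc["prefrail", "robust"]
                    + self.counts.loc["frail", "robust"]
                    + self.counts.loc["frail", "prefrail"])
        n = self.counts.loc[["prefrail", "frail"]].to_numpy().sum()
        return float(improved / n) if n else float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Long-form (from, to, count) table including the lost column."""
        rows = [
            {"from": b, "to": e, "count": int(self.counts.loc[b, e])}
            for b in CATEGORIES for e in CATEGORIES
        ]
        rows += [{"from": b, "to": "lost", "count": int(self.lost[b])} for b in CATEGORIES]
        return pd.DataFrame(rows, columns=["from", "to", "count"])


def track_transitions(
    baseline: pd.DataFrame, endpoint: pd.DataFrame
) -> TransitionMatrix:
    """Count category transitions between two classification tables.

    Animals classified at baseline but absent at endpoint (death,
    missing assessment) go to the ``lost`` column; an animal present at
    endpoint without a baseline classification is an error.
    """
    b_map = dict(zip(baseline["animal_id"], baseline["category"]))
    e_map = dict(zip(endpoint["animal_id"], endpoint["category"]))
    orphans = set(e_map) - set(b_map)
    if orphans:
        raise CohortValidationError(
            f"animal_id {sorted(orphans)[0]!r} classified at endpoint but not baseline"
        )
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES), dtype=int)
    lost = pd.Series(0, index=list(CATEGORIES), dtype=int)
    for animal, b_cat in b_map.items():
        if animal in e_map:
            counts.loc[b_cat, e_map[animal]] += 1
        else:
            lost[b_cat] += 1
    return TransitionMatrix(counts=counts, lost=lost)


def survival_rate(animals: pd.DataFrame, group: str, sex: str) -> float:
    """Percent of a (group, sex) cell alive at the study endpoint."""
    cell = animals.loc[(animals["group"] == group) & (animals["sex"] == sex)]
    if cell.empty:
        raise CohortValidationError(f"no animals with group {group!r} and sex {sex!r}")
    return float(100.0 * cell["alive_at_endpoint"].sum() / len(cell))
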