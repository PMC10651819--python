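"""Typed data model and CSV I/O for the longitudinal cohort.

The cohort is four tables, keyed by (animal_id, timepoint) where
applicable, exchanged as UTF-8 CSV with a header row:

``animals.csv``     animal_id,sex,group,alive_at_endpoint
``trials.csv``      animal_id,timepoint,test,trial_index,value
``bodyweight.csv``  animal_id,week,weight_g
``deficits.csv``    animal_id,timepoint,item,score

Missing measurements are encoded by *absent rows* (a test an animal
never performed has no trial rows); downstream criterion values derived
from them are NaN in memory and empty fields in CSV. Validation is
total: a malformed file raises :class:`~frailtykit.errors.SchemaError`
or :class:`~frailtykit.errors.CohortValidationError` and never yields a
partially loaded cohort.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError
from .instrument import DEFAULT_DEFICIT_ITEMS, VALID_SCORES

SEXES: tuple[str, ...] = ("female", "male")
GROUPS: tuple[str, ...] = ("adult", "old_vehicle", "old_pdx")
TIMEPOINTS: tuple[str, ...] = ("baseline", "endpoint")
#: Tests and the exact number of trial rows each must carry.
TRIAL_COUNTS: dict[str, int] = {
    "walking_speed": 3,   # rotarod maxima, rpm
    "grip_strength": 5,   # combined fore+hindlimb peak force
    "endurance": 1,       # treadmill distance to exhaustion, m
    "activity": 4,        # daily wheel distance, km/day (acclimation day excluded)
}

TABLE_COLUMNS: dict[str, list[str]] = {
    "animals": ["animal_id", "sex", "group", "alive_at_endpoint"],
    "trials": ["animal_id", "timepoint", "test", "trial_index", "value"],
    "bodyweight": ["animal_id", "week", "weight_g"],
    "deficits": ["animal_id", "timepoint", "item", "score"],
}

TABLE_FILENAMES: dict[str, str] = {name: f"{name}.csv" for name in TABLE_COLUMNS}


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame(columns=TABLE_COLUMNS[name])


@dataclass
class Cohort:
    """A fully validated in-memory cohort.

    Construct via :meth:`from_frames` or :func:`read_cohort`; both run
    the full invariant check. Mutating the frames afterwards bypasses
    validation — call :meth:`validate` again if you do.
    """

    animals: pd.DataFrame = field(default_factory=lambda: _empty_table("animals"))
    trials: pd.DataFrame = field(default_factory=lambda: _empty_table("trials"))
    bodyweight: pd.DataFrame = field(default_factory=lambda: _empty_table("bodyweight"))
    deficits: pd.DataFrame = field(default_factory=lambda: _empty_table("deficits"))
    deficit_items: tuple[str, ...] = DEFAULT_DEFICIT_ITEMS

    @classmethod
    def from_frames(
        cls,
        animals: pd.DataFrame,
        trials: pd.DataFrame | None = None,
        bodyweight: pd.DataFrame | None = None,
        deficits: pd.DataFrame | None = None,
        deficit_items: Sequence[str] = DEFAULT_DEFICIT_ITEMS,
    ) -> "Cohort":
        cohort = cls(
            animals=_normalize("animals", animals),
            trials=_normalize("trials", trials if trials is not None else _empty_table("trials")),
            bodyweight=_normalize(
                "bodyweight", bodyweight if bodyweight is not None else _empty_table("bodyweight")
            ),
            deficits=_normalize(
                "deficits", deficits if deficits is not None else _empty_table("deficits")
            ),
            deficit_items=tuple(deficit_items),
        )
        cohort.validate()
        return cohort

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        """Enforce every cohort invariant; raise on the first violation."""
        self._validate_animals()
        known_ids = set(self.animals["animal_id"])
        self._validate_trials(known_ids)
        self._validate_bodyweight(known_ids)
        self._validate_deficits(known_ids)

    def _validate_animals(self) -> None:
        df = self.animals
        dup = df["animal_id"][df["animal_id"].duplicated()]
        if not dup.empty:
            raise CohortValidationError(
                f"animal_id {dup.iloc[0]!r}: duplicated; animal_id must be unique within a cohort"
            )
        for col, allowed in (("sex", SEXES), ("group", GROUPS)):
            bad = df.loc[~df[col].isin(allowed)]
            if not bad.empty:
                raise CohortValidationError(
                    f"animal_id {bad['animal_id'].iloc[0]!r}: field {col} value "
                    f"{bad[col].iloc[0]!r} not in {allowed}"
                )
        if not df.empty and df["alive_at_endpoint"].dtype != bool:
            bad = df.loc[~df["alive_at_endpoint"].isin([True, False])]
            first = bad["animal_id"].iloc[0] if not bad.empty else df["animal_id"].iloc[0]
            raise CohortValidationError(
                f"animal_id {first!r}: field alive_at_endpoint must be boolean True/False"
            )

    def _validate_trials(self, known_ids: set[str]) -> None:
        df = self.trials
        if df.empty:
            return
        self._check_ids("trials", df, known_ids)
        bad_tp = df.loc[~df["timepoint"].isin(TIMEPOINTS)]
        if not bad_tp.empty:
            raise CohortValidationError(
                f"animal_id {bad_tp['animal_id'].iloc[0]!r}: field timepoint value "
                f"{bad_tp['timepoint'].iloc[0]!r} not in {TIMEPOINTS}"
            )
        bad_test = df.loc[~df["test"].isin(TRIAL_COUNTS)]
        if not bad_test.empty:
            raise CohortValidationError(
                f"animal_id {bad_test['animal_id'].iloc[0]!r}: field test value "
                f"{bad_test['test'].iloc[0]!r} not in {tuple(TRIAL_COUNTS)}"
            )
        if df["value"].isna().any() or (df["value"] < 0).any():
            bad = df.loc[df["value"].isna() | (df["value"] < 0)]
            raise CohortValidationError(
                f"animal_id {bad['animal_id'].iloc[0]!r}: field value for test "
                f"{bad['test'].iloc[0]!r} must be a non-negative number"
            )
        for (animal, tp, test), grp in df.groupby(
            ["animal_id", "timepoint", "test"], sort=False
        ):
            expected = TRIAL_COUNTS[test]
            if len(grp) != expected:
                raise CohortValidationError(
                    f"animal_id {animal!r}: test {test!r} at {tp} has {len(grp)} trials, "
                    f"requires exactly {expected}"
                )
            idx = sorted(grp["trial_index"])
            if idx != list(range(1, expected + 1)):
                raise CohortValidationError(
                    f"animal_id {animal!r}: test {test!r} at {tp} trial_index must be "
                    f"1..{expected} without repeats, got {idx}"
                )

    def _validate_bodyweight(self, known_ids: set[str]) -> None:
        df = self.bodyweight
        if df.empty:
            return
        self._check_ids("bodyweight", df, known_ids)
        if df["weight_g"].isna().any() or (df["weight_g"] <= 0).any():
            bad = df.loc[df["weight_g"].isna() | (df["weight_g"] <= 0)]
            raise CohortValidationError(
                f"animal_id {bad['animal_id'].iloc[0]!r}: field weight_g must be > 0"
            )
        for animal, grp in df.groupby("animal_id", sort=False):
            weeks = grp["week"].to_numpy()
            if not np.all(np.diff(np.sort(weeks)) > 0):
                raise CohortValidationError(
                    f"animal_id {animal!r}: field week must be strictly increasing "
                    "(duplicate week found)"
                )

    def _validate_deficits(self, known_ids: set[str]) -> None:
        df = self.deficits
        if df.empty:
            return
        self._check_ids("deficits", df, known_ids)
        bad_score = df.loc[~df["score"].isin(VALID_SCORES)]
        if not bad_score.empty:
            raise CohortValidationError(
                f"animal_id {bad_score['animal_id'].iloc[0]!r}: field score value "
                f"{bad_score['score'].iloc[0]!r} not in allowed set {{0, 0.5, 1}}"
            )
        expected = set(self.deficit_items)
        n = len(expected)
        for (animal, tp), grp in df.groupby(["animal_id", "timepoint"], sort=False):
            items = set(grp["item"])
            if len(grp) != n or items != expected:
                missing = sorted(expected - items)[:3]
                extra = sorted(items - expected)[:3]
                raise CohortValidationError(
                    f"animal_id {animal!r}: deficits at {tp} must cover exactly {n} "
                    f"instrument items; missing={missing} extra={extra}"
                )

    @staticmethod
    def _check_ids(table: str, df: pd.DataFrame, known_ids: set[str]) -> None:
        unknown = df.loc[~df["animal_id"].isin(known_ids)]
        if not unknown.empty:
            raise CohortValidationError(
                f"animal_id {unknown['animal_id'].iloc[0]!r} in {table} is not "
                "present in animals table"
            )

    # -- convenience ---------------------------------------------------

    def trial_values(self, animal_id: str, timepoint: str, test: str) -> np.ndarray | None:
        """Ordered trial values for one (animal, timepoint, test), or None if absent."""
        sel = self.trials.loc[
            (self.trials["animal_id"] == animal_id)
            & (self.trials["timepoint"] == timepoint)
            & (self.trials["test"] == test)
        ]
        if sel.empty:
            return None
        return sel.sort_values("trial_index")["value"].to_numpy(dtype=float)

    def equals(self, other: "Cohort") -> bool:
        """Value-for-value equality of all four tables (order-insensitive)."""
        for name in TABLE_COLUMNS:
            a = _canonical_sort(name, getattr(self, name)).reset_index(drop=True)
            b = _canonical_sort(name, getattr(other, name)).reset_index(drop=True)
            if not a.equals(b):
                return False
        return True


# -- normalisation and I/O --------------------------------------------

_SORT_KEYS: dict[str, list[str]] = {
    "animals": ["animal_id"],
    "trials": ["animal_id", "timepoint", "test", "trial_index"],
    "bodyweight": ["animal_id", "week"],
    "deficits": ["animal_id", "timepoint", "item"],
}

_DTYPES: dict[str, dict[str, type]] = {
    "animals": {"animal_id": str, "sex": str, "group": str},
    "trials": {"animal_id": str, "timepoint": str, "test": str, "trial_index": int,
               "value": float},
    "bodyweight": {"animal_id": str, "week": int, "weight_g": float},
    "deficits": {"animal_id": str, "timepoint": str, "item": str, "score": float},
}


def _normalize(name: str, df: pd.DataFrame) -> pd.DataFrame:
    expected = TABLE_COLUMNS[name]
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{name} table: missing columns {missing}, unexpected columns {extra}; "
            f"required schema is {expected}"
        )
    df = df[expected].copy()
    for col, dtype in _DTYPES[name].items():
        try:
            df[col] = df[col].astype(dtype) if len(df) else df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(
                f"{name} table: column {col!r} could not be coerced to {dtype.__name__}: {exc}"
            ) from exc
    if name == "animals" and len(df):
        df["alive_at_endpoint"] = _parse_bool_column(df["alive_at_endpoint"])
    return _canonical_sort(name, df).reset_index(drop=True)


def _parse_bool_column(col: pd.Series) -> pd.Series:
    mapping = {True: True, False: False, "True": True, "False": False,
               "true": True, "false": False, 1: True, 0: False, "1": True, "0": False}
    out = col.map(mapping)
    if out.isna().any():
        bad = col[out.isna()].iloc[0]
        raise CohortValidationError(
            f"animals table: column alive_at_endpoint has non-boolean value {bad!r}"
        )
    return out.astype(bool)


def _canonical_sort(name: str, df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df
    return df.sort_values(_SORT_KEYS[name], kind="mergesort")


def read_cohort(
    directory: str | Path | None = None,
    paths: Mapping[str, str | Path] | None = None,
    deficit_items: Sequence[str] = DEFAULT_DEFICIT_ITEMS,
) -> Cohort:
    """Load and validate a cohort from CSV files.

    Either pass ``directory`` containing the four canonically named
    files, or an explicit ``paths`` mapping table name → file path.
    """
    if paths is None:
        if directory is None:
            raise ValueError("pass either directory or paths")
        paths = {name: Path(directory) / fn for name, fn in TABLE_FILENAMES.items()}
    frames: dict[str, pd.DataFrame] = {}
    for name in TABLE_COLUMNS:
        path = Path(paths[name])
        if not path.exists():
            raise SchemaError(f"{name} table: file not found: {path}")
        # round_trip parsing keeps write→read exact to the last ulp
        frames[name] = pd.read_csv(path, dtype={"animal_id": str},
                                   float_precision="round_trip")
    return Cohort.from_frames(
        animals=frames["animals"],
        trials=frames["trials"],
        bodyweight=frames["bodyweight"],
        deficits=frames["deficits"],
        deficit_items=deficit_items,
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write all four tables as CSV; returns the paths written.

    Output is deterministic: canonical row order, ``\\n`` line endings,
    and full-precision floats, so ``read_cohort(write_cohort(c))``
    reproduces ``c`` exactly and repeated writes are byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, fn in TABLE_FILENAMES.items():
        path = directory / fn
        df = _canonical_sort(name, getattr(cohort, name))
        write_table(df, path)
        written[name] = path
    return written


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV writer shared by every pipeline artifact."""
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
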