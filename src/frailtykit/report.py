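"""Pipeline driver and group summaries.

``run_pipeline`` chains every stage — cohort acquisition, criterion
panels, cutoff derivation, classification, transitions, survival and
group summaries — and writes a deterministic artifact set:

panel.csv, cutoffs.csv, classifications.csv, transitions.csv,
summary.csv, survival.csv, run_manifest.json and run.log.

Re-running on identical inputs is byte-identical: canonical row order,
no timestamps or locale-dependent formatting in any artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort, write_table
from .classify import (
    DEFAULT_ORIENTATION,
    classify_cohort,
    derive_cutoffs,
    survival_rate,
    track_transitions,
)
from .errors import CohortValidationError, FrailtyKitError
from .metrics import CRITERIA, build_criterion_panel
from .simulate import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

#: Study week of each criterion's assessment at baseline and endpoint;
#: used as the abscissa of the two-point AUC in group summaries. The
#: physical tests run in the first testing week, the frailty index and
#: weight-change window close in the second.
METRIC_WEEKS: dict[str, tuple[int, int]] = {
    "ws": (3, 12), "gft": (3, 12), "td": (3, 12), "vrw": (3, 12),
    "fi": (4, 13), "dbw": (4, 13),
}

SUMMARY_COLUMNS = ["sex", "group", "timepoint", "metric", "n", "mean", "sem",
                   "delta", "auc"]


class PipelineError(FrailtyKitError):
    """A stage failed; the message names the stage and the cause."""


def attach_animal_metadata(panel: pd.DataFrame, animals: pd.DataFrame) -> pd.DataFrame:
    """Join sex and group onto a criterion panel (or classification) table."""
    return panel.merge(animals[["animal_id", "sex", "group"]], on="animal_id",
                       how="left", validate="many_to_one")


def select_reference_panels(
    panels: pd.DataFrame, reference: str = "old_baseline"
) -> pd.DataFrame:
    """Reference population for cutoff derivation.

    ``old_baseline`` (primary rule): both old groups at baseline,
    sex-matched — baseline testing precedes treatment, so vehicle- and
    treatment-assigned old animals pool. ``all_animals``: every group at
    baseline (still sex-matched), the frailest-quintile-of-the-whole-
    cohort variant.
    """
    base = panels.loc[panels["timepoint"] == "baseline"]
    if reference == "old_baseline":
        return base.loc[base["group"].isin(["old_vehicle", "old_pdx"])]
    if reference == "all_animals":
        return base
    raise CohortValidationError(f"unknown cutoff reference {reference!r}")


def summarize_groups(
    panels: pd.DataFrame, classifications: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean ± SEM per (sex, group, timepoint, metric), with endpoint delta
    and two-point trapezoidal AUC over the assessment weeks.

    When classifications are given, per-cell category counts are
    appended as ``n_robust`` / ``n_prefrail`` / ``n_frail`` rows.
    """
    required = {"sex", "group", "timepoint", *CRITERIA}
    missing = required - set(panels.columns)
    if missing:
        raise CohortValidationError(f"panels missing columns {sorted(missing)}")

    cell_means: dict[tuple, float] = {}
    rows = []
    for (sex, group, tp), grp in panels.groupby(["sex", "group", "timepoint"], sort=True):
        for metric in CRITERIA:
            values = grp[metric].to_numpy(dtype=float)
            values = values[~np.isnan(values)]
            if len(values) == 0:
                logger.warning("summary cell (%s, %s, %s, %s) empty; row omitted",
                               sex, group, tp, metric)
                continue
            mean = float(np.mean(values))
            sem = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 \
                else float("nan")
            if len(values) == 1:
                logger.warning("summary cell (%s, %s, %s, %s) has a single value; "
                               "SEM undefined", sex, group, tp, metric)
            cell_means[(sex, group, tp, metric)] = mean
            rows.append({"sex": sex, "group": group, "timepoint": tp, "metric": metric,
                         "n": len(values), "mean": mean, "sem": sem,
                         "delta": float("nan"), "auc": float("nan")})
    for row in rows:
        if row["timepoint"] != "endpoint":
            continue
        key = (row["sex"], row["group"], "baseline", row["metric"])
        if key in cell_means:
            wb, we = METRIC_WEEKS[row["metric"]]
            row["delta"] = row["mean"] - cell_means[key]
            row["auc"] = 0.5 * (row["mean"] + cell_means[key]) * (we - wb)

    if classifications is not None:
        for (sex, group, tp), grp in classifications.groupby(
            ["sex", "group", "timepoint"], sort=True
        ):
            for cat in ("robust", "prefrail", "frail"):
                count = int((grp["category"] == cat).sum())
                rows.append({"sex": sex, "group": group, "timepoint": tp,
                             "metric": f"n_{cat}", "n": len(grp), "mean": float(count),
                             "sem": float("nan"), "delta": float("nan"),
                             "auc": float("nan")})
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return out.sort_values(["sex", "group", "timepoint", "metric"],
                           kind="mergesort").reset_index(drop=True)


def run_pipeline(
    source: GeneratorConfig | str | Path,
    outdir: str | Path,
    seed: int | None = None,
    sex_filter: str | None = None,
    cutoff_reference: str = "old_baseline",
    orientation: dict[str, str] = DEFAULT_ORIENTATION,
) -> dict[str, pd.DataFrame]:
    """Run every stage end-to-end and write the artifact set to ``outdir``.

    ``source`` is either a :class:`GeneratorConfig` (a cohort is
    simulated, and its tables written under ``outdir/cohort/``) or a
    path to a directory of cohort CSVs. ``seed`` overrides the config
    seed for simulated runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = _attach_run_log(outdir / "run.log")
    try:
        manifest: dict[str, object] = {"package": "frailtykit", "version": __version__}

        with _stage("acquire cohort"):
            if isinstance(source, GeneratorConfig):
                config = source.copy()
                if seed is not None:
                    config.seed = seed
                cohort = generate_cohort(config)
                write_cohort(cohort, outdir / "cohort")
                canonical = json.dumps(asdict(config), sort_keys=True)
                manifest["input"] = "simulated"
                manifest["config_sha256"] = hashlib.sha256(canonical.encode()).hexdigest()
                manifest["seed"] = config.seed
            else:
                cohort = read_cohort(source)
                manifest["input"] = str(source)

        with _stage("build criterion panels"):
            panels = pd.concat(
                [build_criterion_panel(cohort, tp) for tp in ("baseline", "endpoint")],
                ignore_index=True,
            )
            panels = attach_animal_metadata(panels, cohort.animals)
            if sex_filter is not None:
                panels = panels.loc[panels["sex"] == sex_filter].reset_index(drop=True)
                if panels.empty:
                    raise CohortValidationError(f"no animals with sex {sex_filter!r}")

        with _stage("derive cutoffs"):
            cutoffs = derive_cutoffs(select_reference_panels(panels, cutoff_reference),
                                     orientation=orientation)

        with _stage("classify cohort"):
            classifications = classify_cohort(panels, cutoffs, orientation=orientation)
            classifications = attach_animal_metadata(classifications, cohort.animals)

        with _stage("track transitions"):
            trans_rows = []
            for (sex, group), _ in classifications.groupby(["sex", "group"], sort=True):
                cell = classifications.loc[
                    (classifications["sex"] == sex) & (classifications["group"] == group)
                ]
                tm = track_transitions(
                    cell.loc[cell["timepoint"] == "baseline"],
                    cell.loc[cell["timepoint"] == "endpoint"],
                )
                frame = tm.to_frame()
                frame.insert(0, "group", group)
                frame.insert(0, "sex", sex)
                trans_rows.append(frame)
            transitions = pd.concat(trans_rows, ignore_index=True)

        with _stage("survival"):
            surv_rows = []
            for (sex, group), cell in cohort.animals.groupby(["sex", "group"], sort=True):
                if sex_filter is not None and sex != sex_filter:
                    continue
                surv_rows.append({"sex": sex, "group": group, "n": len(cell),
                                  "survival_pct": survival_rate(cohort.animals, group, sex)})
            survival = pd.DataFrame(surv_rows, columns=["sex", "group", "n", "survival_pct"])

        with _stage("summaries"):
            summary = summarize_groups(panels, classifications)

        artifacts = {
            "panel": panels, "cutoffs": cutoffs, "classifications": classifications,
            "transitions": transitions, "summary": summary, "survival": survival,
        }
        for name, df in artifacts.items():
            write_table(df, outdir / f"{name}.csv")
        manifest["artifacts"] = sorted(f"{n}.csv" for n in artifacts)
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return artifacts
    finally:
        _detach_run_log(log_handler)


# -- helpers -----------------------------------------------------------

class _stage:
    """Context manager that prefixes stage names onto pipeline failures."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self) -> None:
        logger.info("stage: %s", self.name)

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def _attach_run_log(path: Path) -> logging.Handler:
    handler = logging.FileHandler(path, mode="w", encoding="utf-8")
    handler.setLevel(logging.WARNING)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("frailtykit").addHandler(handler)
    return handler


def _detach_run_log(handler: logging.Handler) -> None:
    logging.getLogger("frailtykit").removeHandler(handler)
    handler.close()
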