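"""Reading, validation and RECIST-style summarisation of lesion time-series.

The canonical on-disk format is a long-format CSV with one row per
measurement and columns ``patient_id, lesion_id, day, diameter_mm``
(header row, UTF-8, comma-separated).  Other column names are handled via
a schema mapping at read time.  In memory a cohort is a validated pandas
DataFrame plus its scheduled imaging days.

Patient-level response at a visit follows RECIST 1.1 target-lesion logic:
the per-patient sum of longest diameters (SLD) is compared with its
baseline (day 0) value, and the visit is classified CR (all target lesion
diameters 0), PR (change <= -30 %), PD (change >= +20 %) or SD otherwise.
The percentage thresholds are overridable through :class:`RecistThresholds`.
PD is referenced to baseline rather than to the nadir; for the only use the
inclusion filter makes of it — the first on-treatment visit — baseline and
nadir coincide.

The inclusion rule used throughout the analysis keeps only patients whose
first on-treatment visit is SD, PR or CR: the object of study is response
followed by resistance re-growth, so primary-progressor patients (and
patients with no on-treatment imaging at all) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "RecistThresholds",
    "CohortDataset",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "summarize_visit",
    "orr_percent",
    "filter_responders",
]

#: Canonical column order of the long-format measurement table.
COLUMNS = ("patient_id", "lesion_id", "day", "diameter_mm")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """Rows of an input table violate the measurement invariants."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(f"{message} (rows: {list(rows)})")
        self.rows = list(rows)


@dataclass(frozen=True)
class RecistThresholds:
    """Target-lesion response thresholds, percent change of SLD from baseline."""

    pr_pct: float = -30.0
    pd_pct: float = 20.0

    def classify(self, pct_change: float, all_zero: bool) -> str:
        if all_zero:
            return "CR"
        if pct_change <= self.pr_pct:
            return "PR"
        if pct_change >= self.pd_pct:
            return "PD"
        return "SD"


@dataclass(frozen=True)
class CohortDataset:
    """A study arm's lesion measurements plus its imaging schedule.

    measurements : DataFrame with columns ``patient_id, lesion_id, day,
        diameter_mm``, one row per (patient, lesion, day).
    visit_days : strictly increasing scheduled imaging days, starting at 0
        (baseline).
    arm_label : free-text label of the treatment arm.
    """

    measurements: pd.DataFrame
    visit_days: tuple[int, ...]
    arm_label: str = ""

    def __post_init__(self) -> None:
        df = self.measurements
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        object.__setattr__(self, "visit_days", tuple(int(d) for d in self.visit_days))
        if not self.visit_days or self.visit_days[0] != 0:
            raise ValueError("visit_days must start at 0 (baseline)")
        if any(b <= a for a, b in zip(self.visit_days, self.visit_days[1:])):
            raise ValueError("visit_days must be strictly increasing")
        _validate_measurements(df, self.visit_days)

    @property
    def n_patients(self) -> int:
        return self.measurements["patient_id"].nunique()

    @property
    def n_lesions(self) -> int:
        return self.measurements.drop_duplicates(["patient_id", "lesion_id"]).shape[0]

    @property
    def on_treatment_days(self) -> tuple[int, ...]:
        return tuple(d for d in self.visit_days if d > 0)

    def with_measurements(self, df: pd.DataFrame) -> "CohortDataset":
        return replace(self, measurements=df.reset_index(drop=True))


def _validate_measurements(df: pd.DataFrame, visit_days: tuple[int, ...]) -> None:
    bad = df.index[df["diameter_mm"] < 0]
    if len(bad):
        raise ValidationError("negative diameter_mm", bad)
    bad = df.index[df["day"] < 0]
    if len(bad):
        raise ValidationError("negative day", bad)
    dup = df.duplicated(["patient_id", "lesion_id", "day"], keep=False)
    if dup.any():
        raise ValidationError("duplicate (patient_id, lesion_id, day)", df.index[dup])
    off = ~df["day"].isin(visit_days)
    if off.any():
        # unscheduled days are rejected, not snapped: switch-point candidates
        # are built from the schedule and must match the data exactly
        raise ValidationError("day not in visit schedule", df.index[off])


def read_cohort(path: str | Path, *, schema: Mapping[str, str] | None = None,
                visit_days: Sequence[int] | None = None,
                arm_label: str = "") -> CohortDataset:
    """Read a long-format lesion CSV into a validated :class:`CohortDataset`.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Optional mapping from the file's column names to the canonical names
        ``patient_id, lesion_id, day, diameter_mm``.
    visit_days:
        Scheduled imaging days.  Defaults to the sorted set of days present
        in the file (with day 0 required).
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns after mapping: {missing}")
    df = df.loc[:, list(COLUMNS)].copy()
    df["day"] = df["day"].astype(int)
    df["diameter_mm"] = df["diameter_mm"].astype(float)
    if visit_days is None:
        visit_days = sorted(df["day"].unique())
        if not visit_days or visit_days[0] != 0:
            raise ValidationError("no baseline (day 0) measurements in file", [])
    return CohortDataset(df.reset_index(drop=True), tuple(visit_days), arm_label)


def write_cohort(dataset: CohortDataset, path: str | Path) -> None:
    """Write the measurement table as canonical long-format CSV."""
    dataset.measurements.loc[:, list(COLUMNS)].to_csv(path, index=False)


def summarize_visit(dataset: CohortDataset, day: int, *,
                    thresholds: RecistThresholds = RecistThresholds()) -> pd.DataFrame:
    """Per-patient SLD, percent change from baseline and RECIST category at ``day``.

    Returns a DataFrame with columns ``patient_id, day, sld_mm,
    pct_change_from_baseline, recist_category``, one row per patient with a
    measurement at ``day``.  Every such patient must have baseline (day 0)
    measurements; at day 0 the change is 0 % by construction.
    """
    if day not in dataset.visit_days:
        raise ValueError(f"day {day} is not in the visit schedule {dataset.visit_days}")
    df = dataset.measurements
    at_day = df[df["day"] == day]
    base = df[df["day"] == 0].groupby("patient_id")["diameter_mm"].sum()
    rows = []
    for pid, grp in at_day.groupby("patient_id", sort=True):
        if pid not in base.index:
            raise ValueError(f"patient {pid!r} has no baseline (day 0) measurements")
        sld = float(grp["diameter_mm"].sum())
        bsl_sld = float(base.loc[pid])
        if bsl_sld <= 0:
            raise ValueError(f"patient {pid!r} has non-positive baseline SLD")
        pct = 100.0 * (sld - bsl_sld) / bsl_sld
        cat = thresholds.classify(pct, all_zero=bool((grp["diameter_mm"] == 0).all()))
        rows.append((pid, day, sld, pct, cat))
    return pd.DataFrame(rows, columns=[
        "patient_id", "day", "sld_mm", "pct_change_from_baseline", "recist_category",
    ])


def orr_percent(summaries: pd.DataFrame) -> float:
    """Objective response rate: 100 x (#CR + #PR) / #patients, nearest integer.

    ``summaries`` is the output of :func:`summarize_visit` (or any table with
    one row per patient and a ``recist_category`` column).
    """
    if len(summaries) == 0:
        raise ValueError("cannot compute ORR of an empty summary table")
    responders = summaries["recist_category"].isin(["CR", "PR"]).sum()
    return float(round(100.0 * responders / len(summaries)))


def filter_responders(dataset: CohortDataset, *,
                      thresholds: RecistThresholds = RecistThresholds()) -> CohortDataset:
    """Keep patients who are SD, PR or CR at the first on-treatment visit.

    Patients classified PD at the first on-treatment visit — and patients
    with no on-treatment measurement at all — are dropped with all their
    measurements.  Idempotent; may return an empty dataset.
    """
    on_days = dataset.on_treatment_days
    if not on_days:
        raise ValueError("dataset has no on-treatment visit days")
    first = on_days[0]
    summ = summarize_visit(dataset, first, thresholds=thresholds)
    keep = set(summ.loc[summ["recist_category"] != "PD", "patient_id"])
    df = dataset.measurements
    return dataset.with_measurements(df[df["patient_id"].isin(keep)])
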