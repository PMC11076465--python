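"""Cohort table: typed wide participant x variable data with loading/validation.

One row per participant.  Mandatory columns are the participant id, clinical
group, age, sex and education band; task scores are wide columns named
``<task_id>.primary`` / ``<task_id>.secondary`` and resolved against a
:class:`~cogbattery.catalog.TaskCatalog`.  Clinical scale scores collected at
two timepoints (recruitment baseline vs the visit closest to the cognitive
assessment) carry a ``_baseline`` / ``_assessment`` suffix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import TaskCatalog

logger = logging.getLogger(__name__)

GROUPS = ("control", "PD", "RBD")
AGE_DECADES = ("50s", "60s", "70s", "80s")
SEXES = ("male", "female")
EDUCATION_BANDS = ("none", "<5y", "5-10y", ">10y")
DEVICES = ("computer", "tablet", "phone")

MANDATORY_COLUMNS = ("participant_id", "group", "age_years", "sex", "education_band")

#: RBDSQ score strictly above this marks probable RBD
RBDSQ_PROBABLE_CUTOFF = 6

_CATEGORICAL_LEVELS = {
    "group": GROUPS,
    "age_decade": AGE_DECADES,
    "sex": SEXES,
    "education_band": EDUCATION_BANDS,
    "device": DEVICES,
}


class CohortError(ValueError):
    """Structured loading/validation failure."""


def age_decade_of(age_years) -> pd.Series:
    """Decade band for an age in years (ages >=80 all map to '80s')."""
    idx = np.clip(np.floor(np.asarray(age_years, dtype=float) / 10).astype(int), 5, 8)
    return pd.Series(np.array(AGE_DECADES)[idx - 5], index=getattr(age_years, "index", None))


@dataclass
class CohortTable:
    """Wide participant table with categorical columns coerced to fixed levels."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.df.columns]
        if missing:
            raise CohortError(f"missing mandatory columns: {missing}")
        df = self.df.copy()
        for col, levels in _CATEGORICAL_LEVELS.items():
            if col not in df.columns:
                continue
            values = df[col]
            bad = values.dropna()[~values.dropna().isin(levels)]
            if len(bad):
                row, val = bad.index[0], bad.iloc[0]
                raise CohortError(
                    f"unparseable {col} value {val!r} at row {row} "
                    f"(allowed: {list(levels)})"
                )
            df[col] = pd.Categorical(values, categories=levels)
        if "age_decade" not in df.columns:
            df["age_decade"] = pd.Categorical(
                age_decade_of(df["age_years"]), categories=AGE_DECADES
            )
        if "rbdsq" in df.columns and "probable_rbd" not in df.columns:
            df["probable_rbd"] = df["rbdsq"] > RBDSQ_PROBABLE_CUTOFF
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]

    def task_columns(self, catalog: TaskCatalog) -> list[str]:
        return [m for m in catalog.measure_ids() if m in self.df.columns]

    def complete_cases(self, measure_ids: list[str]) -> pd.Series:
        """Boolean mask of participants with every listed measure present."""
        return self.df[measure_ids].notna().all(axis=1)


def load_cohort(path, catalog: TaskCatalog) -> CohortTable:
    """Load a cohort CSV, coercing categoricals and checking task columns.

    Unknown columns are preserved untouched.  Empty strings are missing.
    """
    df = pd.read_csv(
        path, na_values=[""], keep_default_na=True, float_precision="round_trip"
    )
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"missing mandatory columns: {missing}")
    known = set(catalog.measure_ids())
    task_cols = [c for c in df.columns if c.endswith((".primary", ".secondary"))]
    unknown_tasks = [c for c in task_cols if c not in known]
    if unknown_tasks:
        raise CohortError(
            f"task columns not resolvable against the catalog: {unknown_tasks}"
        )
    cohort = CohortTable(df)
    logger.info("loaded cohort with %d rows, %d task columns", len(df), len(task_cols))
    return cohort


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort back to CSV; empty cells mark missing values."""
    cohort.df.to_csv(path, index=False, na_rep="")


def validate_cohort(cohort: CohortTable, catalog: TaskCatalog) -> list[dict]:
    """Diagnostic issue scan; never raises.

    Flags age-decade/age mismatches, reports per-task completion counts, the
    complete-case (composite-eligible) count, and out-of-range scale scores.
    """
    issues: list[dict] = []
    df = cohort.df
    expected = age_decade_of(df["age_years"])
    mismatch = df["age_decade"].astype(str) != expected
    for row in df.index[mismatch]:
        issues.append(
            {
                "kind": "age_decade_mismatch",
                "row": int(row),
                "age_years": float(df.loc[row, "age_years"]),
                "age_decade": str(df.loc[row, "age_decade"]),
            }
        )
    task_cols = cohort.task_columns(catalog)
    completion = {c: int(df[c].notna().sum()) for c in task_cols}
    issues.append({"kind": "completion_counts", "counts": completion})
    primaries = [c for c in task_cols if c.endswith(".primary")]
    if primaries:
        complete = cohort.complete_cases(primaries)
        by_group = df.loc[complete, "group"].value_counts().to_dict()
        issues.append(
            {
                "kind": "composite_eligible",
                "n_complete": int(complete.sum()),
                "by_group": {str(k): int(v) for k, v in by_group.items()},
            }
        )
    scale_ranges = {"moca": (0, 30), "mmse": (0, 30), "rbdsq": (0, 13)}
    for col in df.columns:
        for prefix, (lo, hi) in scale_ranges.items():
            if col.startswith(prefix):
                vals = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[(vals < lo) | (vals > hi)]
                for row in bad:
                    issues.append(
                        {
                            "kind": "scale_out_of_range",
                            "column": col,
                            "row": int(row),
                            "value": float(vals.loc[row]),
                            "allowed": [lo, hi],
                        }
                    )
    return issues
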