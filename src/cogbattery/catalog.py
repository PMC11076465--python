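"""Task catalog: the candidate task set, score kinds, directions and battery layout.

The catalog is the single source of truth for which measures exist, whether a
score is an accuracy or a latency, which direction means "good", and which
tasks ended up in the recommended brief battery.  The packaged default
describes a 19-task candidate set split over two assessment sessions, with a
final 8-task battery (immediate and delayed word recognition share one
battery slot because they are two scores of the same word-list task).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

#: measure-kind values a score column can take
MEASURE_KINDS = ("accuracy", "latency")

#: exclusion reasons a task may carry in the catalog / selection report
EXCLUSION_REASONS = (
    "low_discriminability",
    "device_sensitive",
    "non_discrete_loading",
    "redundant",
)

#: the five cognitive domains the battery is built to span
FACTOR_LABELS = (
    "executive",
    "visuospatial_attention",
    "short_term_memory",
    "word_knowledge",
    "motor_rt",
)


class CatalogError(ValueError):
    """Raised when a catalog violates its structural invariants."""


@dataclass(frozen=True)
class TaskCatalog:
    """Immutable wrapper around the task table.

    Parameters
    ----------
    table:
        One row per candidate task, indexed by ``task_id``.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED_COLUMNS = (
        "task_name",
        "battery",
        "operational_complexity",
        "domain",
        "primary_kind",
        "has_secondary",
        "battery_label",
        "final_battery_member",
        "exclusion_reason",
        "duration_minutes",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise CatalogError(f"catalog missing columns: {missing}")
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise CatalogError(f"duplicate task_ids: {dupes}")
        bad_kind = set(self.table["primary_kind"]) - set(MEASURE_KINDS)
        if bad_kind:
            raise CatalogError(f"unknown measure kinds: {sorted(bad_kind)}")
        excluded = self.table[~self.table["final_battery_member"]]
        no_reason = excluded[excluded["exclusion_reason"].isna()].index.tolist()
        if no_reason:
            raise CatalogError(f"excluded tasks without a reason: {no_reason}")
        bad_reason = set(excluded["exclusion_reason"].dropna()) - set(EXCLUSION_REASONS)
        if bad_reason:
            raise CatalogError(f"unknown exclusion reasons: {sorted(bad_reason)}")

    # -- basic views -------------------------------------------------------

    @property
    def task_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_tasks(self) -> int:
        return len(self.table)

    def measure_ids(self, kinds: tuple[str, ...] = ("primary", "secondary")) -> list[str]:
        """All measure column names, in catalog order.

        Primary scores are named ``<task_id>.primary``; optional latency
        secondaries ``<task_id>.secondary``.
        """
        out: list[str] = []
        for task_id, row in self.table.iterrows():
            if "primary" in kinds:
                out.append(f"{task_id}.primary")
            if "secondary" in kinds and row["has_secondary"]:
                out.append(f"{task_id}.secondary")
        return out

    def measure_kind(self, measure_id: str) -> str:
        """'accuracy' or 'latency' for a measure column."""
        task_id, which = split_measure_id(measure_id)
        if task_id not in self.table.index:
            raise KeyError(f"unknown task_id {task_id!r}")
        if which == "primary":
            return str(self.table.loc[task_id, "primary_kind"])
        if not self.table.loc[task_id, "has_secondary"]:
            raise KeyError(f"task {task_id!r} has no secondary measure")
        return "latency"  # all secondaries are response latencies

    def direction(self, measure_id: str) -> str:
        """'higher_better' for accuracy scores, 'lower_better' for latencies."""
        return "higher_better" if self.measure_kind(measure_id) == "accuracy" else "lower_better"

    def task_of(self, measure_id: str) -> str:
        return split_measure_id(measure_id)[0]

    # -- battery views -----------------------------------------------------

    @property
    def final_battery_rows(self) -> pd.DataFrame:
        return self.table[self.table["final_battery_member"]]

    @property
    def final_battery_tasks(self) -> list[str]:
        """Distinct battery slots (immediate+delayed recognition share one)."""
        seen: list[str] = []
        for label in self.final_battery_rows["battery_label"]:
            if label not in seen:
                seen.append(label)
        return seen

    @property
    def battery_duration_minutes(self) -> float:
        return float(self.final_battery_rows["duration_minutes"].sum())

    def exclusion_reasons(self) -> dict[str, str]:
        excluded = self.table[~self.table["final_battery_member"]]
        return dict(excluded["exclusion_reason"])


def load_catalog(path) -> TaskCatalog:
    """Read a task catalog CSV (see the packaged default for the layout)."""
    df = pd.read_csv(path, dtype={"battery": int, "operational_complexity": int})
    if "task_id" not in df.columns:
        raise CatalogError("catalog CSV must have a task_id column")
    df = df.set_index("task_id")
    for col in ("has_secondary", "final_battery_member"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return TaskCatalog(df)


def default_catalog() -> TaskCatalog:
    """The packaged 19-task candidate catalog with the 8-task final battery."""
    with resources.as_file(
        resources.files("cogbattery.data").joinpath("task_catalog.csv")
    ) as p:
        return load_catalog(p)


def split_measure_id(measure_id: str) -> tuple[str, str]:
    """Split ``task.primary`` / ``task.secondary`` into (task_id, slot)."""
    task_id, _, which = measure_id.rpartition(".")
    if which not in ("primary", "secondary") or not task_id:
        raise KeyError(
            f"measure id {measure_id!r} is not of the form <task>.primary/.secondary"
        )
    return task_id, which
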