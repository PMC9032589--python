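"""Label structure: activity catalog, performance groups, and the model grid.

The activity catalog maps each named laboratory activity to one activity-type
category and one intensity category.  The catalog is data, not code: the
packaged default lives in ``data/activity_catalog.csv`` and an alternative
file with the same columns can be supplied to :func:`load_catalog`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TYPE_CATEGORIES",
    "INTENSITY_CATEGORIES",
    "GROUPS",
    "ActivityCatalogEntry",
    "SubjectProfile",
    "TaskSpec",
    "canonicalize",
    "load_catalog",
    "map_activity",
    "assign_group",
    "enumerate_model_configs",
]

TYPE_CATEGORIES = ("Sedentary", "Locomotion", "Lifestyle", "SFE")
INTENSITY_CATEGORIES = ("Low", "Light", "Moderate")
GROUPS = ("LPP", "HPP")
COHORTS = ("LPP", "HPP", "ALL")
ALGORITHMS = ("boosted_trees", "l1_linear")

SPPB_MIN, SPPB_MAX = 0, 12
#: Subjects scoring at or below this SPPB value are the low-performance group.
LPP_THRESHOLD = 9


@dataclass(frozen=True)
class ActivityCatalogEntry:
    """One catalog row: canonical activity name and its two category labels."""

    activity_name: str
    type_category: str
    intensity_category: str

    def __post_init__(self) -> None:
        if self.type_category not in TYPE_CATEGORIES:
            raise ValueError(f"unknown type category {self.type_category!r}")
        if self.intensity_category not in INTENSITY_CATEGORIES:
            raise ValueError(
                f"unknown intensity category {self.intensity_category!r}"
            )


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject covariates; ``group`` is always rederived from the score."""

    subject_id: str
    sppb_score: int
    group: str
    age_years: float
    walk_speed_mps: float | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        expected = assign_group(self.sppb_score)
        if self.group != expected:
            raise ValueError(
                f"group {self.group!r} inconsistent with SPPB "
                f"{self.sppb_score} (expected {expected})"
            )
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")


@dataclass(frozen=True, order=True)
class TaskSpec:
    """One model configuration of the experiment grid."""

    task_kind: str
    positive_class: str | None
    algorithm: str
    cohort: str

    def __post_init__(self) -> None:
        if self.task_kind not in (
            "binary_type",
            "binary_intensity",
            "multiclass_activity",
            "regression_ee",
        ):
            raise ValueError(f"unknown task kind {self.task_kind!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.task_kind == "binary_type":
            if self.positive_class not in TYPE_CATEGORIES:
                raise ValueError(
                    f"binary_type positive class must be one of "
                    f"{TYPE_CATEGORIES}, got {self.positive_class!r}"
                )
        elif self.task_kind == "binary_intensity":
            if self.positive_class not in INTENSITY_CATEGORIES:
                raise ValueError(
                    f"binary_intensity positive class must be one of "
                    f"{INTENSITY_CATEGORIES}, got {self.positive_class!r}"
                )
        else:
            if self.positive_class is not None:
                raise ValueError(
                    f"{self.task_kind} admits no positive class"
                )
            if (
                self.task_kind == "multiclass_activity"
                and self.algorithm != "boosted_trees"
            ):
                raise ValueError(
                    "multiclass_activity supports boosted_trees only"
                )

    @property
    def is_classification(self) -> bool:
        return self.task_kind != "regression_ee"

    def label(self) -> str:
        parts = [self.task_kind]
        if self.positive_class is not None:
            parts.append(self.positive_class)
        parts += [self.algorithm, self.cohort]
        return ":".join(parts)


def canonicalize(name: str) -> str:
    """Uppercase an activity name and collapse internal whitespace."""
    return re.sub(r"\s+", " ", name.strip()).upper()


def load_catalog(path: str | Path | None = None) -> list[ActivityCatalogEntry]:
    """Load the activity catalog (packaged default when *path* is None)."""
    if path is None:
        ref = resources.files("wristfunc.data") / "activity_catalog.csv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
    required = {"activity_name", "type_category", "intensity_category"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    entries = [
        ActivityCatalogEntry(
            canonicalize(row.activity_name),
            row.type_category,
            row.intensity_category,
        )
        for row in frame.itertuples()
    ]
    names = [e.activity_name for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("catalog contains duplicate activity names")
    return entries


_DEFAULT_CATALOG: dict[str, ActivityCatalogEntry] | None = None


def _catalog_index(
    catalog: Iterable[ActivityCatalogEntry] | None = None,
) -> dict[str, ActivityCatalogEntry]:
    global _DEFAULT_CATALOG
    if catalog is not None:
        return {e.activity_name: e for e in catalog}
    if _DEFAULT_CATALOG is None:
        _DEFAULT_CATALOG = {e.activity_name: e for e in load_catalog()}
    return _DEFAULT_CATALOG


def map_activity(
    activity_name: str,
    catalog: Iterable[ActivityCatalogEntry] | None = None,
) -> tuple[str, str]:
    """Return ``(type_category, intensity_category)`` for an activity name.

    Lookup is case- and whitespace-insensitive.  Raises ``KeyError`` listing
    the valid names when the activity is unknown.
    """
    index = _catalog_index(catalog)
    key = canonicalize(activity_name)
    try:
        entry = index[key]
    except KeyError:
        raise KeyError(
            f"unknown activity {activity_name!r}; valid names: "
            f"{sorted(index)}"
        ) from None
    return entry.type_category, entry.intensity_category


def assign_group(sppb_score: int) -> str:
    """Map an SPPB summary score (0-12) to 'LPP' (score <= 9) or 'HPP'."""
    if isinstance(sppb_score, bool) or not isinstance(
        sppb_score, (int, np.integer)
    ):
        raise TypeError(f"SPPB score must be an integer, got {sppb_score!r}")
    if not SPPB_MIN <= sppb_score <= SPPB_MAX:
        raise ValueError(
            f"SPPB score must be in [{SPPB_MIN}, {SPPB_MAX}], got {sppb_score}"
        )
    return "LPP" if sppb_score <= LPP_THRESHOLD else "HPP"


def enumerate_model_configs() -> list[TaskSpec]:
    """Enumerate the full experiment grid of 51 model configurations.

    24 binary activity-type models (4 classes x 2 algorithms x 3 cohorts),
    18 binary intensity models (3 x 2 x 3), 3 multiclass activity models
    (boosted trees only, one per cohort), and 6 energy-expenditure
    regressions (2 algorithms x 3 cohorts), in deterministic order.
    """
    specs: list[TaskSpec] = []
    for positive in TYPE_CATEGORIES:
        for algo in ALGORITHMS:
            for cohort in COHORTS:
                specs.append(TaskSpec("binary_type", positive, algo, cohort))
    for positive in INTENSITY_CATEGORIES:
        for algo in ALGORITHMS:
            for cohort in COHORTS:
                specs.append(
                    TaskSpec("binary_intensity", positive, algo, cohort)
                )
    for cohort in COHORTS:
        specs.append(
            TaskSpec("multiclass_activity", None, "boosted_trees", cohort)
        )
    for algo in ALGORITHMS:
        for cohort in COHORTS:
            specs.append(TaskSpec("regression_ee", None, algo, cohort))
    return specs
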