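"""Reading, validating and averaging per-recall intake tables.

Intake data arrive as one row per subject per 24-hour recall day, either
wide (one column per food group, the canonical layout) or long
(``component,value`` pairs). Replicate recall days are averaged per subject
before scoring; subjects with fewer than the required number of recalls are
dropped and reported. Optionally, per-food-item records can first be rolled
up into food groups through a user-supplied item-to-group mapping table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .index_definition import IndexDefinition

__all__ = [
    "IntakeRecord",
    "SubjectIntake",
    "MappingReport",
    "EXCLUDED",
    "read_intakes",
    "intakes_to_frame",
    "write_intakes",
    "map_food_items",
    "read_mapping",
    "average_recalls",
]

#: Sentinel component id marking food items deliberately outside the index
#: (e.g. fruit juice, pickled vegetables, tubers and starchy vegetables).
EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class IntakeRecord:
    """One subject x one recall day: intake in g/day per component."""

    subject_id: str
    recall_day: int
    intakes: dict[str, float]


@dataclass(frozen=True)
class SubjectIntake:
    """Per-subject intakes, arithmetic mean over recall days."""

    subject_id: str
    n_recalls: int
    intakes: dict[str, float]


@dataclass
class MappingReport:
    """Accounting for a food-item roll-up: grams in = mapped + excluded + unmapped."""

    total_grams: float = 0.0
    mapped_grams: float = 0.0
    excluded_grams: float = 0.0
    unmapped_grams: float = 0.0
    unmapped_items: list[str] = field(default_factory=list)


def _validate_frame(df: pd.DataFrame, component_ids: list[str], source: str) -> None:
    for col in component_ids:
        vals = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals) | (vals < 0))
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{source}: negative or non-finite intake in column {col!r}, row {bad[0] + 2}"
            )
    dup = df.duplicated(subset=["subject_id", "recall_day"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["subject_id", "recall_day"]]
        raise ValueError(
            f"{source}: duplicate (subject_id, recall_day) = ({pair['subject_id']}, {pair['recall_day']})"
        )


def read_intakes(
    path: str | Path,
    defn: IndexDefinition,
    missing_policy: str = "zero",
) -> list[IntakeRecord]:
    """Read a per-recall intake CSV (wide or long) into validated records.

    Wide layout: ``subject_id,recall_day,<one column per component>``.
    Long layout: ``subject_id,recall_day,component,value`` (summed within a
    subject-day if a component repeats). Component columns absent from a
    wide file are handled per ``missing_policy``: ``"zero"`` fills 0 g with
    a warning, ``"strict"`` raises. Unknown columns are reported in a
    warning and ignored.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "recall_day"}
    if not required <= set(df.columns):
        raise ValueError(f"{path.name}: expected columns subject_id and recall_day")

    if {"component", "value"} <= set(df.columns):  # long layout
        unknown = set(df["component"]) - set(defn.component_ids)
        if unknown:
            raise ValueError(
                f"{path.name}: unknown component(s) in long table: {', '.join(sorted(unknown))}"
            )
        df = (
            df.pivot_table(
                index=["subject_id", "recall_day"],
                columns="component",
                values="value",
                aggfunc="sum",
            )
            .reset_index()
        )
        df.columns.name = None

    present = [c for c in defn.component_ids if c in df.columns]
    missing = [c for c in defn.component_ids if c not in df.columns]
    extra = [c for c in df.columns if c not in defn.component_ids and c not in required]
    if extra:
        warnings.warn(f"{path.name}: ignoring unknown column(s): {', '.join(extra)}")
    if missing:
        if missing_policy == "strict":
            raise ValueError(f"{path.name}: missing component column(s): {', '.join(missing)}")
        warnings.warn(
            f"{path.name}: missing component column(s) filled with 0 g: {', '.join(missing)}"
        )
        for c in missing:
            df[c] = 0.0
    df[present] = df[present].fillna(0.0)
    _validate_frame(df, defn.component_ids, path.name)

    return [
        IntakeRecord(
            subject_id=str(row["subject_id"]),
            recall_day=int(row["recall_day"]),
            intakes={c: float(row[c]) for c in defn.component_ids},
        )
        for _, row in df.iterrows()
    ]


def intakes_to_frame(records: Iterable[IntakeRecord], defn: IndexDefinition) -> pd.DataFrame:
    """Wide DataFrame (canonical layout) from intake records."""
    rows = [
        {"subject_id": r.subject_id, "recall_day": r.recall_day, **r.intakes} for r in records
    ]
    cols = ["subject_id", "recall_day", *defn.component_ids]
    return pd.DataFrame(rows, columns=cols)


def write_intakes(records: Iterable[IntakeRecord], defn: IndexDefinition, path: str | Path) -> None:
    intakes_to_frame(records, defn).to_csv(path, index=False)


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a ``food_item,component_id`` mapping CSV into a dict."""
    df = pd.read_csv(path)
    if not {"food_item", "component_id"} <= set(df.columns):
        raise ValueError("mapping CSV needs columns food_item,component_id")
    return dict(zip(df["food_item"].astype(str), df["component_id"].astype(str)))


def map_food_items(
    items: pd.DataFrame,
    mapping: dict[str, str],
    defn: IndexDefinition,
    strict: bool = True,
) -> tuple[list[IntakeRecord], MappingReport]:
    """Roll per-food-item gram amounts up into food-group intake records.

    ``items`` needs columns ``subject_id, recall_day, food_item, grams``.
    Items mapped to the :data:`EXCLUDED` sentinel are dropped (their grams
    are accounted in the report); unmapped items raise in strict mode,
    otherwise they are collected in the report. Grams are summed within each
    (subject, day, component) cell and every component of the registry gets
    a column (0 g where nothing mapped).
    """
    needed = {"subject_id", "recall_day", "food_item", "grams"}
    if not needed <= set(items.columns):
        raise ValueError(f"item table needs columns {sorted(needed)}")
    bad_targets = set(mapping.values()) - set(defn.component_ids) - {EXCLUDED}
    if bad_targets:
        raise ValueError(
            f"mapping targets unknown component(s): {', '.join(sorted(bad_targets))}"
        )

    report = MappingReport(total_grams=float(items["grams"].sum()))
    target = items["food_item"].map(mapping)
    unmapped_mask = target.isna()
    if unmapped_mask.any():
        names = sorted(items.loc[unmapped_mask, "food_item"].unique())
        if strict:
            raise ValueError(f"unmapped food item(s): {', '.join(names)}")
        report.unmapped_items = names
        report.unmapped_grams = float(items.loc[unmapped_mask, "grams"].sum())
    excluded_mask = target == EXCLUDED
    report.excluded_grams = float(items.loc[excluded_mask, "grams"].sum())

    kept = items.loc[~unmapped_mask & ~excluded_mask].copy()
    kept["component"] = target[~unmapped_mask & ~excluded_mask]
    report.mapped_grams = float(kept["grams"].sum())

    grouped = (
        kept.groupby(["subject_id", "recall_day", "component"])["grams"].sum().unstack(fill_value=0.0)
        if len(kept)
        else pd.DataFrame()
    )
    records: list[IntakeRecord] = []
    pairs = items[["subject_id", "recall_day"]].drop_duplicates().itertuples(index=False)
    for subject_id, recall_day in pairs:
        if (subject_id, recall_day) in grouped.index:
            row = grouped.loc[(subject_id, recall_day)]
            intakes = {c: float(row.get(c, 0.0)) for c in defn.component_ids}
        else:
            intakes = {c: 0.0 for c in defn.component_ids}
        records.append(IntakeRecord(str(subject_id), int(recall_day), intakes))
    return records, report


def average_recalls(
    records: list[IntakeRecord],
    min_recalls: int = 2,
) -> tuple[list[SubjectIntake], list[str]]:
    """Average replicate recall days per subject (unweighted arithmetic mean).

    Subjects with fewer than ``min_recalls`` recall days are dropped; the
    second return value lists their ids. The default of 2 follows the
    duplicate-recall design of the source survey. Averaging a single recall
    returns it unchanged.
    """
    if min_recalls < 1:
        raise ValueError("min_recalls must be >= 1")
    if not records:
        warnings.warn("average_recalls: empty input")
        return [], []

    by_subject: dict[str, list[IntakeRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)

    subjects: list[SubjectIntake] = []
    dropped: list[str] = []
    for sid, recs in by_subject.items():
        if len(recs) < min_recalls:
            dropped.append(sid)
            continue
        component_ids = recs[0].intakes.keys()
        means = {
            c: float(np.mean([r.intakes[c] for r in recs])) for c in component_ids
        }
        subjects.append(SubjectIntake(subject_id=sid, n_recalls=len(recs), intakes=means))
    return subjects, dropped
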