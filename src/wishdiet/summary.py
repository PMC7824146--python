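"""Population-level descriptive summaries of intakes and scores.

Produces, per component: mean (SD) score, percentage of non-consumers
(subjects whose recall-averaged intake is exactly 0 g), mean (SD) intake,
and a direction-of-change label saying whether the population mean intake
should rise or fall to raise the score. Totals and sub-scores get mean (SD)
rows as well. SDs use the sample (n-1) convention; for a single subject the
SD is reported as 0 with a warning so tabular output stays well-formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .aggregate import ScoreResult
from .index_definition import FoodGroupSpec, HealthClass, IndexDefinition
from .intake_io import SubjectIntake

__all__ = ["PopulationSummary", "summarize", "direction_of_change", "plot_mean_scores"]

Direction = Literal["Increase", "Decrease", "Good"]

AGGREGATE_NAMES = ("total", "healthy", "less_healthy", "low_env", "high_env")


@dataclass(frozen=True)
class PopulationSummary:
    """Component table plus aggregate mean/SD rows."""

    n_subjects: int
    components: pd.DataFrame  # index: component id
    aggregates: pd.DataFrame  # index: total + 4 sub-score names

    def to_csv(self, path: str | Path) -> None:
        comp = self.components.copy()
        comp.insert(0, "kind", "component")
        agg = self.aggregates.copy()
        agg.insert(0, "kind", "aggregate")
        pd.concat([comp, agg]).rename_axis("name").to_csv(path)


def direction_of_change(spec: FoodGroupSpec, mean_intake: float) -> Direction:
    """Label whether the population mean intake should move to score higher.

    Protective and neutral groups are compared to the point recommended
    value: below it the advice is Increase, above it Decrease, exactly at it
    Good. Limit groups are Good anywhere at or below the recommended cut-off
    and Decrease above it. The comparison deliberately uses the recommended
    value rather than the full scoring band: a mean inside an optimum band
    but above the recommended point (e.g. fish) still labels Decrease,
    reflecting over-consumers within the population.
    """
    if mean_intake < 0:
        raise ValueError("mean intake must be non-negative")
    if spec.health_class is HealthClass.LIMIT:
        return "Good" if mean_intake <= spec.recommended else "Decrease"
    if mean_intake < spec.recommended:
        return "Increase"
    if mean_intake > spec.recommended:
        return "Decrease"
    return "Good"


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    if values.size == 1:
        return mean, 0.0
    return mean, float(np.std(values, ddof=1))


def summarize(
    defn: IndexDefinition,
    subjects: Iterable[SubjectIntake],
    results: Iterable[ScoreResult],
) -> PopulationSummary:
    """Build the population summary from aligned intakes and score results.

    ``subjects`` and ``results`` must cover the same subject ids. A
    non-consumer of a component is a subject whose recall-averaged intake of
    it is exactly 0 g/day.
    """
    subjects = list(subjects)
    results = list(results)
    if not subjects:
        raise ValueError("empty population")
    by_id = {r.subject_id: r for r in results}
    if set(by_id) != {s.subject_id for s in subjects}:
        raise ValueError("subjects and results are not aligned on subject_id")
    if len(subjects) == 1:
        warnings.warn("single-subject population: SDs reported as 0")

    rows = []
    for spec in defn.components:
        intakes = np.array([s.intakes[spec.id] for s in subjects], dtype=float)
        scores = np.array([by_id[s.subject_id].component_scores[spec.id] for s in subjects])
        mean_intake, sd_intake = _mean_sd(intakes)
        mean_score, sd_score = _mean_sd(scores)
        rows.append(
            {
                "component": spec.id,
                "mean_score": mean_score,
                "sd_score": sd_score,
                "pct_nonconsumers": 100.0 * float(np.mean(intakes == 0.0)),
                "mean_intake": mean_intake,
                "sd_intake": sd_intake,
                "direction": direction_of_change(spec, mean_intake),
            }
        )
    components = pd.DataFrame(rows).set_index("component")

    agg_rows = []
    for name in AGGREGATE_NAMES:
        values = np.array([getattr(by_id[s.subject_id], name) for s in subjects])
        mean, sd = _mean_sd(values)
        agg_rows.append({"name": name, "mean_score": mean, "sd_score": sd})
    aggregates = pd.DataFrame(agg_rows).set_index("name")

    return PopulationSummary(
        n_subjects=len(subjects), components=components, aggregates=aggregates
    )


def plot_mean_scores(summary: PopulationSummary, path: str | Path) -> None:
    """Bar chart of mean component scores (values only; no styling claims)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4), width_ratios=[3, 1])
    comp = summary.components
    ax1.bar(comp.index, comp["mean_score"], yerr=comp["sd_score"], capsize=2)
    ax1.set_ylabel("mean component score (0-10)")
    ax1.set_ylim(0, 10.5)
    ax1.tick_params(axis="x", rotation=75)
    agg = summary.aggregates
    ax2.bar(agg.index, agg["mean_score"], yerr=agg["sd_score"], capsize=2)
    ax2.set_ylabel("mean aggregate score")
    ax2.tick_params(axis="x", rotation=75)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
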