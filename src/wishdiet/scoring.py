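"""Component scoring: the 0-10 piecewise-linear adherence score.

Each food group maps reported intake (g/day) to a score between 0 (no
adherence) and 10 (full adherence) through one of five shapes. The rising
ramp between the lower and the recommended intake is

    10 * (intake - lower) / (recommended - lower)

and the falling ramp between the recommended and the upper intake is

    10 * ((upper - recommended) - (intake - recommended)) / (upper - recommended).

Boundary conventions follow the index's "or less" / "or higher" phrasing:
plateau boundaries are inclusive (dairy at exactly 500 g scores 10,
saturated oils at exactly 11.8 g scores 10), while "above"/"below" bounds
are strict (dairy at 500.01 scores 0, whole grains at 99.99 scores 0). At
the foot of a rising ramp the score is exactly 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

from .aggregate import ScoreResult, aggregate_scores
from .index_definition import FoodGroupSpec, IndexDefinition, ScoringShape

__all__ = ["ComponentScore", "score_component", "score_all", "MissingPolicy"]

MissingPolicy = Literal["zero", "strict"]


@dataclass(frozen=True)
class ComponentScore:
    component_id: str
    intake: float
    score: float


def _ramp_up(spec: FoodGroupSpec, intake: float) -> float:
    # rising ramp from lower to recommended; callers handle the plateau
    return 10.0 * (intake - spec.lower) / (spec.recommended - spec.lower)


def _ramp_down(spec: FoodGroupSpec, intake: float) -> float:
    width = spec.upper - spec.recommended
    return 10.0 * (width - (intake - spec.recommended)) / width


def score_component(spec: FoodGroupSpec, intake: float) -> ComponentScore:
    """Score one component at the given intake (g/day).

    Raises
    ------
    ValueError
        If the intake is negative or non-finite. Out-of-range intakes are
        never clamped: a negative value signals a data-cleaning problem
        upstream and must not silently score 0.
    """
    if not math.isfinite(intake) or intake < 0:
        raise ValueError(f"{spec.id}: intake must be a finite non-negative number, got {intake!r}")

    shape = spec.shape
    if shape is ScoringShape.RAMP_UP_OPEN or shape is ScoringShape.RAMP_UP_CAPPED:
        if shape is ScoringShape.RAMP_UP_CAPPED and intake > spec.upper:
            score = 0.0
        elif intake >= spec.recommended:
            score = 10.0
        elif intake < spec.lower:
            score = 0.0
        else:
            score = _ramp_up(spec, intake)
    elif shape is ScoringShape.OPTIMUM_BAND:
        if intake > spec.upper:
            score = 0.0
        elif intake >= spec.recommended:
            score = 10.0
        else:
            # "scored as a ratio between 0 and 10": linear through the origin
            score = 10.0 * intake / spec.recommended
    elif shape is ScoringShape.RAMP_DOWN:
        if intake <= spec.recommended:
            score = 10.0
        elif intake > spec.upper:
            score = 0.0
        else:
            score = _ramp_down(spec, intake)
    elif shape is ScoringShape.BIVARIATE_LIMIT:
        score = 10.0 if intake <= spec.recommended else 0.0
    else:  # pragma: no cover - enum is closed
        raise AssertionError(f"unhandled shape {shape}")

    # guard against float drift at ramp endpoints
    score = min(10.0, max(0.0, score))
    return ComponentScore(spec.id, intake, score)


def score_all(
    defn: IndexDefinition,
    intakes: Mapping[str, float],
    subject_id: str = "",
    missing_policy: MissingPolicy = "zero",
) -> ScoreResult:
    """Score every component of the index for one subject and aggregate.

    ``intakes`` maps component ids to recall-averaged g/day. A component
    absent from the mapping is treated per ``missing_policy``: ``"zero"``
    (default) scores it as 0 g consumed and emits a warning — legitimate for
    true non-consumers but usually a column-mapping error — while
    ``"strict"`` raises.
    """
    unknown = set(intakes) - set(defn.component_ids)
    if unknown:
        raise ValueError(f"unknown component id(s) in intakes: {', '.join(sorted(unknown))}")

    component_scores: dict[str, float] = {}
    missing: list[str] = []
    for spec in defn.components:
        if spec.id in intakes:
            amount = float(intakes[spec.id])
        else:
            if missing_policy == "strict":
                raise ValueError(f"missing intake for component {spec.id!r}")
            missing.append(spec.id)
            amount = 0.0
        component_scores[spec.id] = score_component(spec, amount).score

    if missing:
        warnings.warn(
            f"subject {subject_id or '<unnamed>'}: missing intake for "
            f"{', '.join(missing)}; scored as 0 g consumed",
            stacklevel=2,
        )
    result = aggregate_scores(defn, component_scores, subject_id=subject_id)
    return result
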