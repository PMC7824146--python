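"""Total score and sub-score aggregation.

All components enter the total with equal weight, so the total is simply the
sum of the 13 component scores (maximum 130 with the default registry). The
total alone dilutes opposing dietary patterns, so four sub-scores are
reported alongside it: healthy (protective + neutral groups, max 100),
less-healthy (limit groups, max 30), low environmental impact (max 60) and
high environmental impact (max 70). Each pair partitions the component set,
so healthy + less-healthy = low-env + high-env = total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .index_definition import IndexDefinition

__all__ = ["ScoreResult", "aggregate_scores"]


@dataclass(frozen=True)
class ScoreResult:
    """Per-subject component scores, total, and the four sub-scores."""

    subject_id: str
    component_scores: dict[str, float] = field(repr=False)
    total: float = 0.0
    healthy: float = 0.0
    less_healthy: float = 0.0
    low_env: float = 0.0
    high_env: float = 0.0

    def as_row(self) -> dict[str, float | str]:
        """Flatten to a tabular row (component columns then aggregates)."""
        row: dict[str, float | str] = {"subject_id": self.subject_id}
        row.update(self.component_scores)
        row.update(
            total=self.total,
            healthy=self.healthy,
            less_healthy=self.less_healthy,
            low_env=self.low_env,
            high_env=self.high_env,
        )
        return row


def aggregate_scores(
    defn: IndexDefinition,
    component_scores: dict[str, float],
    subject_id: str = "",
) -> ScoreResult:
    """Sum component scores into the total and the four sub-scores.

    Sub-score maxima are derived from membership sizes (10 points per
    member), so a locally adapted registry aggregates correctly without any
    hard-coded constants.

    Raises
    ------
    ValueError
        If the score map does not cover exactly the registry's components,
        or any score falls outside [0, 10].
    """
    expected = set(defn.component_ids)
    got = set(component_scores)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        parts = []
        if missing:
            parts.append(f"missing: {', '.join(missing)}")
        if extra:
            parts.append(f"unexpected: {', '.join(extra)}")
        raise ValueError("component scores do not match index definition — " + "; ".join(parts))
    for cid, s in component_scores.items():
        if not (0.0 <= s <= 10.0):
            raise ValueError(f"{cid}: score {s} outside [0, 10]")

    def subsum(name: str) -> float:
        return sum(component_scores[cid] for cid in defn.subscores[name])

    total = sum(component_scores.values())
    return ScoreResult(
        subject_id=subject_id,
        component_scores={cid: component_scores[cid] for cid in defn.component_ids},
        total=total,
        healthy=subsum("healthy"),
        less_healthy=subsum("less_healthy"),
        low_env=subsum("low_env"),
        high_env=subsum("high_env"),
    )
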