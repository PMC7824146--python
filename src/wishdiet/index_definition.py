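"""Declarative registry of the WISH index components.

The WISH (World Index for Sustainability and Health) scores a diet on 13
EAT-Lancet food groups. Each component carries a health classification
(protective / neutral / limit), an environmental-impact classification
(low / medium / high), intake thresholds in grams per day, and one of five
piecewise-linear scoring shapes. The default registry ships the published
thresholds; a YAML file with the same schema can override them for local
adaptations of the index.
"""

from __future__ import annotations

import enum
import math
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "ScoringShape",
    "HealthClass",
    "EnvClass",
    "FoodGroupSpec",
    "IndexDefinition",
    "COMPONENT_IDS",
    "load_index",
    "validate_index",
    "IndexValidationError",
]

#: Canonical component ids, in registry order (wide-CSV column order).
COMPONENT_IDS = (
    "whole_grains",
    "vegetables",
    "fruits",
    "dairy",
    "red_meat",
    "fish",
    "eggs",
    "poultry",
    "legumes",
    "nuts",
    "unsat_oils",
    "sat_oils",
    "added_sugars",
)


class ScoringShape(str, enum.Enum):
    """The five piecewise-linear adherence shapes.

    RAMP_UP_OPEN
        0 below ``lower``, linear from ``lower`` to ``recommended``, 10 at or
        above ``recommended`` with no upper restriction (whole grains,
        vegetables, fruits, legumes).
    RAMP_UP_CAPPED
        As RAMP_UP_OPEN, but intakes strictly above ``upper`` score 0
        (unsaturated oils — excess fat adds energy).
    OPTIMUM_BAND
        Linear from 0 g to ``recommended`` scoring 0 to 10, a plateau of 10
        from ``recommended`` to ``upper``, and 0 strictly above ``upper``
        (dairy, fish, nuts — capped for environmental impact).
    RAMP_DOWN
        10 at or below ``recommended``, linear down to 0 at ``upper``, 0
        strictly above ``upper`` (red meat, eggs, poultry).
    BIVARIATE_LIMIT
        All-or-nothing: 10 at or below ``recommended``, 0 strictly above
        (saturated oils, added sugars — no upper range is defined).
    """

    RAMP_UP_OPEN = "RAMP_UP_OPEN"
    RAMP_UP_CAPPED = "RAMP_UP_CAPPED"
    OPTIMUM_BAND = "OPTIMUM_BAND"
    RAMP_DOWN = "RAMP_DOWN"
    BIVARIATE_LIMIT = "BIVARIATE_LIMIT"


class HealthClass(str, enum.Enum):
    PROTECTIVE = "protective"
    NEUTRAL = "neutral"
    LIMIT = "limit"


class EnvClass(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


#: Shapes whose scoring rule reads the ``upper`` threshold. RAMP_UP_OPEN
#: components may carry an upper value from the published ranges, but the
#: rule never uses it.
SHAPES_USING_UPPER = frozenset(
    {ScoringShape.RAMP_UP_CAPPED, ScoringShape.OPTIMUM_BAND, ScoringShape.RAMP_DOWN}
)


class IndexValidationError(ValueError):
    """Raised when a config fails structural validation; carries all violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid index definition:\n  " + "\n  ".join(violations))


class FoodGroupSpec(BaseModel):
    """One food group: identity, classifications, thresholds (g/day), shape."""

    id: str
    health_class: HealthClass
    env_class: EnvClass
    lower: float = Field(ge=0)
    recommended: float = Field(ge=0)
    upper: Optional[float] = Field(default=None, ge=0)
    shape: ScoringShape

    model_config = {"frozen": True}

    @field_validator("lower", "recommended", "upper")
    @classmethod
    def _finite(cls, v):
        if v is not None and not math.isfinite(v):
            raise ValueError("thresholds must be finite")
        return v

    @model_validator(mode="after")
    def _ordered(self):
        if self.lower > self.recommended:
            raise ValueError(
                f"{self.id}: lower ({self.lower}) exceeds recommended ({self.recommended})"
            )
        if self.upper is not None and self.recommended > self.upper:
            raise ValueError(
                f"{self.id}: recommended ({self.recommended}) exceeds upper ({self.upper})"
            )
        if self.shape in SHAPES_USING_UPPER and self.upper is None:
            raise ValueError(f"{self.id}: shape {self.shape.value} requires an upper threshold")
        return self


class IndexDefinition(BaseModel):
    """The ordered component registry plus sub-score membership lists.

    Two membership pairs each partition the component set: healthy /
    less-healthy (diet-quality axis) and low / high environmental impact
    (sustainability axis).
    """

    components: list[FoodGroupSpec]
    subscores: dict[str, list[str]]

    model_config = {"frozen": True}

    @property
    def component_ids(self) -> list[str]:
        return [c.id for c in self.components]

    def spec(self, component_id: str) -> FoodGroupSpec:
        for c in self.components:
            if c.id == component_id:
                return c
        raise KeyError(f"unknown component: {component_id!r}")

    def max_total(self) -> float:
        return 10.0 * len(self.components)

    def max_subscore(self, name: str) -> float:
        return 10.0 * len(self.subscores[name])

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "components": [
                {
                    "id": c.id,
                    "health_class": c.health_class.value,
                    "env_class": c.env_class.value,
                    "lower": c.lower,
                    "recommended": c.recommended,
                    "upper": c.upper,
                    "shape": c.shape.value,
                }
                for c in self.components
            ],
            "subscores": {k: list(v) for k, v in self.subscores.items()},
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


SUBSCORE_NAMES = ("healthy", "less_healthy", "low_env", "high_env")

# The two partitions of the 13-component set.
_PARTITION_PAIRS = (("healthy", "less_healthy"), ("low_env", "high_env"))


def validate_index(defn: IndexDefinition, expected_n: int | None = 13) -> list[str]:
    """Check registry invariants; return a list of human-readable violations.

    An empty list means the definition is structurally valid. Checks: the
    component count (13 for the canonical WISH; pass ``expected_n=None`` to
    allow locally adapted registries of another size), unique ids, threshold
    ordering, and that each sub-score pair exactly partitions the component
    set.
    """
    violations: list[str] = []
    ids = [c.id for c in defn.components]
    if expected_n is not None and len(ids) != expected_n:
        missing = set(COMPONENT_IDS) - set(ids)
        if missing:
            violations.append(f"missing component(s): {', '.join(sorted(missing))}")
        else:
            violations.append(f"expected {expected_n} components, found {len(ids)}")
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        violations.append(f"duplicate component id(s): {', '.join(sorted(dupes))}")

    for c in defn.components:
        if c.lower > c.recommended:
            violations.append(f"{c.id}: lower > recommended")
        if c.upper is not None and c.recommended > c.upper:
            violations.append(f"{c.id}: recommended > upper")
        if c.shape in SHAPES_USING_UPPER and c.upper is None:
            violations.append(f"{c.id}: shape {c.shape.value} requires upper")

    for name in SUBSCORE_NAMES:
        if name not in defn.subscores:
            violations.append(f"missing sub-score membership list: {name}")
        else:
            unknown = set(defn.subscores[name]) - set(ids)
            if unknown:
                violations.append(
                    f"sub-score {name} references unknown component(s): {', '.join(sorted(unknown))}"
                )
    for a, b in _PARTITION_PAIRS:
        if a in defn.subscores and b in defn.subscores:
            sa, sb = set(defn.subscores[a]), set(defn.subscores[b])
            overlap = sa & sb
            if overlap:
                violations.append(
                    f"sub-scores {a}/{b} overlap on: {', '.join(sorted(overlap))}"
                )
            if sa | sb != set(ids):
                violations.append(f"sub-scores {a}+{b} do not cover all components")
    return violations


def _default_yaml_text() -> str:
    return resources.files("wishdiet.data").joinpath("wish_default.yaml").read_text()


def load_index(config_source: str | Path | None = None) -> IndexDefinition:
    """Load and validate an index definition.

    With no argument, returns the published WISH registry (13 components,
    EAT-Lancet thresholds). With a path, parses that YAML file against the
    same schema and validates it fully.

    Raises
    ------
    IndexValidationError
        If the config is malformed or violates a registry invariant; the
        exception lists every offending field.
    """
    if config_source is None:
        text = _default_yaml_text()
    else:
        text = Path(config_source).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise IndexValidationError([f"YAML parse error: {exc}"]) from exc
    if not isinstance(doc, dict) or "components" not in doc:
        raise IndexValidationError(["config must be a mapping with a 'components' key"])

    try:
        defn = IndexDefinition(
            components=doc.get("components", []),
            subscores=doc.get("subscores", {}),
        )
    except Exception as exc:  # pydantic collects per-field errors
        raise IndexValidationError([str(exc)]) from exc

    violations = validate_index(defn)
    if violations:
        raise IndexValidationError(violations)
    return defn
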