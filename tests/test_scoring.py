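"""Component scoring: worked breakpoints, oracle equivalence, shape properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import FULL_SCORE_DIET
from oracle import PARAGRAPH_RULES
from wishdiet import ScoringShape, score_all, score_component
from wishdiet.index_definition import COMPONENT_IDS


@pytest.mark.parametrize(
    "cid, intake, expected",
    [
        # published worked values and breakpoints
        ("whole_grains", 125, 10), ("whole_grains", 99, 0), ("whole_grains", 100, 0),
        ("whole_grains", 112.5, 5), ("whole_grains", 1000, 10),
        ("vegetables", 300, 10), ("vegetables", 199.99, 0), ("vegetables", 250, 5),
        ("fruits", 200, 10), ("fruits", 150, 5), ("fruits", 99, 0),
        ("dairy", 250, 10), ("dairy", 500, 10), ("dairy", 600, 0), ("dairy", 500.01, 0),
        ("dairy", 125, 5), ("dairy", 0, 0),
        ("red_meat", 10, 10), ("red_meat", 14, 10), ("red_meat", 21, 5),
        ("red_meat", 28, 0), ("red_meat", 29, 0),
        ("fish", 28, 10), ("fish", 100, 10), ("fish", 100.01, 0), ("fish", 14, 5),
        ("eggs", 13, 10), ("eggs", 19, 5), ("eggs", 25, 0), ("eggs", 26, 0),
        ("poultry", 29, 10), ("poultry", 43.5, 5), ("poultry", 58, 0),
        ("legumes", 75, 10), ("legumes", 37.5, 5), ("legumes", 0, 0), ("legumes", 200, 10),
        ("nuts", 50, 10), ("nuts", 75, 10), ("nuts", 76, 0), ("nuts", 25, 5),
        ("unsat_oils", 40, 10), ("unsat_oils", 60, 10), ("unsat_oils", 80, 10),
        ("unsat_oils", 81, 0), ("unsat_oils", 30, 5), ("unsat_oils", 19.99, 0),
        ("sat_oils", 11.8, 10), ("sat_oils", 11.81, 0), ("sat_oils", 0, 10),
        ("added_sugars", 0, 10), ("added_sugars", 31, 10), ("added_sugars", 32, 0),
    ],
)
def test_breakpoints_and_worked_examples(index, cid, intake, expected):
    assert score_component(index.spec(cid), intake).score == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("cid", COMPONENT_IDS)
def test_engine_matches_paragraph_oracle_on_dense_grid(index, cid):
    """1,000 grid points per component plus all breakpoints +- 1e-9 must agree
    with a literal transcription of the published scoring paragraph to 1e-12."""
    spec = index.spec(cid)
    rule = PARAGRAPH_RULES[cid]
    hi = 2.0 * (spec.upper or spec.recommended) + 50.0
    points = list(np.linspace(0.0, hi, 1000))
    for b in (spec.lower, spec.recommended, spec.upper or spec.recommended):
        points += [b, max(0.0, b - 1e-9), b + 1e-9]
    for x in points:
        assert abs(score_component(spec, x).score - rule(x)) < 1e-12, (cid, x)


@pytest.mark.parametrize("cid", COMPONENT_IDS)
def test_continuity_except_documented_jumps(index, cid):
    """Each shape is continuous except at its documented jump point(s)."""
    spec = index.spec(cid)
    jumps = set()
    if spec.shape in (ScoringShape.RAMP_UP_CAPPED, ScoringShape.OPTIMUM_BAND):
        jumps.add(spec.upper)
    if spec.shape is ScoringShape.BIVARIATE_LIMIT:
        jumps.add(spec.recommended)
    hi = 2.0 * (spec.upper or spec.recommended) + 50.0
    eps = 1e-9
    for x in np.linspace(eps, hi, 500):
        left = score_component(spec, x - eps).score
        right = score_component(spec, x + eps).score
        near_jump = any(abs(x - j) < 1e-6 for j in jumps)
        if not near_jump:
            assert abs(left - right) < 1e-5, (cid, x)
    for j in jumps:
        assert score_component(spec, j).score - score_component(spec, j + eps).score > 5


def test_falling_ramp_endpoints_are_exact(index):
    """The falling-ramp formula gives exactly 10 at the recommended intake and
    exactly 0 at the upper intake (algebraic identity)."""
    for cid in ("red_meat", "eggs", "poultry"):
        spec = index.spec(cid)
        width = spec.upper - spec.recommended
        at_rec = 10.0 * (width - 0.0) / width
        at_upper = 10.0 * (width - (spec.upper - spec.recommended)) / width
        assert at_rec == 10.0 and at_upper == 0.0
        assert score_component(spec, spec.recommended).score == 10.0
        assert score_component(spec, spec.upper).score == 0.0


@settings(max_examples=200, derandomize=True)
@given(
    cid=st.sampled_from(COMPONENT_IDS),
    intake=st.floats(min_value=0, max_value=2000, allow_nan=False),
)
def test_score_always_in_range(index, cid, intake):
    assert 0.0 <= score_component(index.spec(cid), intake).score <= 10.0


@settings(max_examples=200, derandomize=True)
@given(
    cid=st.sampled_from(COMPONENT_IDS),
    a=st.floats(min_value=0, max_value=1500, allow_nan=False),
    b=st.floats(min_value=0, max_value=1500, allow_nan=False),
)
def test_shape_monotonicity(index, cid, a, b):
    """Open rising ramps never decrease with intake; falling ramps and
    bivariate cut-offs never increase; optimum bands never decrease below
    their upper bound."""
    spec = index.spec(cid)
    lo, hi = min(a, b), max(a, b)
    s_lo = score_component(spec, lo).score
    s_hi = score_component(spec, hi).score
    if spec.shape is ScoringShape.RAMP_UP_OPEN:
        assert s_hi >= s_lo - 1e-12
    elif spec.shape in (ScoringShape.RAMP_DOWN, ScoringShape.BIVARIATE_LIMIT):
        assert s_hi <= s_lo + 1e-12
    elif spec.shape is ScoringShape.OPTIMUM_BAND and hi <= spec.upper:
        assert s_hi >= s_lo - 1e-12


@pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
def test_invalid_intake_raises(index, bad):
    with pytest.raises(ValueError, match="vegetables"):
        score_component(index.spec("vegetables"), bad)


def test_full_adherence_diet_scores_maximum(index):
    result = score_all(index, FULL_SCORE_DIET, "ideal")
    assert result.total == 130.0
    assert all(s == 10.0 for s in result.component_scores.values())


def test_all_zero_diet(index):
    """At zero intake the limit and neutral groups score 10 (nothing consumed
    is full adherence for them), everything else scores 0."""
    result = score_all(index, {c: 0.0 for c in COMPONENT_IDS}, "fasting")
    tens = {"eggs", "poultry", "red_meat", "sat_oils", "added_sugars"}
    for cid, s in result.component_scores.items():
        assert s == (10.0 if cid in tens else 0.0)
    assert result.total == 50.0


def test_missing_component_policies(index):
    partial = {c: 0.0 for c in COMPONENT_IDS if c != "fish"}
    with pytest.warns(UserWarning, match="fish"):
        result = score_all(index, partial, "A", missing_policy="zero")
    assert result.component_scores["fish"] == 0.0
    with pytest.raises(ValueError, match="fish"):
        score_all(index, partial, "A", missing_policy="strict")
    with pytest.raises(ValueError, match="unknown component"):
        score_all(index, {**FULL_SCORE_DIET, "tubers": 100.0}, "A")
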