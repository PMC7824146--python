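# Methods

## The index

The WISH (World Index for Sustainability and Health) rates a diet's joint
adherence to healthiness and environmental-sustainability recommendations
derived from the EAT-Lancet reference diet. Thirteen food groups are each
scored 0–10 from the reported intake in grams per day; the total is the
unweighted sum (maximum 130). Because a total dilutes opposing patterns —
much of the desirable groups plus much of the undesirable ones can score the
same as moderation in everything — four sub-scores are reported alongside
it, formed by summing disjoint membership lists that partition the
components two ways:

| axis | sub-score | members | maximum |
|---|---|---|---|
| diet quality | healthy | 8 protective + 2 neutral groups | 100 |
| diet quality | less healthy | red meat, saturated oils, added sugars | 30 |
| sustainability | low environmental impact | whole grains, vegetables, fruits, legumes, unsaturated oils, added sugars | 60 |
| sustainability | high environmental impact | saturated oils, dairy, red meat, fish, eggs, poultry, nuts | 70 |

Maxima are derived (10 × membership size), never hard-coded, so a locally
adapted registry aggregates correctly. Because each pair partitions the
component set, `healthy + less_healthy = low_env + high_env = total` holds
identically; the test suite asserts it on 10,000 random score vectors.

## Scoring shapes

Each component maps intake to a score through one of five piecewise-linear
shapes. The rising ramp between the lower bound `l` and the recommended
intake `r` is `10·(x−l)/(r−l)`; the falling ramp between `r` and the upper
bound `u` is `10·((u−r)−(x−r))/(u−r)`, which is exactly 10 at `r` and
exactly 0 at `u`.

- **Open rising ramp** (whole grains, vegetables, fruits, legumes): 0 below
  `l`, ramp to 10 at `r`, 10 for any higher intake. Upper range values from
  the published table are stored but unused — no upper restriction is
  modelled for these groups.
- **Capped rising ramp** (unsaturated oils): as above but intakes strictly
  above `u` = 80 g score 0, because excess fat raises energy intake.
- **Optimum band** (dairy, fish, nuts): linear through the origin up to `r`
  (`10·x/r`), a plateau of 10 on [`r`, `u`], and 0 strictly above `u` —
  the cap reflects these groups' medium/high environmental impact. The
  "ratio between 0 and 10" wording of the source is interpreted as linear
  through the origin.
- **Falling ramp** (red meat, eggs, poultry): 10 at or below `r`, falling
  ramp to 0 at `u`, 0 above.
- **Bivariate cut-off** (saturated oils 11.8 g, added sugars 31 g): 10 at or
  below the cut-off, 0 strictly above — no upper range exists for these
  groups, so the score is all-or-nothing.

Boundary conventions honour the "or less"/"or higher" phrasing of each
rule: plateau edges are inclusive (dairy at exactly 500 g scores 10;
saturated oils at exactly 11.8 g scores 10) while "above"/"below" bounds
are strict (dairy 500.01 → 0; whole grains 99.99 → 0). At the foot of a
rising ramp the score is exactly 0 (whole grains 100 → 0). The
discontinuities at an optimum band's upper edge and at a bivariate cut-off
are intentional; no smoothing is offered. For unsaturated oils between 40
and 80 g/day the generic plateau rule applies (score 10); the per-group
prose only states the 20–40 ramp and the >80 cut explicitly, and we note
that gap here.

Negative or non-finite intakes raise rather than clamp, to surface
data-cleaning problems. A component missing from a subject's record is, by
default, scored as 0 g consumed with a warning (true non-consumers are
legitimate; absent *columns* usually mean mapping errors), or rejected
under the `strict` policy. Scores carry full float precision internally;
rounding to one decimal is left to reporting.

## Input handling

Per-recall tables are accepted wide (one column per group — canonical) or
long (`component,value`); replicate recall days are combined by unweighted
arithmetic mean, and subjects with fewer than `min_recalls` (default 2,
matching the duplicate-recall design of the motivating survey) are dropped
and reported. Optionally, per-food-item gram amounts are rolled up through
a user-supplied `food_item → component_id` mapping with an `EXCLUDED`
sentinel for items outside the index (fruit juice, pickled vegetables,
tubers). No default mapping is shipped — item lists are context-specific —
but `data/mapping_template.csv` shows the expected schema with example
Vietnamese items. Mass is conserved and accounted: grams in = mapped +
excluded + unmapped. Energy-based outlier cleaning is out of scope because
it needs a food composition table, which the index is designed not to
require.

## Population summaries

Per component: mean (SD) score, mean (SD) intake, percentage of
non-consumers, and a direction-of-change label. A non-consumer is a subject
whose *recall-averaged* intake is exactly 0 g. SDs use the sample (n−1)
convention; a single-subject population reports SD 0 with a warning so the
table stays well-formed.

The direction label compares the population mean intake to the point
recommended value: protective/neutral groups label Increase below it,
Decrease above it, Good at it; limit groups label Good at or below the
cut-off, Decrease above. Comparing to the point value rather than the
scoring band is a deliberate convention — it is the only rule that
reproduces all 13 published labels, including fish, whose population mean
(35.6 g) sits inside the 10-point band yet labels Decrease because
individual over-consumers pull the mean past the recommended 28 g.

## Correlation analysis

Spearman rank correlations (average-rank ties) are computed across the 13
component scores, the four sub-scores and the total, with two-sided
p-values from the t-distribution approximation; exact permutation p-values
are available for very small n. Components constant across the population —
common, since piecewise-linear scores pile up at exactly 0 or 10 — are
excluded with reason "constant score" rather than yielding undefined
coefficients; zero variance is detected by exact equality by default, with
a tolerance flag for noisy inputs. Components stay inside the total they
are correlated against (the part–whole composition is the published
analysis); a leave-one-out variant is available behind a flag for
methodological use. No multiple-testing correction is applied by default;
Benjamini–Hochberg is available behind a flag.

## Synthetic populations

Real 24-hour-recall data for this index are access-restricted, so the
generator emulates their structure: for each component a subject is a
consumer with probability `p_consume` (drawn once per subject, matching the
subject-level non-consumer definition); consumers' day-level intakes are
lognormal — the standard choice for right-skewed dietary data — correlated
across recall days through an equicorrelated Gaussian copula on the log
scale (default day correlation 0.3, a plausible but arbitrary stability
value, exposed in config).

Consumer-level parameters come from moment matching: with consumer
probability `p`, consumer mean `m` and variance `v`, the zero-inflated
mixture has overall mean `p·m` and overall variance `p·v + p(1−p)m²`;
solving for `(m, v)` from the target overall mean/SD and inverting the
lognormal moment relations gives the log-location and log-scale. Targets
the mixture cannot reach (SD below the zero-inflation floor) degrade to a
point mass with a warning. The default calibration is the published survey
margins for 396 urban Vietnamese adults — per-component non-consumer
percentages and overall mean (SD) intakes — with 396 subjects × 2 recalls
as the default design.

What the generator does **not** model, and what passing tests therefore do
not show about real data: components are simulated independently (the real
between-component correlation structure is unknown), true intake
distributions need not be lognormal, and calibration matches *day-level*
moments — the SD of two-day-averaged intakes is accordingly shrunk relative
to the day-level target (means and non-consumer fractions are unaffected,
and those are what the recovery tests check). The published margins are
also read as all-participant statistics (zeros included), per their column
heading; a consumer-only reading would change the calibration.

## Problem sizes and numerical choices

The suite exercises the scoring oracle on 1,000-point grids per component
plus breakpoints perturbed by ±1e-9, requiring agreement with an
independent transcription of each scoring rule to 1e-12; conservation on
10,000 random vectors to 1e-9; generator recovery at n = 5,000 (within 3
Monte-Carlo standard errors); and survey-scale (n = 396) scoring echoes
over several seeds. A single integer seed drives all randomness through
numpy's `default_rng`; fixed seed means bit-identical output, recorded in
each run manifest.

## Known limitations

- The index is WISH-specific; no other diet-quality registries ship,
  though the YAML schema supports local adaptations (thresholds, shapes,
  memberships) with full validation.
- Upper range values stored for open-ramp groups (e.g. vegetables 600 g)
  are intentionally unused by the scoring rule.
- The sub-ramp/plateau behaviour encodes the published rules exactly,
  including their discontinuities; score differences of 10 points can
  follow from 0.01 g of intake at a cut-off. That is a property of the
  index, not of this implementation.
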