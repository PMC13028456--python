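# Methods

## The pricing procedure

A drug's daily price is produced in four steps.

1. **Score base elements.** Each of efficacy, safety, scientific novelty and
   clinical positioning takes exactly one criterion level; points are a pure
   function of (element, level). The base total is a multiple of 5 in
   [25, 50] — this is exhaustively checkable over the 3×2×2×2 = 24 level
   combinations, and the test suite does so.
2. **Look up the base price.** The maximum projected patient count selects
   one of 15 ordered categories; the conversion table cell at (base points,
   category) is the base daily price in JPY. No interpolation is defined for
   points that are not multiples of 5; lookups outside {5, …, 50} are
   errors.
3. **Score additional elements.** Eight elements contribute 0–50 premium
   points. An element omitted from the assessment document scores its
   zero level.
4. **Apply the premium.** `final = base × (1 + r·A)` with `r = 0.02` per
   point. The form is linear, not compounding: 5 points give exactly +10%,
   and the 50-point maximum exactly doubles the base price. (A compounding
   form would give 1.02⁵ ≈ 1.104 at 5 points, which contradicts the
   framework's own worked example, so it is rejected.)

### Conversion-table mechanics

The table carries no information beyond its 35-point **anchor row**:
`cell(p, c) = anchor(c) × (1 + 0.10 × (p − 35)/5)`. Consequences used by the
verifier: prices are strictly increasing in points within a category, and
adjacent rows differ by exactly `anchor(c)/10`. Both bundled reference grids
(FY2012–FY2021 and FY2015–FY2024) regenerate bit-exactly from their anchor
rows; the bundled CSVs are transcriptions of the published grids, not
regenerated output, so this check is meaningful.

Anchor values obey the fraction-adjustment rule: a median daily price is
floored to an integer, then a 3-digit value drops its last digit and a
value of 4+ digits drops its last two. Values of ≤2 digits pass unchanged —
the rule as stated covers only 3 and 4+ digits, and the smallest published
anchor (80 JPY) is consistent with that reading. Truncation is idempotent
and never increases its input.

### Numerical choices

* All price arithmetic is exact (`int`/`fractions.Fraction`); binary
  floating point is never allowed to perturb a table cell. Published
  anchors are all divisible by 10, so extrapolated cells are exact
  integers. A user-supplied anchor not divisible by 10 yields fractional
  cells, which are rounded half-up to whole JPY with a warning.
* Final quoted prices are stored unrounded; a display value rounded
  half-up to 0.01 JPY is provided alongside, since NHI list prices can
  carry fractions of a yen and no final rounding rule is part of the
  framework.
* Median convention: for an even-sized sample, the mean of the two central
  values floored to an integer. Flooring keeps all downstream arithmetic
  integral; for realistic sample sizes it moves the median by less than
  1 JPY, well inside truncation resolution.
* Patient categories are half-open `[lower, upper)`. The published category
  labels overlap at every boundary (e.g. "5000 to 10,000" then "10,000 to
  30,000"); half-open-from-below makes the label's leading number
  inclusive, so exactly 10,000 patients falls in "10,000 to 30,000" and
  exactly 2,000,000 in "More than 2,000,000".
* Percent-change trends between table versions are reported per category on
  the anchor row (the only data-derived row), both exactly and rounded to
  the nearest multiple of 10 (half away from zero), matching how
  one-significant-figure trends are quoted. A published narrative that
  pools "3000 to 10,000" spans two table bins; the comparison reports the
  two bins separately because the table has no pooled bin.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `premium_rate` | 0.02 / point | premium fraction per additional point |
| `anchor_points` | 35 | row holding the truncated medians |
| `step_rate` | 0.10 / 5 points | extrapolation step |
| points range | 5..50 step 5 | defined table rows |

The framework fixes these values but is explicitly meant to be adapted to
other pricing environments, so they are configuration, not hard-coded
logic. Why the median maps to the 35-point row in particular is a
convention of the framework; the package treats it as a constant
(`anchor_points`) rather than logic.

## The update pipeline

`update_table` rebuilds a conversion table from listing records:
filter → per-category medians → truncation → extrapolation.

Inclusion requires: fiscal year inside the 10-year window, a per-day price
basis, and a stated or derivable daily price. Every excluded record is
logged with one reason (`outside_window`, `per_treatment_basis`,
`per_season_basis`, `price_not_stated_or_derivable`), so included and
excluded sets always partition the input; the pipeline is invariant to
record order. Filtering precedes category assignment (the order does not
affect the result). A category with no included listings aborts the build —
a partial anchor row is not meaningful — naming the empty categories.

Fiscal years follow the April–March convention: a listing dated
2025-02-01 belongs to FY2024.

The `price_derivable` flag is an input: deriving a daily price from
dosage-and-administration text is a human judgment on regulatory documents
and out of scope.

## The synthetic-listings generator

Real listing source material is not machine-readable, so the update
pipeline is exercised on generated data. Each synthetic drug draws:

* a patient category from configured weights (default uniform over the 15
  bins — no per-category listing counts are published, and uniform weights
  exercise every bin at realistic dataset sizes);
* a maximum patient count uniform within the category bounds (the unbounded
  top bin is capped at 10,000,000 for sampling; config-exposed);
* a daily price from a log-normal distribution whose median equals the
  category target — multiplicative noise is the natural model for prices
  spanning tens to hundreds of thousands of JPY/day (default log-sd 0.6);
* exclusion flags with configured probabilities (defaults ≈0.5%
  per-treatment, ≈0.25% per-season, ≈10% not derivable — the rough shares
  seen in real listing rounds, where a decade yields a handful of
  per-treatment/per-season drugs and a few dozen underivable prices among
  ~400 candidates).

The reference conditions (`default_simulation_config`) use 372 drugs over
FY2015–FY2024 with per-category target medians following the published
anchor structure, in which the median daily price rises as the maximum
patient count falls. That published structure itself contains ties and one
local inversion in the mid-categories, so the generator's trend check is
advisory (a warning) and only constrains the extremes: the smallest-patient
category must carry the highest target and the largest-population category
the lowest.

`invert_anchor_targets` builds round-trip fixtures: targets are placed at
the **midpoint** of each anchor value's truncation preimage (anchor + 50
for 4+-digit anchors, + 5 for 3-digit, + 0.5 for 2-digit) with uniform
weights, zero exclusion fractions, and near-degenerate dispersion (1e-9).
A target on the preimage's lower edge would let the empirical median land
just below the anchor under sampling noise and truncate one step low;
the midpoint makes the reconstruction exact for every seed once each
category is populated (with uniform weights and n = 10,000, each bin
receives ≈667 records, so coverage is not in doubt).

### What the generator does and does not emulate

It reproduces the statistical shape the update procedure relies on:
per-category price medians with the published tier structure, realistic
patient counts, and the exclusion mechanisms. It does **not** emulate
temporal price trends within a window, drug-class structure, correlations
between price and fiscal year, or real drug names. Passing the round-trip
tests therefore shows the pipeline arithmetic is correct and
order/filter-invariant — not that any particular real listing dataset would
yield a particular anchor row.

## Problem sizes

The round-trip demonstrations use 10,000 synthetic listings (sample medians
then sit within ±0.1% of their targets, far inside truncation resolution);
order-invariance and fixture tests use 2,000–3,000. The generator
calibration check uses 10,000 drugs at log-sd 0.05 and verifies per-category
medians within 1% of targets.

## Known limitations

* The published drug counts behind the real tables (364 and 372 extracted
  drugs) cannot be reproduced: the source documents are not deposited
  machine-readable data. Only the extraction *rules* are implemented.
* The scoring vocabulary is fixed to the twelve published elements;
  re-weighting or adding elements is possible only by editing the criteria
  tables and is untested against any published grid.
* Assessment scoring of real drugs from review reports requires human
  judgment; the package validates and prices assessments, it does not
  author them.
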