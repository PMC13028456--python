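# marie — multiple-criteria qualitative value-based drug pricing

`marie` implements a value-based pricing (VBP) framework for new drugs that
needs no comparator product and no health-economic model. It was designed
around the Japanese National Health Insurance (NHI) listing process, where a
new drug's reimbursement price must be fixed within 60–90 days of approval,
but the machinery — value scoring, a conversion table, a premium multiplier —
is configurable for other settings.

The package is for health-policy researchers and HTA analysts who want to
score drugs, recompute or audit conversion tables, and study how table
updates shift prices across patient-population tiers.

## The model

A drug is assessed on twelve qualitative **value elements**:

* **Base elements** (always scored): efficacy (20/15/10 points), safety
  (10/5), scientific novelty (10/5), clinical positioning (10/5). The base
  total *B* is a multiple of 5 in [25, 50].
* **Additional elements** (0–50 points total): unmet needs (5/3/1), QoL,
  true endpoints, productivity loss, convenience, diagnosis (5/0 each),
  pediatric use (10/0), others (10/0, justification required).

The **conversion table** maps (*B*, maximum-patient category) to a base
daily price in JPY. Patient counts are binned into 15 ordered categories
from "1 to 10" up to "More than 2,000,000". The table is fully determined by
its **anchor row** at 35 points — the per-category median daily price of
drugs newly listed over a 10-year fiscal window, with the last digit
truncated (last two digits for values of four or more digits). Every other
row follows the extrapolation rule

```
price(B, c) = anchor(c) × (1 + 0.10 × (B − 35)/5)
```

Finally, each additional point adds a **2% premium** on the base price
(linear, not compounding), so the final daily price is

```
final = price(B, c) × (1 + 0.02 × A),   A ∈ [0, 50]
```

which at the 50-point maximum exactly doubles the base price. All of this is
computed with exact rational arithmetic, so published grids reproduce
bit-for-bit.

Two reference conversion tables ship with the package: the FY2012–FY2021
window and the updated FY2015–FY2024 window.

## Worked example

```python
from marie import load_reference_table, price_drug, validate_assessment

assessment = validate_assessment({
    "drug_id": "EXAMPLE-ULTRA-ORPHAN",
    "efficacy": "superiority",                      # 20
    "safety": "acceptable_with_surveillance",       # 10
    "scientific_novelty": "novel_mechanism",        # 10
    "clinical_positioning": "new_option",           # 10
    "unmet_needs": "low_satisfaction_low_contribution",  # +5
    "pediatric_use": "approved",                         # +10
})
table = load_reference_table("FY2015-FY2024")
quote = price_drug(assessment, max_patients=8, table=table)
```

Running `python examples/score_and_price.py` prints:

```
base points:        50
additional points:  15
patient category:   1 to 10
base daily price:   183,430 JPY
premium factor:     1.30
final daily price:  238,459.00 JPY
```

The drug scores the 50-point base maximum, so its base price is the
(50 points, 1-to-10 patients) cell of the FY2015–FY2024 table, 183,430
JPY/day; 15 additional points add 30%, giving 238,459 JPY/day.

The other `examples/` scripts demonstrate rebuilding a table from listing
data, comparing the two table versions (the ultra-orphan anchor rose ≈50%
between windows, the 3000-to-5000-patient anchor fell ≈20%), and generating
synthetic listing datasets.

## Command line

The same operations are available as a thin CLI:

```
marie score drug.yaml
marie price drug.yaml --max-patients 8 --table table.csv
marie build-table --anchors anchors.csv --provenance "FY2015-FY2024" --out table.csv
marie verify-table table.csv
marie update-table --listings listings.csv --window FY2015:FY2024 --out table.csv
marie compare-tables old.csv new.csv
marie simulate --config sim.yaml --out listings.csv
```

## Scope

The package implements the scoring rules, table mechanics, and the update
pipeline. It does not score real drugs from regulatory review documents
(that requires human judgment), parse council PDF materials, or handle
per-treatment or per-season pricing bases (such drugs are excluded by the
update pipeline's filter, as in the published methodology).
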