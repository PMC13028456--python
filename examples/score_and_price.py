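"""Score a drug's value elements and turn them into a daily price.

Builds an assessment for a hypothetical ultra-orphan drug (projected to
treat 8 patients), scores it, and prices it against the bundled
FY2015-FY2024 conversion table.
"""

from marie import load_reference_table, price_drug, validate_assessment

assessment = validate_assessment({
    "drug_id": "EXAMPLE-ULTRA-ORPHAN",
    # base elements (always assessed; here 20 + 10 + 10 + 10 = 50 points)
    "efficacy": "superiority",
    "safety": "acceptable_with_surveillance",
    "scientific_novelty": "novel_mechanism",
    "clinical_positioning": "new_option",
    # additional elements (omitted ones score 0); 5 + 10 = 15 points
    "unmet_needs": "low_satisfaction_low_contribution",
    "pediatric_use": "approved",
})

table = load_reference_table("FY2015-FY2024")
quote = price_drug(assessment, max_patients=8, table=table)

print(f"base points:        {quote.base_points}")
print(f"additional points:  {quote.additional_points}")
print(f"patient category:   {quote.category.label}")
print(f"base daily price:   {quote.base_price:,} JPY")
print(f"premium factor:     {float(quote.premium_factor):.2f}")
print(f"final daily price:  {quote.final_price_rounded:,} JPY")

# The base price is the conversion-table cell for (50 points, 1-10
# patients); 15 additional points add 2% each, a 1.30 multiplier.
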