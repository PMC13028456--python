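"""Generate a realistic synthetic listing dataset.

Uses the generator's reference conditions: 372 drugs over FY2015-FY2024,
log-normal daily prices whose per-category medians follow the published
anchor structure (prices rise as the maximum patient count falls), and
small fractions of per-treatment / per-season / price-not-derivable drugs.
"""

from marie import filter_listings, write_listings
from marie.simulate import default_simulation_config, generate_listings

config = default_simulation_config(seed=7)
records = generate_listings(config)
included, log = filter_listings(records, config.window)

print(f"generated {len(records)} listings over {config.window}")
print(f"pass the inclusion criteria: {len(included)}")
print(f"excluded: {log.reasons()}")
write_listings(records, "scratch_listings.csv")
print("wrote scratch_listings.csv")

# Exclusion reasons mirror the real screening: drugs priced per treatment
# course or per season, and drugs whose daily price cannot be derived.
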