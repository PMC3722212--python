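"""Generate a synthetic geo-stratified survey and inspect its design.

Builds the full two-country sampling frame (429 Norwegian + 280 Swedish
municipalities, 4-5 respondents each), generates the 16-item Likert battery,
and prints the per-country binarized acceptance rates for the four poaching
items.  The rates should sit near the calibrated targets: ~13% in Norway and
~3.5% in Sweden, a log-odds gap of 1.35.
"""

from conflictpci import (
    GeneratorConfig,
    SPECIES_ITEMS,
    binarize_acceptance,
    generate_survey,
)

config = GeneratorConfig(seed=42)
survey, regions = generate_survey(config)

print(f"municipalities: {len(regions)}   respondents: {len(survey)}")
print(f"counties: {regions['county_id'].nunique()}")

df = survey.merge(regions[["municipality_id", "country"]], on="municipality_id")
print("\nBinarized acceptance of poaching (% answering agree/highly agree):")
for country in ("Norway", "Sweden"):
    sub = df[df["country"] == country]
    rates = {
        sp: 100 * binarize_acceptance(sub[f"item_{item}"]).mean()
        for sp, item in SPECIES_ITEMS.items()
    }
    formatted = "  ".join(f"{sp} {r:4.1f}%" for sp, r in rates.items())
    print(f"  {country:7s}: {formatted}")
print("\nNorwegians accept poaching far more often than Swedes; the gap is")
print("the generator's country effect (1.35 log-odds) plus rate-level noise.")
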