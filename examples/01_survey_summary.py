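"""Descriptive summary of a visitation survey: species shares, link persistence.

Generates a small synthetic five-year survey, applies the core-season and
rare-species filters, and prints per-species visit shares plus how many
distinct bee-plant links persist across 1..5 years.
"""

from beepac import data_model as dm
from beepac.synthetic import SyntheticConfig, generate_community

visits, plots, traits, _ = generate_community(SyntheticConfig(seed=1))
visits = dm.filter_rare_species(dm.restrict_to_core_season(visits), min_total=20)

summary = dm.summarize_visitation(visits)
print(f"{summary.grand_total} individuals, {summary.total_links} distinct links\n")
print(summary.species_shares.head(5).to_string(index=False))
print("\nlink persistence (years observed -> n links):")
print(summary.link_persistence.to_string())
# The top share shows community dominance: one species typically accounts
# for ~half of all visits, as in strongly skewed bumblebee assemblages.
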