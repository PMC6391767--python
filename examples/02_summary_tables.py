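"""Build journeys and print the group-level summary tables.

Shows the counts/averages/proportions triple plus time-in-state and
conditional gap tables for a simulated cohort, in the published layout
(columns AP, MY, MO, FY, FO).
"""

from patient_journeys import (
    build_all,
    contact_counts,
    default_sim_config,
    gap_table,
    generate_cohort,
    state_time_table,
)
from patient_journeys.journeys import group_sizes
from patient_journeys.summaries import average_contacts, with_totals

collection, _ = generate_cohort(default_sim_config(seed=42))
journeys = build_all(collection)

counts = contact_counts(journeys)
print("Contacts by type and group:")
print(with_totals(counts), "\n")

print("Mean contacts per patient:")
print(average_contacts(counts, group_sizes(journeys)).round(2), "\n")

print("Mean days in each state (N = no contact):")
print(state_time_table(journeys).round(4), "\n")

print("Mean gap (days) until next contact, by previous type:")
print(gap_table(journeys).round(4))
# Old groups (MO, FO) show more inpatient contacts and shorter
# no-contact sojourns than young groups — the age gradient the default
# configuration encodes.
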