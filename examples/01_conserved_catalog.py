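"""Catalog statistics and tissue-bias calls for the published conserved
miRNA catalog.

The package ships the 85-entry conserved catalog (per-tissue read counts
and seven-species conservation symbols) and the three libraries'
clean-read totals.  This script recomputes the summary statistics and the
family-level tissue-bias calls from those tables.
"""

from mulmir.conserved_catalog import (
    catalog_stats,
    load_catalog,
    load_library_totals,
)
from mulmir.expression import biased_units, call_bias, family_aggregate, to_rpm

df = load_catalog()
stats = catalog_stats(df)

print(f"conserved miRNAs: {stats.n_mirnas} in {stats.n_families} families")
print(f"present per tissue: {stats.presence}")
print(f"common to all three tissues: {stats.n_common_all}")
print(f"length peak: {stats.fraction_length[21]:.1%} of matures are 21 nt")
print(f"families found in <=2 of 7 species: {stats.n_families_in_at_most(2)}")

fam = family_aggregate(
    df.set_index("name")[["leaf", "bark", "male_flower"]],
    df.set_index("name")["family"].to_dict(),
)
calls = call_bias(to_rpm(fam, load_library_totals()))
for tissue in ("leaf", "bark", "male_flower"):
    print(f"{tissue}-biased families: {', '.join(biased_units(calls, tissue))}")

# A family is tissue-biased when its reads-per-million in one tissue are at
# least twice the RPM in each of the other two tissues.
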