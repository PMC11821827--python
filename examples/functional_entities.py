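"""Group species into functional entities (FEs) and measure redundancy.

An FE is a set of species sharing one identical combination of the ten
trait values; species in a shared FE buffer each other's loss.
"""

from benthovuln import (
    SyntheticConfig,
    build_functional_entities,
    generate_trait_table,
    summarize_redundancy,
)

table = generate_trait_table(SyntheticConfig(seed=1))
fes = build_functional_entities(table)
summ = summarize_redundancy(fes)

print(f"{summ.n_species} species -> {summ.n_fes} functional entities")
print(f"mean species per FE: {summ.mean_species_per_fe:.2f} (max {summ.max_species_per_fe})")
print(f"singleton FEs: {summ.n_singletons} ({100 * summ.singleton_share:.1f}%)")
# A singleton FE has no functional redundancy: losing its single species
# removes that trait combination from the assemblage entirely.
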