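"""Generate a synthetic benthic mortality dataset and summarize it.

The defaults emulate the study conditions: 389 species, mass-mortality
records from 1986-2020 with rising frequency, abiotic/biotic drivers, and
trait-dependent severities drawn from a zero-one-inflated beta model.
"""

from collections import Counter

from benthovuln import SyntheticConfig, generate_mortality_records, generate_trait_table

cfg = SyntheticConfig(seed=1)
table = generate_trait_table(cfg)
records, truth = generate_mortality_records(table, cfg)

print(f"species: {table.n_species}, records: {len(records)}")
mix = Counter(r.severity for r in records)
for sev in ("severe", "moderate", "low"):
    print(f"  {sev:9s} {100 * mix[sev] / len(records):5.1f}%")
per_period = Counter((r.year - 1986) // 5 for r in records)
print("events per 5-year period:", [per_period[k] for k in sorted(per_period)])
print("ground-truth beta precision phi:", truth.phi)
# The severity mix approximates the published severe/moderate/low split and
# the period counts rise roughly tenfold, mirroring the observed escalation.
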