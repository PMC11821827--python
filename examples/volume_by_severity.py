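"""Impacted trait volume across mortality-severity thresholds.

For each minimum-mortality threshold, the records at or above it mark their
species' FEs as impacted; the impacted fraction is the ratio of the
impacted-FE convex hull volume to the global hull volume in the selected
trait space.
"""

from benthovuln import (
    SyntheticConfig,
    build_functional_entities,
    generate_mortality_records,
    generate_trait_table,
    gower_distance,
    impacted_fe_ids,
    impacted_fraction,
    select_dimension,
    subset_records,
)

cfg = SyntheticConfig(seed=1)
table = generate_trait_table(cfg)
records, _ = generate_mortality_records(table, cfg)
fes = build_functional_entities(table)
space = select_dimension(gower_distance(table, level="fe"))

print(f"threshold  records  FEs impacted  volume fraction (m={space.m_selected})")
for thr in range(10, 101, 10):
    sub = subset_records(records, min_percent=thr)
    res = impacted_fraction(space, fes, impacted_fe_ids(sub, fes))
    print(f"  >={thr:3d}%   {len(sub):6d}   {res.n_fes_impacted:6d}        {res.fraction:.3f}")
# The fraction shrinks as the threshold rises: fewer records reach higher
# severities, so fewer FEs (and less trait volume) are marked vulnerable.
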