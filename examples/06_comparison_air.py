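"""Between-sample structure and cells-per-air-volume conversion.

Shared-OTU (Venn) partitions and Bray-Curtis similarities on a synthetic
3-sample table, then the water-to-air concentration conversion on the
bundled published cloud-sample measurements.
"""

import pandas as pd

from cloudotu import (
    SyntheticConfig,
    bray_curtis_matrix,
    cells_per_air_volume,
    generate_community,
    normalize_proportions,
    round_reported_concentration,
    run_filter_chain,
    venn_partition,
)
from cloudotu.datasets import cloud_sample_metadata

table, _ = generate_community(
    SyntheticConfig(n_otus=150, depth_dna=10_000, depth_rna=10_000, seed=3)
)
filtered, _ = run_filter_chain(table)

print("DNA-fraction Venn regions (samples sharing each OTU set):")
for p in venn_partition(filtered, "DNA"):
    label = " & ".join(sorted(p.region)) or "(none)"
    print(f"  {label:28s}: {p.otu_count:4d} OTUs")

sim = bray_curtis_matrix(normalize_proportions(filtered))
labels = filtered.column_labels()
print("\nBray-Curtis similarity:")
print(pd.DataFrame(sim, index=labels, columns=labels).round(2))

print("\ncells per m^3 of cloudy air (from published sample measurements):")
for sid, m in cloud_sample_metadata().items():
    prok = cells_per_air_volume(m.prok_conc_per_mL, m.water_volume_mL, m.air_volume_m3)
    euk = cells_per_air_volume(m.euk_conc_per_mL, m.water_volume_mL, m.air_volume_m3)
    print(
        f"  {sid:12s}: prokaryotes {round_reported_concentration(prok):>6g}, "
        f"eukaryotes {round_reported_concentration(euk):>4g}"
    )
# The three samples span roughly 8-270 eukaryote and 0.35e3-2.5e3
# prokaryote cells per m^3 of cloudy air.
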