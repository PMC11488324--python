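"""Call per-cell mitochondrial variants through the full filter cascade.

Plants three clonal heteroplasmies (including the designated aging sites
m.9821A>T, m.15219T>C, m.15984C>T), genotypes every cell at ~60x, and shows
the filter audit trail plus functional annotation.
"""

import numpy as np

from mitoscatac import (
    GenotypingConfig,
    SimConfig,
    VariantSpec,
    call_variants,
    mouse_mito_genome,
    qpcr_copy_number,
    simulate_cells,
    simulate_mito_read_arrays,
)

genome = mouse_mito_genome()
config = SimConfig(
    n_cells=80, seed=12, mito_coverage=100,
    variants=(
        VariantSpec(9821, "T", pi=0.1, beta_a=1.0, beta_b=10.0),
        VariantSpec(15219, "C", pi=0.1, beta_a=1.0, beta_b=10.0),
        VariantSpec(15984, "T", pi=0.1, beta_a=1.0, beta_b=10.0),
    ),
)
truth = simulate_cells(config, genome)
reads = simulate_mito_read_arrays(truth, config, genome)

table, vaf, tensor = call_variants(reads, GenotypingConfig(), genome)
passing = table[table["pass_all"]]
cols = ["pos", "ref", "alt", "bulk_vaf", "n_cells", "strand_concordance",
        "vmr", "gene", "region", "effect", "aa_change"]
print(passing[cols].to_string(index=False))
print(f"\n{len(passing)} variants pass all seven bulk filters "
      f"(allele-depth ratio, strand bias, depth >= 250, BQ20/MAPQ30/NM<=2, "
      f">= 50 cells) plus the blacklist.")
cytb = passing[passing["pos"] == 15219]
if len(cytb):
    r = cytb.iloc[0]
    print(f"m.15219T>C annotates as {r['gene']} {r['cdna']} / {r['aa_change']} — "
          f"a {r['effect']} substitution in cytochrome b.")

for vid in vaf.columns:
    planted = truth.vafs[vid]
    est = vaf[vid]
    rmse = float(np.sqrt(np.nanmean((est.to_numpy() - planted.to_numpy()) ** 2)))
    print(f"{vid}: per-cell VAF RMSE vs truth = {rmse:.3f} "
          f"(binomial noise at this coverage)")

print(f"\nqPCR check: Ct_nuclear=25, Ct_mito=17 -> "
      f"{qpcr_copy_number(25, 17):.0f} mtDNA copies per cell")
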