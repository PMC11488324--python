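"""Carrier-vs-WT differential accessibility with a permutation control and
motif enrichment.

Cells carrying any of the three designated mtDNA variants form the carrier
group; 30 of 150 peaks receive a 2x accessibility effect in carriers and an
instance of a planted motif. The logistic LR test should recover the
affected peaks, the 100 random splits should find nothing, and the planted
motif should top the enrichment table.
"""

import numpy as np
import pandas as pd

from mitoscatac import (
    SimConfig,
    VariantSpec,
    default_pwms,
    differential_peaks,
    embed_carrier_effects,
    make_peaks,
    motif_enrichment,
    mouse_mito_genome,
    permutation_control,
    scan_motifs,
    simulate_cells,
)

genome = mouse_mito_genome()
config = SimConfig(
    n_cells=1000, seed=31,
    variants=(
        VariantSpec(9821, "T", pi=0.5, beta_a=2, beta_b=10),
        VariantSpec(15219, "C", pi=0.7, beta_a=2, beta_b=10),
        VariantSpec(15984, "T", pi=0.7, beta_a=2, beta_b=10),
    ),
)
truth = simulate_cells(config, genome)
peaks = make_peaks(genome, config).head(150)
pwms = default_pwms()
counts, seqs, affected, peak_truth, totals = embed_carrier_effects(
    truth, peaks, pwms, effect=2.0, n_affected=30
)
status = pd.Series(
    np.where(truth.cells["carrier"], "carrier", "WT"), index=truth.cells["barcode"]
)
print(f"{(status == 'carrier').sum()} carrier / {(status == 'WT').sum()} WT cells")

res = differential_peaks(counts, status, total_fragments=totals)
sig = res.loc[res["significant"], "peak"]
hit = len(set(sig) & set(affected))
print(f"{len(sig)} significant peaks (q<0.01, |FC|>=1.25); "
      f"{hit}/{len(affected)} planted peaks recovered, "
      f"{len(sig) - hit} false positives")

perm = permutation_control(counts, status, n_reps=100, seed=5,
                           total_fragments=totals)
print(f"permutation control: median {perm['n_significant'].median():.0f} "
      f"significant peaks across 100 random splits "
      f"({(perm['n_significant'] >= 1).mean():.0%} of splits find anything) — "
      f"the signal is carrier-linked, not an artifact of the test")

hits = scan_motifs(pwms, seqs)
enrich = motif_enrichment(hits, list(sig))
print("\nmotif over-representation in significant peaks (hypergeometric):")
print(enrich.to_string(index=False))
print(f"top motif: {enrich.iloc[0]['motif']} "
      f"(the one planted into carrier-affected peaks)")
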