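"""Ligand-class enrichment among the most abundant OSN subtypes.

Simulates a species in which receptors detecting the planted ligand class
(key food odorants) have 2.4-fold elevated abundance, then asks: are
deorphaned KFO receptors over-represented above the 90th expression
percentile, and how much higher is their mean expression?
"""

from olfatlas import quantify
from olfatlas.ligand_enrichment import binom_two_tail, enrichment_report
from olfatlas.synthetic_data import (
    SimulationConfig, gen_count_matrix, gen_ligand_annotations, gen_or_catalog,
)

cfg = SimulationConfig(seed=7)  # planted_fold = 2.4 for KFO receptors
catalog = gen_or_catalog(cfg, "human")
pairs, multipliers = gen_ligand_annotations(catalog, cfg, "human")
counts, _, _ = gen_count_matrix(catalog, cfg, "human", multipliers=multipliers)
norm = quantify.normalize(counts, quantify.estimate_size_factors(counts))
abundance = quantify.summarize_abundance(norm, catalog.index)
quantify.top_decile_set(abundance)

for cls in ("KFO", "SMC", "other"):
    res = enrichment_report(abundance, pairs, cls)
    print(f"{cls:>5}: {res.k}/{res.n} in top decile, p = {res.p_two_tail:.4f}, "
          f"Wilson 95% CI ({res.wilson_low:.3f}, {res.wilson_high:.3f}), "
          f"fold change {res.fold_change:.2f}")

print()
print("reference scenarios (in-study k/n):")
print(f"  26/73 vs 10% baseline: p = {binom_two_tail(26, 73, 0.10):.2e}")
print(f"  13/89 vs 10% baseline: p = {binom_two_tail(13, 89, 0.10):.4f}")
# The planted KFO class shows both an excess of top-decile receptors and an
# elevated fold change; unplanted classes stay near the 10% baseline.
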