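"""Generate a synthetic keratinocyte cohort with planted ground truth.

The generator emulates the data the analysis assumes: a UMI count matrix
with 8 discrete differentiation stages, a FANTOM-style bulk cell-type atlas
with a small keratinocyte sample group, and basal (BK) / differentiated (DK)
super-enhancer sets with planted motif densities.
"""

from collections import Counter

from keranet.simulate import (
    SimulationConfig,
    simulate_bulk_celltype_matrix,
    simulate_se_regions,
    simulate_stage_counts,
)

config = SimulationConfig(seed=1)
counts, truth = simulate_stage_counts(config)
print(f"counts: {counts.n_genes} genes x {counts.n_cells} cells, "
      f"{(counts.values == 0).mean():.0%} zeros")

roles = Counter(r.split("_of_")[0] for r in truth.gene_role.values())
print("planted gene roles:", dict(roles))

bulk, _ = simulate_bulk_celltype_matrix(config)
n_target = sum(g == "keratinocyte" for g in bulk.sample_group.values())
print(f"bulk atlas: {len(bulk.feature_ids)} TSS features, "
      f"{len(bulk.sample_ids)} samples ({n_target} keratinocyte)")

se, se_truth = simulate_se_regions(config)
print(f"super-enhancers: {len(se.by_state('BK'))} BK + {len(se.by_state('DK'))} DK regions, "
      f"{len(se_truth.planted_sites)} planted motif sites")
# Every quantity above is recorded in PlantedTruth, so each downstream
# analysis step can be scored against what was actually planted.
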