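"""Scan super-enhancers for TF motifs and call differential enrichment
between the basal and differentiated SE sets.

Each sequence is scanned on both strands with a log-odds PWM whose hit
threshold has an exact per-position null p-value of 1e-4 (dynamic
programming over the integer-rounded score distribution).  Counts are scaled
per kilobase, the BK and DK distributions are compared per TF with a
two-sided Mann-Whitney U, and the signed magnitude is the rank-biserial
effect (positive = BK-enriched).
"""

import warnings

warnings.filterwarnings("ignore")

from keranet.motifs import enrichment_table
from keranet.simulate import SimulationConfig, simulate_motifs, simulate_se_regions

config = SimulationConfig(seed=4)
pwms = simulate_motifs(config)
se, truth = simulate_se_regions(config, pwms)
table, counts = enrichment_table(se, pwms)

print(table[["direction", "signed_magnitude", "q_value"]].to_string())
correct = sum(table.loc[tf, "direction"] == d
              for tf, d in truth.tf_enrichment_direction.items() if d != "none")
print(f"\nplanted directions recovered: {correct}/10; "
      "signed_magnitude > 0 marks BK-enriched motifs, < 0 DK-enriched, "
      "and 'none' rows did not pass the BH-corrected 5% threshold.")
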