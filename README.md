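# keranet

Staging, regulatory-network inference and transcription-factor
prioritization for keratinocyte differentiation single-cell RNA-seq.

Human epidermis renews from basal keratinocytes (BK) that exit the cell
cycle, migrate upward and terminally differentiate (DK). `keranet`
reimplements, as a tested and fully synthetic-data-verifiable pipeline, a
computational workflow that:

1. orders keratinocytes into **K = 8 discrete differentiation stages** by
   diffusion imputation (a cell–cell Markov operator `M` on the symmetrized
   kNN graph; imputed expression `X · (Mᵀ)ᵗ`) followed by k-means-based
   approximate spectral clustering, with per-stage outlier removal and a
   light re-imputation at reduced diffusion time;
2. identifies **keratinocyte-specific genes and TFs** from a FANTOM/CAGE-style
   bulk atlas (TSS features summed to genes; two-sided Mann–Whitney U of a
   3-sample keratinocyte group vs. the remaining primary-cell samples; BH
   FDR < 0.05 with elevated target-group mean; raw-UMI expression filters);
3. computes **moderated BK-vs-DK differential expression** on log₂(cpm+1)
   with empirical-Bayes variance shrinkage
   `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` (two-group limma-trend style);
4. scores **differential TF motif enrichment** between BK- and DK-specific
   super-enhancers: exact-threshold PWM scanning (per-position null p-value
   by dynamic programming), per-kilobase occurrence counts, Mann–Whitney U
   per TF with the rank-biserial effect `2·AUC − 1` as signed magnitude, and
   a one-sided concordance test between motif enrichment and the TF
   expression branches;
5. builds **module-level regulatory networks** per state from signed
   soft-thresholded similarity `S_ij = sign(r_ij)·|r_ij|^β` (β = 6) between
   enriched TFs and keratinocyte genes, clustering TFs by expression and
   genes by their TF-correlation profiles, and calling a signed edge for
   every (TF module A, gene module B) with `|mean_{i∈A,j∈B} S_ij|` above a
   permutation-null threshold;
6. ranks knockdown candidates by the **differentiation-promoting score**
   `Σ_t sign(r_t) · log2FC_t` over each TF's correlated targets (negative =
   basal/progenitor-promoting), after a strict `< 5 FPKM` culture-expression
   filter.

A first-class synthetic-data generator (`keranet.simulate`) produces every
input — stage-structured negative-binomial UMI counts with dropout, the bulk
atlas, super-enhancer sequences with planted motif densities — together with
complete planted truth, so every stage of the pipeline is scored against
known labels.

## Worked example

```python
from keranet.simulate import SimulationConfig, simulate_stage_counts
from keranet.staging import stage_cells
from keranet.evaluate import stage_ari

config = SimulationConfig(seed=2)          # 3,000 cells x 1,500 genes, 8 stages
counts, truth = simulate_stage_counts(config)
result = stage_cells(counts, n_stages=8, seed=2)
print(len(result.retained_cells), stage_ari(result, truth))
```

prints

```
retained 2576 / 3000 cells after outlier removal
stage sizes: {1: 343, 2: 345, 3: 314, 4: 319, 5: 310, 6: 310, 7: 308, 8: 327}
adjusted Rand index vs planted stages: 1.000
```

i.e. after outlier removal the recovered stages coincide exactly with the
planted differentiation stages. Running the whole pipeline
(`examples/05_full_pipeline_and_network.py`, or `keranet run --seed 1
--outdir out/`) finishes in well under a minute and ends with the knockdown
ranking:

```
 rank   tf       score  n_targets      fpkm  passed_culture_filter
    1 TF05 -416.195832        195 24.154847                   True
    2 TF01 -391.089551        180 84.404596                   True
    3 TF03 -302.865218        138 30.371726                   True
```

The most negative scores nominate basal-state promoters — here the top
candidates are exactly the planted basal TFs, the synthetic analogue of the
experimentally validated basal promoters in the study this pipeline models.

The `examples/` directory holds one short script per capability
(simulation, staging, specificity screen + DE, motif enrichment, full
pipeline + network). The `keranet` command exposes the same stages as
subcommands (`simulate`, `stage`, `specificity`, `de`, `trajectories`,
`motifs`, `network`, `prioritize`, `run`) driven by one YAML config.

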