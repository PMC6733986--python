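"""Planted-truth recovery metrics for the synthetic pipeline.

These helpers compare pipeline outputs against the generator's
:class:`~keranet.simulate.PlantedTruth`: stage recovery (adjusted Rand
index), TF branch purity, motif direction recovery and null false-positive
rate, module-edge precision/recall, and the top-rank rate of planted
basal-promoting TFs over scoring replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import CountMatrix
from .simulate import PlantedTruth, SimulationConfig, simulate_stage_counts
from .staging import (
    StagingResult,
    build_diffusion_operator,
    cpm,
    impute,
    normalize_log_cpm,
    pca_embedding,
)
from .network import StateNetwork
from .prioritize import differentiation_score, identify_targets
from .screen import moderated_de


def stage_ari(staging: StagingResult, truth: PlantedTruth) -> float:
    """Adjusted Rand index of assigned vs planted stages over retained cells."""
    planted = [truth.cell_stage[c] for c in staging.retained_cells]
    return float(adjusted_rand_score(planted, staging.stages.labels))


def branch_purity(branch_of: dict[str, str], truth: PlantedTruth) -> float:
    """Purity of the 2-branch TF split against planted bk_tf/dk_tf roles.

    For each branch, its majority planted role wins; purity is the fraction
    of TFs matching their branch's majority role, maximized over the two
    possible branch-role pairings.
    """
    tfs = [t for t in branch_of if truth.gene_role.get(t) in ("bk_tf", "dk_tf")]
    if not tfs:
        raise ValueError("no planted TFs among the branched items")
    match_a = sum(
        1
        for t in tfs
        if (branch_of[t] == "BK_branch") == (truth.gene_role[t] == "bk_tf")
    )
    return max(match_a, len(tfs) - match_a) / len(tfs)


def direction_recovery(enrichment: pd.DataFrame, truth: PlantedTruth) -> tuple[float, float]:
    """(recovery rate over directional motifs, FPR over null motifs).

    Recovery: a directional motif counts as recovered when its called
    direction equals the planted one.  FPR: fraction of planted-null motifs
    called in either direction.
    """
    directional = [t for t, d in truth.tf_enrichment_direction.items() if d in ("BK", "DK")]
    nulls = [t for t, d in truth.tf_enrichment_direction.items() if d == "none"]
    directional = [t for t in directional if t in enrichment.index]
    nulls = [t for t in nulls if t in enrichment.index]
    rec = (
        np.mean(
            [enrichment.loc[t, "direction"] == truth.tf_enrichment_direction[t] for t in directional]
        )
        if directional
        else np.nan
    )
    fpr = np.mean([enrichment.loc[t, "direction"] != "none" for t in nulls]) if nulls else 0.0
    return float(rec), float(fpr)


def module_edge_precision_recall(net: StateNetwork, truth: PlantedTruth) -> tuple[float, float, int]:
    """Module-level precision/recall of signed edges against planted TF-target pairs.

    A planted pair (tf, gene, sign) is *eligible* when both ends are in the
    network.  Recall: fraction of eligible pairs whose module pair carries an
    edge of the planted sign.  Precision: fraction of predicted edges
    supported by at least one eligible planted pair of matching sign.
    Returns ``(precision, recall, n_eligible_pairs)``.
    """
    tf_mod = net.modules.tf_modules
    gene_mod = net.modules.gene_modules
    edge_sign = {
        (int(r.tf_module), int(r.gene_module)): (1 if r.sign == "activation" else -1)
        for r in net.edges.itertuples()
    }
    eligible = [
        (tf, g, sign)
        for tf, g, sign in truth.target_pairs()
        if tf in tf_mod and g in gene_mod
    ]
    if not eligible:
        return float("nan"), float("nan"), 0
    hits = sum(
        1
        for tf, g, sign in eligible
        if edge_sign.get((tf_mod[tf], gene_mod[g])) == sign
    )
    recall = hits / len(eligible)
    supported = 0
    support_map: dict[tuple[int, int], set[int]] = {}
    for tf, g, sign in eligible:
        support_map.setdefault((tf_mod[tf], gene_mod[g]), set()).add(sign)
    for pair, sign in edge_sign.items():
        if sign in support_map.get(pair, set()):
            supported += 1
    precision = supported / len(edge_sign) if edge_sign else float("nan")
    return float(precision), float(recall), len(eligible)


# ---------------------------------------------------------------------------
# reduced-size scoring replicates for the prioritization ranking property


def scoring_replicate_top_is_basal(
    config: SimulationConfig,
    seed: int,
    t_impute: int = 2,
    min_abs_r: float = 0.3,
) -> bool:
    """One reduced-size prioritization replicate.

    Simulates a cohort at the configured (reduced) size, uses the planted
    stage labels, imputes lightly, computes moderated DE between the planted
    BK and DK stages and correlation-called targets over stages 1..K-1, and
    checks that the most negative (most basal-promoting) TF score belongs to
    a planted basal TF.
    """
    cfg = SimulationConfig(**{**config.to_dict(), "seed": seed})
    counts, truth = simulate_stage_counts(cfg)
    log_raw = normalize_log_cpm(counts)
    emb = pca_embedding(log_raw, 20, seed)
    op = build_diffusion_operator(emb, min(15, cfg.n_cells - 1), 5)
    imputed = impute(cpm(counts), op, t_impute)
    log_imp = pd.DataFrame(
        np.log2(imputed + 1.0), index=counts.gene_ids, columns=counts.cell_ids
    )
    stage_of = np.array([truth.cell_stage[c] for c in counts.cell_ids])
    bk_lo, bk_hi = cfg.bk_stage_range
    dk_lo, dk_hi = cfg.dk_stage_range
    state = {
        c: ("BK" if bk_lo <= s <= bk_hi else "DK" if dk_lo <= s <= dk_hi else "other")
        for c, s in zip(counts.cell_ids, stage_of)
    }
    log_cpm_raw = pd.DataFrame(log_raw, index=counts.gene_ids, columns=counts.cell_ids)
    de = moderated_de(log_cpm_raw, state, trend=True)
    traj_mask = stage_of <= cfg.n_stages - 1  # stages 1..K-1: the trajectory
    candidates = {
        g for g, r in truth.gene_role.items() if r.startswith("target_of_") or r in ("bk_tf", "dk_tf")
    }
    best_tf, best_score = None, np.inf
    for tf in cfg.tfs:
        targets = identify_targets(log_imp, traj_mask, tf, candidates - {tf}, min_abs_r)
        score = differentiation_score(tf, targets, de).score
        if score < best_score:
            best_tf, best_score = tf, score
    return truth.gene_role.get(best_tf) == "bk_tf"


def make_counts_subset(counts: CountMatrix, gene_order: list[str], cell_order: list[str]) -> CountMatrix:
    """Reorder a count matrix by explicit gene/cell orders (for invariance checks)."""
    gi = [counts.gene_ids.index(g) for g in gene_order]
    ci = [counts.cell_ids.index(c) for c in cell_order]
    return CountMatrix(counts.values[np.ix_(gi, ci)], list(gene_order), list(cell_order))
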