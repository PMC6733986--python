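"""End-to-end pipeline orchestration with manifests and resumability.

Stages run in dependency order: simulate (optional when inputs are supplied)
-> stage -> specificity -> de -> trajectories -> motifs (incl. concordance)
-> network (BK, DK) -> prioritize.  Each stage writes its outputs under the
run directory; a manifest records the configuration snapshot, the root seed,
per-stage wall-clock and SHA-256 digests of every output.  With
``resume=True`` a stage whose outputs all exist is loaded from disk instead
of recomputed, so deleting one intermediate recomputes only its dependents.

Every stochastic stage derives its seed from the root seed through a named
substream, making reruns with identical config byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    ConfigurationError,
    read_bulk_tsv,
    read_counts_tsv,
    read_gene_list,
    read_json,
    read_mtx_triplet,
    read_se_regions,
    write_bulk_tsv,
    write_gene_list,
    write_json,
    write_mtx_triplet,
    write_se_regions,
)
from .motifs import concordance_test, enrichment_table, read_jaspar, write_jaspar
from .network import build_state_network, edges_to_graphml
from .prioritize import (
    differentiation_score,
    identify_targets,
    rank_candidates,
    target_audit_frame,
)
from .screen import (
    aggregate_features_to_genes,
    assemble_gene_sets,
    celltype_specific_screen,
    de_expressed_filter,
    GeneSets,
    moderated_de,
    normalize_log_cpm_frame,
    scrna_expression_filter,
)
from .simulate import (
    PlantedTruth,
    SimulationConfig,
    curated_tf_list,
    simulate_bulk_celltype_matrix,
    simulate_culture_fpkm,
    simulate_motifs,
    simulate_se_regions,
    simulate_stage_counts,
    tf_annotation_list,
)
from .staging import (
    StageAssignment,
    StagingResult,
    orient_stages,
    stage_cells,
    stage_profile,
)
from .trajectories import (
    cluster_size_enrichment,
    cluster_trajectories,
    dynamic_gene_filter,
    linkage_to_bracket,
    peak_stage,
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # SimulationConfig field overrides
    "stage": {
        "n_stages": 8,
        "n_pcs": 30,
        "knn": 30,
        "ka": 10,
        "t_impute": 6,
        "t_reimpute": 1,
        "knn_reimpute": 10,
        "ka_reimpute": 4,
        "m_representatives": 1000,
        "mad_c": 3.0,
    },
    "specificity": {"alpha": 0.05, "exclude_samples": []},
    "de": {"trend": True, "alpha": 0.05, "lfc_threshold": 0.25, "min_umis": 3, "min_cells": 20},
    "trajectories": {
        "min_lfc": 1.0,
        "n_tf_clusters": 2,
        "antioxidant_min_lfc": 1.0,
        "antioxidant_n_clusters": 3,
    },
    "motifs": {"scan_p": 1e-4, "alpha": 0.05, "min_regions": 5, "restrict_concordance": True},
    "network": {
        "beta": 6.0,
        "n_tf_modules": None,
        "n_gene_modules": None,
        "threshold": None,
        "null_quantile": 0.95,
        "n_permutations": 200,
    },
    "prioritize": {"min_abs_r": 0.3, "min_fpkm": 5.0},
}

STAGE_ORDER = [
    "simulate",
    "stage",
    "specificity",
    "de",
    "trajectories",
    "motifs",
    "network",
    "prioritize",
]


def merge_config(overrides: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def substream_seed(root_seed: int, name: str) -> int:
    """Stable per-stage integer seed below 2**31 derived from the root seed."""
    key = zlib.crc32(name.encode())
    ss = np.random.SeedSequence(root_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# per-stage output layout


def _stage_outputs(outdir: Path) -> dict[str, list[Path]]:
    d = outdir
    return {
        "simulate": [
            d / "sim/counts/matrix.mtx",
            d / "sim/counts/genes.tsv",
            d / "sim/counts/barcodes.tsv",
            d / "sim/truth.json",
            d / "sim/bulk.tsv",
            d / "sim/bulk_samples.tsv",
            d / "sim/feature_map.tsv",
            d / "sim/se.bed",
            d / "sim/se.fasta",
            d / "sim/motifs.pfm",
            d / "sim/culture_fpkm.tsv",
            d / "sim/curated_tfs.txt",
            d / "sim/tf_annotation.txt",
            d / "sim/antioxidant_genes.txt",
        ],
        "stage": [
            d / "stage/stage_labels.tsv",
            d / "stage/retained_mask.tsv",
            d / "stage/stage_profile.tsv",
            d / "stage/stage_profile_normalized.tsv",
            d / "stage/imputed_log.tsv",
        ],
        "specificity": [d / "specificity/specificity.tsv", d / "specificity/gene_sets.json"],
        "de": [d / "de/de.tsv"],
        "trajectories": [
            d / "trajectories/tf_branches.tsv",
            d / "trajectories/tf_linkage.txt",
            d / "trajectories/antioxidant_clusters.tsv",
            d / "trajectories/antioxidant_enrichment.json",
        ],
        "motifs": [
            d / "motifs/motif_enrichment.tsv",
            d / "motifs/motif_counts.tsv",
            d / "motifs/concordance.json",
        ],
        "network": [
            d / "network/BK_edges.tsv",
            d / "network/BK_tf_modules.tsv",
            d / "network/BK_gene_modules.tsv",
            d / "network/BK_similarity.tsv",
            d / "network/BK_modules.graphml",
            d / "network/DK_edges.tsv",
            d / "network/DK_tf_modules.tsv",
            d / "network/DK_gene_modules.tsv",
            d / "network/DK_similarity.tsv",
            d / "network/DK_modules.graphml",
            d / "network/thresholds.json",
        ],
        "prioritize": [d / "prioritize/ranking.tsv", d / "prioritize/target_audit.tsv"],
    }


# ---------------------------------------------------------------------------
# stage implementations (compute + write + load)


def _run_simulate(ctx: dict, outdir: Path) -> None:
    sim_cfg = SimulationConfig(**{**ctx["config"]["simulate"], "seed": ctx["seed"]})
    counts, truth = simulate_stage_counts(sim_cfg)
    bulk, _ = simulate_bulk_celltype_matrix(sim_cfg)
    pwms = simulate_motifs(sim_cfg)
    se, se_truth = simulate_se_regions(sim_cfg, pwms)
    truth.planted_sites = se_truth.planted_sites
    ctx.update(
        sim_config=sim_cfg,
        counts=counts,
        truth=truth,
        bulk=bulk,
        pwms=pwms,
        se=se,
        culture_fpkm=simulate_culture_fpkm(sim_cfg),
        curated_tfs=set(curated_tf_list(sim_cfg)),
        tf_annotation=set(tf_annotation_list(sim_cfg)),
        antioxidant_genes=[g for g, r in truth.gene_role.items() if r.startswith("antioxidant_")],
    )
    d = outdir / "sim"
    d.mkdir(parents=True, exist_ok=True)
    write_mtx_triplet(counts, d / "counts")
    write_json(truth.to_dict(), d / "truth.json")
    write_bulk_tsv(bulk, d / "bulk.tsv", d / "bulk_samples.tsv")
    pd.DataFrame(
        {"feature_id": list(bulk.feature_to_gene), "gene": list(bulk.feature_to_gene.values())}
    ).to_csv(d / "feature_map.tsv", sep="\t", index=False)
    write_se_regions(se, d / "se.bed", d / "se.fasta")
    write_jaspar(pwms, d / "motifs.pfm")
    ctx["culture_fpkm"].to_csv(d / "culture_fpkm.tsv", sep="\t", index=False)
    write_gene_list(sorted(ctx["curated_tfs"]), d / "curated_tfs.txt")
    write_gene_list(sorted(ctx["tf_annotation"]), d / "tf_annotation.txt")
    write_gene_list(sorted(ctx["antioxidant_genes"]), d / "antioxidant_genes.txt")


def _load_simulate(ctx: dict, outdir: Path) -> None:
    d = outdir / "sim"
    sim_cfg = SimulationConfig(**{**ctx["config"]["simulate"], "seed": ctx["seed"]})
    fmap = pd.read_csv(d / "feature_map.tsv", sep="\t")
    ctx.update(
        sim_config=sim_cfg,
        counts=read_mtx_triplet(d / "counts"),
        truth=PlantedTruth.from_dict(read_json(d / "truth.json")),
        bulk=read_bulk_tsv(
            d / "bulk.tsv",
            d / "bulk_samples.tsv",
            dict(zip(fmap["feature_id"].astype(str), fmap["gene"].astype(str))),
        ),
        pwms=read_jaspar(d / "motifs.pfm"),
        se=read_se_regions(d / "se.bed", d / "se.fasta"),
        culture_fpkm=pd.read_csv(d / "culture_fpkm.tsv", sep="\t").set_index("tf", drop=False),
        curated_tfs=set(read_gene_list(d / "curated_tfs.txt")),
        tf_annotation=set(read_gene_list(d / "tf_annotation.txt")),
        antioxidant_genes=read_gene_list(d / "antioxidant_genes.txt"),
    )


def _run_stage(ctx: dict, outdir: Path) -> None:
    cfg = ctx["config"]["stage"]
    res = stage_cells(
        ctx["counts"],
        n_stages=cfg["n_stages"],
        n_pcs=cfg["n_pcs"],
        k_neighbors=cfg["knn"],
        ka_adaptive=cfg["ka"],
        t_impute=cfg["t_impute"],
        t_reimpute=cfg["t_reimpute"],
        k_reimpute=cfg["knn_reimpute"],
        ka_reimpute=cfg["ka_reimpute"],
        m_representatives=min(cfg["m_representatives"], ctx["counts"].n_cells),
        c_mad=cfg["mad_c"],
        seed=substream_seed(ctx["seed"], "stage"),
    )
    # orient the stage axis: TFs robustly expressed in undifferentiated
    # culture must peak at the basal (low-numbered) end
    fpkm = ctx["culture_fpkm"]
    basal_weight = {
        str(t): float(np.log2(v + 1.0)) for t, v in zip(fpkm["tf"], fpkm["fpkm"])
    }
    peaks = {}
    for tf in basal_weight:
        if tf in res.profile.mean_expr.index:
            row = res.profile.mean_expr.loc[tf]
            peaks[tf] = int(row.idxmax())
    new_labels, flipped = orient_stages(
        res.stages.labels, res.stages.K, peaks, basal_weight
    )
    if flipped:
        res.stages = StageAssignment(
            new_labels, res.stages.K, res.stages.representative_index
        )
        res.profile = stage_profile(
            res.imputed_cpm.to_numpy(), list(res.imputed_cpm.index), res.stages
        )
    ctx["staging"] = res
    d = outdir / "stage"
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": res.retained_cells, "stage": res.stages.labels}).to_csv(
        d / "stage_labels.tsv", sep="\t", index=False
    )
    pd.DataFrame({"cell_id": res.all_cells, "retained": res.mask.astype(int)}).to_csv(
        d / "retained_mask.tsv", sep="\t", index=False
    )
    res.profile.mean_expr.to_csv(d / "stage_profile.tsv", sep="\t")
    res.profile.normalized.to_csv(d / "stage_profile_normalized.tsv", sep="\t")
    res.log_imputed.round(6).to_csv(d / "imputed_log.tsv", sep="\t")


def _load_stage(ctx: dict, outdir: Path) -> None:
    d = outdir / "stage"
    labels = pd.read_csv(d / "stage_labels.tsv", sep="\t")
    mask_df = pd.read_csv(d / "retained_mask.tsv", sep="\t")
    log_imp = pd.read_csv(d / "imputed_log.tsv", sep="\t", index_col=0)
    prof = pd.read_csv(d / "stage_profile.tsv", sep="\t", index_col=0)
    prof.columns = [int(c) for c in prof.columns]
    norm = pd.read_csv(d / "stage_profile_normalized.tsv", sep="\t", index_col=0)
    norm.columns = [int(c) for c in norm.columns]
    from .staging import StageProfile

    stages = StageAssignment(
        labels["stage"].to_numpy(), ctx["config"]["stage"]["n_stages"]
    )
    imputed_cpm = np.exp2(log_imp.to_numpy()) - 1.0
    ctx["staging"] = StagingResult(
        retained_cells=labels["cell_id"].astype(str).tolist(),
        stages=stages,
        imputed_cpm=pd.DataFrame(
            imputed_cpm, index=log_imp.index, columns=log_imp.columns
        ),
        log_imputed=log_imp,
        profile=StageProfile(prof, norm),
        embedding=np.zeros((len(labels), 0)),
        mask=mask_df["retained"].to_numpy(dtype=bool),
        first_pass_stages=stages,
        all_cells=mask_df["cell_id"].astype(str).tolist(),
    )


def _run_specificity(ctx: dict, outdir: Path) -> None:
    cfg = ctx["config"]["specificity"]
    gene_bulk = aggregate_features_to_genes(ctx["bulk"])
    screen = celltype_specific_screen(
        gene_bulk, "keratinocyte", alpha=cfg["alpha"], exclude_samples=cfg["exclude_samples"]
    )
    expressed = scrna_expression_filter(ctx["counts"])
    selected = set(screen.index[screen["selected"]]) & expressed
    tf_ann = ctx["tf_annotation"]
    gene_sets = assemble_gene_sets(
        screen_tfs=selected & tf_ann,
        screen_genes=selected - tf_ann,
        curated_tfs=ctx["curated_tfs"],
        manual_additions=set(),
        expressed_genes=expressed,
    )
    ctx.update(screen=screen, gene_sets=gene_sets, expressed_genes=expressed)
    d = outdir / "specificity"
    d.mkdir(parents=True, exist_ok=True)
    screen.drop(columns="gene").to_csv(d / "specificity.tsv", sep="\t")
    write_json(gene_sets.to_dict(), d / "gene_sets.json")


def _load_specificity(ctx: dict, outdir: Path) -> None:
    d = outdir / "specificity"
    ctx["screen"] = pd.read_csv(d / "specificity.tsv", sep="\t", index_col=0)
    gs = read_json(d / "gene_sets.json")
    ctx["gene_sets"] = GeneSets(
        fantom_genes=set(gs["fantom_genes"]),
        fantom_tfs=set(gs["fantom_tfs"]),
        curated_tfs=set(gs["curated_tfs"]),
        manual_additions=set(gs["manual_additions"]),
    )
    ctx["expressed_genes"] = scrna_expression_filter(ctx["counts"])


def _state_map(ctx: dict) -> dict[str, str]:
    sim_cfg = ctx["sim_config"]
    bk_lo, bk_hi = sim_cfg.bk_stage_range
    dk_lo, dk_hi = sim_cfg.dk_stage_range
    staging: StagingResult = ctx["staging"]
    out = {}
    for cell, s in zip(staging.retained_cells, staging.stages.labels):
        if bk_lo <= s <= bk_hi:
            out[cell] = "BK"
        elif dk_lo <= s <= dk_hi:
            out[cell] = "DK"
        else:
            out[cell] = "other"
    return out


def _run_de(ctx: dict, outdir: Path) -> None:
    cfg = ctx["config"]["de"]
    counts = ctx["counts"]
    staging: StagingResult = ctx["staging"]
    kept = [counts.cell_ids.index(c) for c in staging.retained_cells]
    sub = counts.values[:, kept]
    from .io import CountMatrix

    retained_counts = CountMatrix(sub, counts.gene_ids, staging.retained_cells)
    expressed = de_expressed_filter(retained_counts, cfg["min_umis"], cfg["min_cells"])
    genes = sorted(expressed | (ctx["gene_sets"].keratinocyte_genes & set(counts.gene_ids)))
    log_cpm = normalize_log_cpm_frame(retained_counts).loc[genes]
    de = moderated_de(
        log_cpm,
        _state_map(ctx),
        trend=cfg["trend"],
        alpha=cfg["alpha"],
        lfc_threshold=cfg["lfc_threshold"],
    )
    ctx["de"] = de
    d = outdir / "de"
    d.mkdir(parents=True, exist_ok=True)
    de.drop(columns="gene").to_csv(d / "de.tsv", sep="\t")


def _load_de(ctx: dict, outdir: Path) -> None:
    ctx["de"] = pd.read_csv(outdir / "de/de.tsv", sep="\t", index_col=0)


def _run_trajectories(ctx: dict, outdir: Path) -> None:
    cfg = ctx["config"]["trajectories"]
    staging: StagingResult = ctx["staging"]
    K = staging.stages.K
    trajectory_stages = list(range(1, K))  # stages 1..K-1: the differentiation axis
    profile = stage_profile(
        staging.imputed_cpm.to_numpy(),
        list(staging.imputed_cpm.index),
        staging.stages,
        stage_subset=trajectory_stages,
    )
    ctx["trajectory_profile"] = profile

    kera_tfs = sorted(ctx["gene_sets"].keratinocyte_tfs & set(profile.mean_expr.index))
    dynamic_tfs = sorted(set(kera_tfs) & dynamic_gene_filter(profile, cfg["min_lfc"]))
    if len(dynamic_tfs) < cfg["n_tf_clusters"]:
        raise ConfigurationError("too few dynamic TFs for branch clustering")
    tf_cl = cluster_trajectories(profile, dynamic_tfs, cfg["n_tf_clusters"])
    peak_of = {t: peak_stage(profile, t)[0] for t in dynamic_tfs}
    mean_peak = {
        c: float(np.mean([peak_of[t] for t in tf_cl.members(c)]))
        for c in set(tf_cl.labels.values())
    }
    bk_cluster = min(mean_peak, key=lambda c: (mean_peak[c], c))
    branch_of = {
        t: ("BK_branch" if c == bk_cluster else "DK_branch") for t, c in tf_cl.labels.items()
    }
    ctx.update(tf_clustering=tf_cl, tf_branches=branch_of)

    aox = sorted(set(ctx["antioxidant_genes"]) & set(profile.mean_expr.index))
    aox_dynamic = sorted(set(aox) & dynamic_gene_filter(profile, cfg["antioxidant_min_lfc"]))
    aox_result: dict = {"n_dynamic": len(aox_dynamic)}
    aox_labels: dict[str, int] = {}
    if len(aox_dynamic) >= max(cfg["antioxidant_n_clusters"], 2):
        aox_cl = cluster_trajectories(profile, aox_dynamic, cfg["antioxidant_n_clusters"])
        aox_labels = dict(aox_cl.labels)
        sizes = aox_cl.sizes()
        largest = max(sizes, key=lambda c: (sizes[c], -c))
        k, n, p = cluster_size_enrichment(aox_cl, largest)
        peak_stages = {
            c: float(np.mean([peak_stage(profile, g)[0] for g in aox_cl.members(c)]))
            for c in sizes
        }
        aox_result.update(
            largest_cluster=largest,
            largest_cluster_size=k,
            n_clustered=n,
            p_value=p,
            cluster_mean_peak_stage=peak_stages,
        )
    ctx["antioxidant_enrichment"] = aox_result

    d = outdir / "trajectories"
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "tf": dynamic_tfs,
            "cluster": [tf_cl.labels[t] for t in dynamic_tfs],
            "branch": [branch_of[t] for t in dynamic_tfs],
            "peak_stage": [peak_of[t] for t in dynamic_tfs],
        }
    ).to_csv(d / "tf_branches.tsv", sep="\t", index=False)
    (d / "tf_linkage.txt").write_text(linkage_to_bracket(tf_cl) + "\n")
    pd.DataFrame(
        {"gene": sorted(aox_labels), "cluster": [aox_labels[g] for g in sorted(aox_labels)]}
    ).to_csv(d / "antioxidant_clusters.tsv", sep="\t", index=False)
    write_json(aox_result, d / "antioxidant_enrichment.json")


def _load_trajectories(ctx: dict, outdir: Path) -> None:
    d = outdir / "trajectories"
    tb = pd.read_csv(d / "tf_branches.tsv", sep="\t")
    ctx["tf_branches"] = dict(zip(tb["tf"].astype(str), tb["branch"].astype(str)))
    ctx["antioxidant_enrichment"] = read_json(d / "antioxidant_enrichment.json")
    staging: StagingResult = ctx["staging"]
    ctx["trajectory_profile"] = stage_profile(
        staging.imputed_cpm.to_numpy(),
        list(staging.imputed_cpm.index),
        staging.stages,
        stage_subset=list(range(1, staging.stages.K)),
    )


def _run_motifs(ctx: dict, outdir: Path) -> None:
    cfg = ctx["config"]["motifs"]
    table, counts = enrichment_table(
        ctx["se"],
        ctx["pwms"],
        score_threshold_pvalue=cfg["scan_p"],
        alpha=cfg["alpha"],
        min_regions=cfg["min_regions"],
    )
    ctx["enrichment"] = table
    magnitudes = dict(zip(table.index, table["signed_magnitude"]))
    significant = set(table.index[table["direction"] != "none"])
    try:
        p = concordance_test(
            ctx["tf_branches"],
            magnitudes,
            restrict_to_significant=cfg["restrict_concordance"],
            significant=significant,
        )
    except ConfigurationError:
        p = float("nan")
    ctx["concordance_p"] = p
    d = outdir / "motifs"
    d.mkdir(parents=True, exist_ok=True)
    table.drop(columns="tf").to_csv(d / "motif_enrichment.tsv", sep="\t")
    counts.to_csv(d / "motif_counts.tsv", sep="\t")
    write_json({"concordance_p": p, "n_significant": len(significant)}, d / "concordance.json")


def _load_motifs(ctx: dict, outdir: Path) -> None:
    d = outdir / "motifs"
    ctx["enrichment"] = pd.read_csv(d / "motif_enrichment.tsv", sep="\t", index_col=0)
    ctx["concordance_p"] = read_json(d / "concordance.json")["concordance_p"]


def _run_network(ctx: dict, outdir: Path) -> None:
    cfg = ctx["config"]["network"]
    sim_cfg: SimulationConfig = ctx["sim_config"]
    bk_lo, bk_hi = sim_cfg.bk_stage_range
    dk_lo, dk_hi = sim_cfg.dk_stage_range
    mitotic = bk_hi + 1  # transition stage bridging the two states
    d = outdir / "network"
    d.mkdir(parents=True, exist_ok=True)
    thresholds = {}
    for state, stages_used in (("BK", (bk_lo, mitotic)), ("DK", (mitotic, dk_hi))):
        net = build_state_network(
            state,
            ctx["staging"],
            ctx["enrichment"],
            ctx["de"],
            ctx["gene_sets"],
            beta=cfg["beta"],
            n_tf_modules=cfg["n_tf_modules"],
            n_gene_modules=cfg["n_gene_modules"],
            threshold=cfg["threshold"],
            null_quantile=cfg["null_quantile"],
            n_permutations=cfg["n_permutations"],
            bk_stages=(bk_lo, mitotic),
            dk_stages=(mitotic, dk_hi),
            seed=substream_seed(ctx["seed"], f"network_{state}"),
        )
        ctx[f"network_{state}"] = net
        thresholds[state] = net.threshold
        net.edges.to_csv(d / f"{state}_edges.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(net.modules.tf_modules.items()), columns=["tf", "module"]
        ).to_csv(d / f"{state}_tf_modules.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(net.modules.gene_modules.items()), columns=["gene", "module"]
        ).to_csv(d / f"{state}_gene_modules.tsv", sep="\t", index=False)
        net.sim.s.round(6).to_csv(d / f"{state}_similarity.tsv", sep="\t")
        edges_to_graphml(net, d / f"{state}_modules.graphml")
    write_json(thresholds, d / "thresholds.json")


def _load_network(ctx: dict, outdir: Path) -> None:
    # module networks are terminal outputs; nothing downstream needs them
    d = outdir / "network"
    for state in ("BK", "DK"):
        ctx[f"network_{state}_edges"] = pd.read_csv(d / f"{state}_edges.tsv", sep="\t")


def _run_prioritize(ctx: dict, outdir: Path) -> None:
    cfg = ctx["config"]["prioritize"]
    staging: StagingResult = ctx["staging"]
    K = staging.stages.K
    traj_mask = staging.stages.cells_in(range(1, K))
    gene_sets: GeneSets = ctx["gene_sets"]
    candidates = sorted(gene_sets.candidate_tfs & set(staging.log_imputed.index))
    scores = []
    for tf in candidates:
        targets = identify_targets(
            staging.log_imputed,
            traj_mask,
            tf,
            gene_sets.keratinocyte_genes - {tf},
            min_abs_r=cfg["min_abs_r"],
        )
        targets = [t for t in targets if t.gene in ctx["de"].index]
        scores.append(differentiation_score(tf, targets, ctx["de"]))
    ranking = rank_candidates(scores, ctx["culture_fpkm"], min_fpkm=cfg["min_fpkm"])
    ctx.update(dp_scores=scores, ranking=ranking)
    d = outdir / "prioritize"
    d.mkdir(parents=True, exist_ok=True)
    ranking.to_csv(d / "ranking.tsv", sep="\t")
    target_audit_frame(scores).to_csv(d / "target_audit.tsv", sep="\t", index=False)


def _load_prioritize(ctx: dict, outdir: Path) -> None:
    ctx["ranking"] = pd.read_csv(outdir / "prioritize/ranking.tsv", sep="\t", index_col=0)


_RUNNERS = {
    "simulate": (_run_simulate, _load_simulate),
    "stage": (_run_stage, _load_stage),
    "specificity": (_run_specificity, _load_specificity),
    "de": (_run_de, _load_de),
    "trajectories": (_run_trajectories, _load_trajectories),
    "motifs": (_run_motifs, _load_motifs),
    "network": (_run_network, _load_network),
    "prioritize": (_run_prioritize, _load_prioritize),
}


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path = "keranet_run",
    seed: int | None = None,
    resume: bool = False,
    stages: list[str] | None = None,
) -> dict:
    """Run the pipeline end to end and return the run manifest.

    ``config`` is a (possibly partial) override of :data:`DEFAULT_CONFIG`;
    ``seed`` overrides the config's root seed.  With ``resume=True`` stages
    whose outputs already exist are loaded instead of recomputed.  ``stages``
    restricts execution to a prefix-closed subset of the stage order (earlier
    stages are loaded or computed as needed).
    """
    cfg = merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"config": cfg, "seed": int(cfg["seed"])}
    wanted = stages or STAGE_ORDER
    layout = _stage_outputs(outdir)
    manifest: dict = {
        "package_version": __version__,
        "config": cfg,
        "seed": ctx["seed"],
        "stages": {},
        "outputs": {},
    }
    for name in STAGE_ORDER:
        run_fn, load_fn = _RUNNERS[name]
        outputs = layout[name]
        have_all = all(p.exists() for p in outputs)
        t0 = time.time()
        if resume and have_all:
            load_fn(ctx, outdir)
            action = "loaded"
        else:
            run_fn(ctx, outdir)
            action = "computed"
        manifest["stages"][name] = {
            "action": action,
            "wall_clock_s": round(time.time() - t0, 3),
        }
        manifest["outputs"][name] = {
            str(p.relative_to(outdir)): _sha256(p) for p in outputs if p.exists()
        }
        if name == wanted[-1] and name != STAGE_ORDER[-1]:
            break
    write_json(manifest, outdir / "manifest.json")
    return manifest
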