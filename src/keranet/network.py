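"""Signed soft-thresholded TF-gene similarity and module-level networks.

The similarity between TF *i* and gene *j* over a stage-restricted cell set
is the sign-preserving soft-thresholded Pearson correlation
``S_ij = sign(r_ij) * |r_ij|^beta`` (beta = 6 by default, the conventional
power for signed coexpression networks).  TFs are clustered on their per-cell
expression, genes on their rows of S (their TF-correlation profiles), and a
regulatory edge connects a TF module A to a gene module B when
``|mean_{i in A, j in B} S_ij|`` exceeds a threshold — by default the 95th
percentile of a gene-label permutation null.  The BK network restricts cells
to the basal stages and TFs to those with BK-enriched motifs; the DK network
mirrors it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cluster import CorrClustering, corr_cluster
from .io import ConfigurationError
from .screen import GeneSets
from .staging import StagingResult


@dataclass
class SimilarityMatrix:
    """TF x gene signed soft-thresholded Pearson similarities in [-1, 1]."""

    s: pd.DataFrame  # TFs x genes
    beta: float
    stage_range: tuple[int, int]

    def __post_init__(self) -> None:
        if np.any(np.abs(self.s.to_numpy()) > 1 + 1e-12):
            raise ConfigurationError("similarities must lie in [-1, 1]")

    @property
    def tfs(self) -> list[str]:
        return list(self.s.index)

    @property
    def genes(self) -> list[str]:
        return list(self.s.columns)


@dataclass
class ModuleSet:
    """TF -> module id and gene -> module id partitions with provenance."""

    tf_modules: dict[str, int]
    gene_modules: dict[str, int]
    tf_clustering: CorrClustering | None = None
    gene_clustering: CorrClustering | None = None
    flagged_genes: set[str] = field(default_factory=set)


def signed_similarity(
    expr: pd.DataFrame,
    tfs: list[str],
    genes: list[str],
    cell_mask: np.ndarray,
    beta: float = 6.0,
    stage_range: tuple[int, int] = (0, 0),
) -> SimilarityMatrix:
    """``S_ij = sign(r_ij) |r_ij|^beta`` over the selected cells.

    ``expr`` is genes x cells log-imputed expression; zero-variance TF or gene
    vectors over the selected cells are an error listing the offenders
    (filter first).
    """
    cells = np.asarray(cell_mask, dtype=bool)
    if cells.sum() < 10:
        raise ConfigurationError("need at least 10 cells for correlation")
    sub = expr.loc[list(tfs) + [g for g in genes if g not in set(tfs)], expr.columns[cells]]
    vals = sub.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    offenders = [str(g) for g, s in zip(sub.index, sd) if s == 0]
    if offenders:
        raise ConfigurationError(f"zero-variance vectors over selected cells: {offenders[:10]}")
    r = np.corrcoef(vals)
    idx = {g: i for i, g in enumerate(sub.index)}
    rows = [idx[t] for t in tfs]
    cols = [idx[g] for g in genes]
    r_tg = np.clip(r[np.ix_(rows, cols)], -1.0, 1.0)
    s = np.sign(r_tg) * np.abs(r_tg) ** beta
    return SimilarityMatrix(pd.DataFrame(s, index=tfs, columns=genes), beta, stage_range)


def cluster_tf_modules(
    expr: pd.DataFrame, tfs: list[str], cell_mask: np.ndarray, n_modules: int
) -> CorrClustering:
    """Cluster TFs on per-cell expression similarity (1 - Pearson, average
    linkage, deterministic lexicographic ordering)."""
    if n_modules > len(tfs):
        raise ConfigurationError("more TF modules requested than TFs")
    cells = np.asarray(cell_mask, dtype=bool)
    frame = expr.loc[sorted(tfs), expr.columns[cells]]
    return corr_cluster(frame, n_modules)


def cluster_gene_modules(sim: SimilarityMatrix, n_modules: int) -> tuple[CorrClustering, set[str]]:
    """Cluster genes on the similarity of their TF-correlation profiles.

    Each gene is represented by its row of S across TFs; distance is
    1 - Pearson between these profiles.  Genes with constant profiles cannot
    enter the correlation distance; they are assigned afterwards to the
    nearest module centroid in Euclidean distance and returned as flagged.
    """
    prof = sim.s.T  # genes x TFs
    if n_modules > len(prof):
        raise ConfigurationError("more gene modules requested than genes")
    sd = prof.to_numpy().std(axis=1)
    constant = set(prof.index[sd == 0])
    usable = prof.loc[[g for g in prof.index if g not in constant]]
    if len(usable) < n_modules:
        raise ConfigurationError("too few non-constant gene profiles for the requested modules")
    cl = corr_cluster(usable, n_modules)
    if constant:
        warnings.warn(
            f"{len(constant)} constant gene profiles assigned by Euclidean fallback",
            stacklevel=2,
        )
        centroids = {}
        for m in range(1, n_modules + 1):
            members = cl.members(m)
            centroids[m] = usable.loc[members].to_numpy().mean(axis=0)
        for g in sorted(constant):
            v = prof.loc[g].to_numpy()
            best = min(centroids, key=lambda m: float(np.linalg.norm(v - centroids[m])))
            cl.labels[g] = best
            cl.item_ids.append(g)
    return cl, constant


def module_edges(
    sim: SimilarityMatrix, modules: ModuleSet, threshold: float
) -> pd.DataFrame:
    """Signed module-level edges by thresholded mean similarity.

    For every (TF module A, gene module B) pair, ``mean_s`` is the mean of
    S_ij over all i in A, j in B; an edge is emitted iff ``|mean_s| >
    threshold``, signed activation/inhibition by the mean's sign.
    """
    S = sim.s
    tf_ids = np.array(sim.tfs)
    gene_ids = np.array(sim.genes)
    tf_lab = np.array([modules.tf_modules[t] for t in tf_ids])
    gene_lab = np.array([modules.gene_modules[g] for g in gene_ids])
    rows = []
    for a in sorted(set(tf_lab.tolist())):
        in_a = tf_lab == a
        for b in sorted(set(gene_lab.tolist())):
            in_b = gene_lab == b
            mean_s = float(S.to_numpy()[np.ix_(in_a, in_b)].mean())
            if abs(mean_s) > threshold:
                rows.append(
                    {
                        "tf_module": a,
                        "gene_module": b,
                        "mean_s": mean_s,
                        "strength": abs(mean_s),
                        "sign": "activation" if mean_s > 0 else "inhibition",
                    }
                )
    return pd.DataFrame(rows, columns=["tf_module", "gene_module", "mean_s", "strength", "sign"])


def edge_threshold_from_null(
    sim: SimilarityMatrix,
    modules: ModuleSet,
    n_permutations: int = 200,
    q_quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Permutation-null threshold for |mean S| over module pairs.

    Gene labels are permuted, all |mean_s| values recomputed and pooled over
    permutations; the threshold is the ``q_quantile`` of the pooled null.
    """
    if n_permutations < 100:
        raise ConfigurationError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    S = sim.s.to_numpy()
    tf_lab = np.array([modules.tf_modules[t] for t in sim.tfs])
    gene_lab = np.array([modules.gene_modules[g] for g in sim.genes])
    tf_groups = [tf_lab == a for a in sorted(set(tf_lab.tolist()))]
    pool = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(gene_lab))
        gl = gene_lab[perm]
        for in_a in tf_groups:
            block = S[in_a]
            for b in sorted(set(gl.tolist())):
                pool.append(abs(float(block[:, gl == b].mean())))
    return float(np.quantile(np.array(pool), q_quantile))


@dataclass
class StateNetwork:
    """One state's network: similarities, modules, edges, and bookkeeping."""

    state: str
    sim: SimilarityMatrix
    modules: ModuleSet
    edges: pd.DataFrame
    threshold: float
    tfs: list[str]
    genes: list[str]


def build_state_network(
    state: str,
    staging: StagingResult,
    enrichment: pd.DataFrame,
    de: pd.DataFrame,
    gene_sets: GeneSets,
    beta: float = 6.0,
    n_tf_modules: int | None = None,
    n_gene_modules: int | None = None,
    threshold: float | None = None,
    null_quantile: float = 0.95,
    n_permutations: int = 200,
    bk_stages: tuple[int, int] = (1, 4),
    dk_stages: tuple[int, int] = (4, 7),
    seed: int = 0,
) -> StateNetwork:
    """Build the BK or DK module network from the upstream artifacts.

    BK: cells in stages ``bk_stages``, TFs with BK-enriched motifs, candidate
    target genes = keratinocyte genes that are not DK-specific (i.e. not
    down-regulated in BK).  DK mirrors it with ``dk_stages``, DK-enriched
    motifs, and exclusion of BK-specific genes.
    """
    if state not in ("BK", "DK"):
        raise ConfigurationError("state must be 'BK' or 'DK'")
    lo, hi = bk_stages if state == "BK" else dk_stages
    cell_mask = staging.stages.cells_in(range(lo, hi + 1))
    expr = staging.log_imputed
    tfs = sorted(
        t
        for t in enrichment.index[enrichment["direction"] == state]
        if t in expr.index and t in gene_sets.keratinocyte_tfs
    )
    if not tfs:
        raise ConfigurationError(f"no TFs with motifs enriched in {state} SEs")
    excluded_state = "DK" if state == "BK" else "BK"
    excluded = set(de.index[de["state_specific"] == excluded_state])
    genes = sorted(
        g for g in gene_sets.keratinocyte_genes if g in expr.index and g not in excluded
    )
    # drop zero-variance vectors over the selected cells up front
    sub = expr.loc[:, expr.columns[np.asarray(cell_mask, dtype=bool)]]
    sd = sub.std(axis=1)
    tfs = [t for t in tfs if sd[t] > 0]
    genes = [g for g in genes if sd[g] > 0]
    if not tfs:
        raise ConfigurationError(f"all {state} TFs are constant over the selected cells")

    sim = signed_similarity(expr, tfs, genes, cell_mask, beta=beta, stage_range=(lo, hi))
    n_tf = n_tf_modules if n_tf_modules is not None else min(13 if state == "BK" else 9, len(tfs))
    n_gene = (
        n_gene_modules if n_gene_modules is not None else min(23 if state == "BK" else 21, len(genes))
    )
    tf_cl = cluster_tf_modules(expr, tfs, cell_mask, n_tf)
    gene_cl, flagged = cluster_gene_modules(sim, n_gene)
    modules = ModuleSet(
        tf_modules=dict(tf_cl.labels),
        gene_modules=dict(gene_cl.labels),
        tf_clustering=tf_cl,
        gene_clustering=gene_cl,
        flagged_genes=flagged,
    )
    thr = (
        threshold
        if threshold is not None
        else edge_threshold_from_null(sim, modules, n_permutations, null_quantile, seed)
    )
    edges = module_edges(sim, modules, thr)
    return StateNetwork(state, sim, modules, edges, thr, tfs, genes)


def edges_to_graphml(net: StateNetwork, path) -> None:
    """Write the module graph (TF modules -> gene modules) as GraphML."""
    import networkx as nx

    G = nx.DiGraph()
    for t, m in sorted(net.modules.tf_modules.items()):
        G.add_node(f"TFmod{m}", kind="tf_module")
    for g, m in sorted(net.modules.gene_modules.items()):
        G.add_node(f"GENEmod{m}", kind="gene_module")
    for _, row in net.edges.iterrows():
        G.add_edge(
            f"TFmod{int(row.tf_module)}",
            f"GENEmod{int(row.gene_module)}",
            mean_s=float(row.mean_s),
            sign=row.sign,
        )
    nx.write_graphml(G, str(path))
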