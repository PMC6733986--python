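"""Trajectory clustering of stage-wise expression profiles.

Genes passing a dynamic-range filter are clustered hierarchically on Pearson
correlation distance between their stage-mean trajectories (the engine shared
with the regulatory-network module); a gene's peak stage separates basal-state
from differentiated-state expressors; and the size of a trajectory cluster
(e.g. the basal-peaking antioxidant cluster) is tested against an
equal-probability exact binomial null.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from ._cluster import CorrClustering, corr_cluster, linkage_to_bracket  # noqa: F401
from .io import ConfigurationError
from .screen import bh_fdr
from .staging import StageProfile

TrajectoryClustering = CorrClustering


def dynamic_gene_filter(profile: StageProfile, min_range_log2fc: float) -> set[str]:
    """Genes whose stage-wise log2 mean range is at least the threshold."""
    M = profile.mean_expr
    rng = M.max(axis=1) - M.min(axis=1)
    return set(M.index[rng >= min_range_log2fc])


def cluster_trajectories(
    profile: StageProfile,
    genes: list[str] | set[str],
    n_clusters: int,
    linkage_method: str = "average",
) -> TrajectoryClustering:
    """Hierarchical clustering of trajectories on 1 - Pearson r.

    Zero-variance trajectories must be filtered out first (they have no
    defined correlation) and raise an error here.
    """
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in profile.mean_expr.index]
    if missing:
        raise ConfigurationError(f"genes absent from profile: {missing[:5]}")
    frame = profile.mean_expr.loc[genes]
    return corr_cluster(frame, n_clusters, linkage_method)


def peak_stage(profile: StageProfile, gene: str) -> tuple[int, bool]:
    """Stage of maximal mean expression; ties take the lowest stage, flagged."""
    if gene not in profile.mean_expr.index:
        raise ConfigurationError(f"gene {gene} not in profile")
    row = profile.mean_expr.loc[gene]
    top = row.max()
    winners = [int(s) for s, v in row.items() if v == top]
    return min(winners), len(winners) > 1


def cluster_size_enrichment(
    clustering: TrajectoryClustering, cluster_id: int, n_clusters: int | None = None
) -> tuple[int, int, float]:
    """Exact binomial upper tail for the size of one trajectory cluster.

    Under the equal-probability null each of the ``n`` clustered genes lands
    in the chosen cluster with probability ``1/n_clusters``; the p-value is
    ``P(X >= k)`` summed directly (exact rational arithmetic, then floated).
    Returns ``(k, n, p)``.
    """
    sizes = clustering.sizes()
    if cluster_id not in sizes:
        raise ConfigurationError(f"no cluster {cluster_id} in clustering")
    m = n_clusters if n_clusters is not None else clustering.n_clusters
    if m < 2:
        raise ConfigurationError("n_clusters must be >= 2 for the enrichment null")
    k = sizes[cluster_id]
    n = len(clustering.item_ids)
    p = binomial_upper_tail(k, n, Fraction(1, m))
    return k, n, p


def binomial_upper_tail(k: int, n: int, prob: Fraction | float) -> float:
    """P(X >= k) for X ~ Binomial(n, prob), by direct exact summation."""
    q = Fraction(prob).limit_denominator(10**9) if not isinstance(prob, Fraction) else prob
    total = Fraction(0)
    for j in range(k, n + 1):
        total += comb(n, j) * q**j * (1 - q) ** (n - j)
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# generic set-enrichment utility (hypergeometric, BH-corrected)


def set_enrichment(
    query: set[str],
    gene_sets: dict[str, list[str] | set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each annotated set.

    All sets are intersected with the ``background`` universe first.  Returns
    a frame with overlap counts, the upper-tail hypergeometric p-value and BH
    q-values across the tested sets.
    """
    from scipy.stats import hypergeom

    q = set(query) & background
    if not q:
        raise ConfigurationError("query has no genes in the background universe")
    rows = []
    N = len(background)
    for name, members in sorted(gene_sets.items()):
        m = set(members) & background
        k = len(q & m)
        p = float(hypergeom.sf(k - 1, N, len(m), len(q))) if m else 1.0
        rows.append(
            {"set": name, "overlap": k, "set_size": len(m), "query_size": len(q), "p_value": p}
        )
    out = pd.DataFrame(rows).set_index("set", drop=False)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out
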