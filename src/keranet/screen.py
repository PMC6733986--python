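"""Cell-type-specificity screen, scRNA expression filters, gene-set assembly,
and moderated two-group differential expression.

The specificity screen mirrors the FANTOM5/CAGE workflow: TSS-level features
are summed to gene level, each gene is tested (two-sided Mann-Whitney U) for
elevated expression in a small target cell-type group against all remaining
primary-cell samples, and selection requires BH FDR < alpha together with a
higher target-group mean.

``moderated_de`` is an empirical-Bayes moderated t for the two-group design
(basal vs differentiated keratinocytes, BK vs DK): per-gene residual
variances are squeezed toward a prior estimated by moment-matching the
distribution of log sample variances (digamma/trigamma equations), optionally
with the prior following a smooth trend in mean log-expression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import BulkExpressionMatrix, ConfigurationError, CountMatrix

# ---------------------------------------------------------------------------
# shared elementary statistics


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U of ``x`` (first sample) with a fixed method policy.

    Exact enumeration when the combined sample size is <= 12 and the pooled
    data are tie-free; otherwise the normal approximation with tie and
    continuity corrections.  The fixed switch keeps results bit-reproducible.
    ``alternative`` follows scipy ("two-sided", "greater", "less").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ConfigurationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        return len(x) * len(y) / 2.0, 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any(np.isnan(p)):
        raise ConfigurationError("NaN p-values passed to BH correction")
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def normalize_log_cpm_frame(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(cpm + pseudocount) of raw counts as a genes x cells DataFrame."""
    from .staging import normalize_log_cpm

    return pd.DataFrame(
        normalize_log_cpm(counts, pseudocount), index=counts.gene_ids, columns=counts.cell_ids
    )


# ---------------------------------------------------------------------------
# bulk screen


def aggregate_features_to_genes(bulk: BulkExpressionMatrix) -> BulkExpressionMatrix:
    """Sum feature rows (e.g. CAGE TSS peaks) onto their annotated genes.

    Unmapped features are dropped; their number is reported via a warning.
    """
    if not bulk.feature_to_gene:
        raise ConfigurationError("feature_to_gene map is empty")
    mapped = [f for f in bulk.feature_ids if f in bulk.feature_to_gene]
    n_dropped = len(bulk.feature_ids) - len(mapped)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} features without gene annotation", stacklevel=2)
    df = bulk.to_frame().loc[mapped]
    genes = pd.Index([bulk.feature_to_gene[f] for f in mapped], name="gene")
    agg = df.groupby(genes, sort=True).sum()
    return BulkExpressionMatrix(
        agg.to_numpy(),
        [str(g) for g in agg.index],
        list(bulk.sample_ids),
        dict(bulk.sample_group),
        None,
    )


def celltype_specific_screen(
    bulk_gene: BulkExpressionMatrix,
    target_group: str,
    alpha: float = 0.05,
    exclude_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene two-sided MWU of the target cell type versus all other samples.

    Returns a frame indexed by gene with u_statistic, p_value, q_value,
    direction (up_in_target / down_in_target) and the boolean ``selected``
    (q < alpha and higher mean in the target group).  ``exclude_samples``
    drops samples (e.g. a non-epidermal replicate of the target type) before
    testing.
    """
    keep = [s for s in bulk_gene.sample_ids if s not in set(exclude_samples or [])]
    groups = np.array([bulk_gene.sample_group[s] for s in keep])
    in_target = groups == target_group
    if in_target.sum() < 2:
        raise ConfigurationError("target group must contain at least 2 samples")
    cols = [bulk_gene.sample_ids.index(s) for s in keep]
    vals = bulk_gene.values[:, cols]
    x = vals[:, in_target]
    y = vals[:, ~in_target]
    # large-n screen: the fixed method policy always lands on the normal
    # approximation here, so the vectorized scipy call is identical
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True, axis=1
        )
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.all(vals == vals[:, [0]], axis=1)
    p[constant | np.isnan(p)] = 1.0
    q = bh_fdr(p)
    up = x.mean(axis=1) > y.mean(axis=1)
    return pd.DataFrame(
        {
            "gene": bulk_gene.feature_ids,
            "u_statistic": np.asarray(res.statistic, dtype=float),
            "p_value": p,
            "q_value": q,
            "direction": np.where(up, "up_in_target", "down_in_target"),
            "selected": (q < alpha) & up,
        }
    ).set_index("gene", drop=False)


# ---------------------------------------------------------------------------
# scRNA-seq expression filters


def scrna_expression_filter(
    counts: CountMatrix, min_umis: int = 1, min_cell_fraction: float = 0.01
) -> set[str]:
    """Genes with >= ``min_umis`` raw UMIs in >= ceil(fraction * n_cells) cells."""
    n_needed = math.ceil(min_cell_fraction * counts.n_cells)
    n_ok = (counts.values >= min_umis).sum(axis=1)
    return {g for g, n in zip(counts.gene_ids, n_ok) if n >= n_needed}


def de_expressed_filter(counts: CountMatrix, min_umis: int = 3, min_cells: int = 20) -> set[str]:
    """Genes with >= ``min_umis`` raw UMIs in at least ``min_cells`` cells."""
    n_ok = (counts.values >= min_umis).sum(axis=1)
    return {g for g, n in zip(counts.gene_ids, n_ok) if n >= min_cells}


# ---------------------------------------------------------------------------
# gene-set assembly


@dataclass
class GeneSets:
    """The analysis gene sets and their defining set algebra.

    ``keratinocyte_tfs = fantom_tfs | curated_tfs``;
    ``candidate_tfs = fantom_tfs - curated_tfs`` (the prioritization focus);
    ``keratinocyte_genes = keratinocyte_tfs | fantom_genes``.
    """

    fantom_genes: set[str]
    fantom_tfs: set[str]
    curated_tfs: set[str]
    manual_additions: set[str] = field(default_factory=set)

    @property
    def keratinocyte_tfs(self) -> set[str]:
        return self.fantom_tfs | self.curated_tfs

    @property
    def candidate_tfs(self) -> set[str]:
        return self.fantom_tfs - self.curated_tfs

    @property
    def keratinocyte_genes(self) -> set[str]:
        return self.keratinocyte_tfs | self.fantom_genes

    def to_dict(self) -> dict[str, list[str]]:
        return {
            "fantom_genes": sorted(self.fantom_genes),
            "fantom_tfs": sorted(self.fantom_tfs),
            "curated_tfs": sorted(self.curated_tfs),
            "manual_additions": sorted(self.manual_additions),
            "keratinocyte_tfs": sorted(self.keratinocyte_tfs),
            "candidate_tfs": sorted(self.candidate_tfs),
            "keratinocyte_genes": sorted(self.keratinocyte_genes),
        }


def assemble_gene_sets(
    screen_tfs: set[str],
    screen_genes: set[str],
    curated_tfs: set[str],
    manual_additions: set[str] | None = None,
    expressed_genes: set[str] | None = None,
) -> GeneSets:
    """Assemble the analysis gene sets.

    ``screen_tfs``/``screen_genes`` are the specificity-screen survivors split
    by a TF annotation list; ``curated_tfs`` the literature regulators (also
    subject to the expression filter when ``expressed_genes`` is given);
    ``manual_additions`` are appended to the screen TFs with provenance kept.
    Additions absent from ``expressed_genes`` are kept with a warning.
    """
    manual = set(manual_additions or set())
    if expressed_genes is not None:
        missing = manual - expressed_genes
        if missing:
            warnings.warn(
                f"manual additions not in the expressed-gene universe: {sorted(missing)}",
                stacklevel=2,
            )
        curated_tfs = curated_tfs & expressed_genes
    return GeneSets(
        fantom_genes=set(screen_genes),
        fantom_tfs=set(screen_tfs) | manual,
        curated_tfs=set(curated_tfs),
        manual_additions=manual,
    )


# ---------------------------------------------------------------------------
# moderated two-group differential expression


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def fit_variance_prior(
    s2: np.ndarray, df: float, covariate: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Moment-match a scaled-F prior for gene-wise sample variances.

    Under the hierarchical model ``s2_g ~ s0^2 * F(df, d0)`` the statistic
    ``e_g = log s2_g - digamma(df/2) + log(df/2)`` has mean
    ``log s0^2 - digamma(d0/2) + log(d0/2)`` and variance
    ``trigamma(df/2) + trigamma(d0/2)``; ``d0`` and ``s0^2`` follow from the
    empirical mean and variance of ``e``.  With a covariate (mean
    log-expression), the prior follows a lowess trend fitted to ``e``.

    Returns ``(d0, s0_sq)`` with ``s0_sq`` per gene (constant without trend);
    ``d0 = inf`` signals a near-constant variance distribution (pooled prior).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ConfigurationError("need at least two positive gene variances")
    e = np.full(len(s2), np.nan)
    e[ok] = np.log(s2[ok]) - special.digamma(df / 2.0) + math.log(df / 2.0)
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        sm = lowess(e[ok], cov[ok], frac=0.5, it=3, return_sorted=False)
        e_center = np.full(len(s2), np.nan)
        e_center[ok] = sm
        # extend the trend to zero-variance genes via nearest covariate value
        if (~ok).any():
            order = np.argsort(cov[ok])
            xs = cov[ok][order]
            ys = sm[order]
            e_center[~ok] = np.interp(cov[~ok], xs, ys)
        resid_var = float(np.var(e[ok] - e_center[ok], ddof=1))
    else:
        e_center = np.full(len(s2), float(np.nanmean(e)))
        resid_var = float(np.var(e[ok], ddof=1))
    evar = resid_var - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        warnings.warn("variance distribution is near-constant; using pooled prior", stacklevel=2)
        return math.inf, np.exp(e_center)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(e_center + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_sq


def squeeze_variances(s2: np.ndarray, df: float, d0: float, s0_sq: np.ndarray) -> np.ndarray:
    """Posterior variances ``(d0*s0^2 + df*s2) / (d0 + df)`` (prior alone if d0 = inf)."""
    s0_sq = np.broadcast_to(np.asarray(s0_sq, dtype=float), np.shape(s2))
    if math.isinf(d0):
        return s0_sq.copy()
    return (d0 * s0_sq + df * np.asarray(s2, dtype=float)) / (d0 + df)


def moderated_de(
    log_cpm: pd.DataFrame,
    state: dict[str, str],
    trend: bool = True,
    alpha: float = 0.05,
    lfc_threshold: float = 0.25,
) -> pd.DataFrame:
    """Moderated DK-vs-BK differential expression on log2(cpm + 1) values.

    ``log_cpm`` is genes x cells; ``state`` maps each cell to "BK" or "DK"
    (cells mapped to other labels are ignored).  Returns a frame indexed by
    gene with logfc (DK - BK), t_mod, p_value, q_value, and state_specific in
    {"BK", "DK", "none"}: a gene is state-specific when q < alpha and
    |logfc| > lfc_threshold, on the side of its fold change.
    """
    cells = [c for c in log_cpm.columns if state.get(c) in ("BK", "DK")]
    labels = np.array([state[c] for c in cells])
    n_bk = int(np.sum(labels == "BK"))
    n_dk = int(np.sum(labels == "DK"))
    if n_bk < 2 or n_dk < 2:
        raise ConfigurationError("each state needs at least 2 cells")
    x = log_cpm[cells].to_numpy(dtype=float)
    bk = x[:, labels == "BK"]
    dk = x[:, labels == "DK"]
    mean_bk = bk.mean(axis=1)
    mean_dk = dk.mean(axis=1)
    logfc = mean_dk - mean_bk
    df = n_bk + n_dk - 2
    rss = ((bk - mean_bk[:, None]) ** 2).sum(axis=1) + ((dk - mean_dk[:, None]) ** 2).sum(axis=1)
    s2 = rss / df
    a_mean = x.mean(axis=1)
    d0, s0_sq = fit_variance_prior(s2, df, covariate=a_mean if trend else None)
    s2_post = squeeze_variances(s2, df, d0, s0_sq)
    se = np.sqrt(s2_post * (1.0 / n_bk + 1.0 / n_dk))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = logfc / se
    df_total = df if math.isinf(d0) else d0 + df
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_fdr(p)
    specific = np.where(
        (q < alpha) & (logfc > lfc_threshold),
        "DK",
        np.where((q < alpha) & (logfc < -lfc_threshold), "BK", "none"),
    )
    return pd.DataFrame(
        {
            "gene": list(log_cpm.index),
            "logfc": logfc,
            "t_mod": t_mod,
            "p_value": p,
            "q_value": q,
            "state_specific": specific,
            "mean_log_cpm": a_mean,
            "s2": s2,
            "s2_post": s2_post,
        }
    ).set_index("gene", drop=False)
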