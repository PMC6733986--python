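"""Normalization, diffusion imputation and stage assignment for single cells.

The staging workflow: log2(cpm + 1) normalization; PCA embedding; a cell-cell
Markov diffusion operator on the symmetrized kNN graph with adaptive Gaussian
bandwidths (the imputation scheme popularized by MAGIC); k-means-based
approximate spectral clustering into K differentiation stages; per-stage
outlier removal by a median + c*MAD distance rule; re-imputation with a
reduced diffusion time; and stage-wise mean expression profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ConfigurationError, CountMatrix


def normalize_log_cpm(
    counts: CountMatrix | np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """log2(1e6 * count / column_sum + pseudocount), per cell.

    A cell with zero total counts is a degenerate input and raises an error
    naming the cell.
    """
    if isinstance(counts, CountMatrix):
        values = counts.values
        cell_ids = counts.cell_ids
    else:
        values = np.asarray(counts)
        cell_ids = [str(i) for i in range(values.shape[1])]
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be positive")
    colsum = values.sum(axis=0)
    zero = np.nonzero(colsum == 0)[0]
    if len(zero):
        raise ConfigurationError(
            f"cells with zero total counts: {[cell_ids[i] for i in zero[:5]]}"
        )
    return np.log2(1e6 * values / colsum + pseudocount)


def cpm(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Counts per million (no log); errors on all-zero cells."""
    values = counts.values if isinstance(counts, CountMatrix) else np.asarray(counts)
    colsum = values.sum(axis=0)
    if np.any(colsum == 0):
        raise ConfigurationError("cells with zero total counts")
    return 1e6 * values / colsum


def pca_embedding(expr: np.ndarray, n_components: int = 30, seed: int = 0) -> np.ndarray:
    """Cells x d PCA embedding of a genes x cells expression matrix."""
    X = np.asarray(expr, dtype=float).T
    d = min(n_components, X.shape[0] - 1, X.shape[1])
    return PCA(n_components=d, svd_solver="full", random_state=seed).fit_transform(X)


# ---------------------------------------------------------------------------
# diffusion operator


@dataclass
class DiffusionOperator:
    """Row-stochastic cell-cell Markov matrix on the symmetrized kNN graph."""

    matrix: scipy.sparse.csr_matrix
    k_neighbors: int
    ka_adaptive: int
    t: int = 0  # default diffusion time used by callers that do not override

    def __post_init__(self) -> None:
        rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
        if np.max(np.abs(rowsum - 1.0)) > 1e-10:
            raise ConfigurationError("diffusion operator rows must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


def build_diffusion_operator(
    embedding: np.ndarray, k_neighbors: int = 30, ka_adaptive: int = 10
) -> DiffusionOperator:
    """Adaptive-bandwidth Gaussian kernel on the kNN graph, symmetrized and
    row-normalized.

    Affinity ``a(i, j) = exp(-(d(i, j) / sigma_i)^2)`` for ``j`` among the k
    nearest neighbors of ``i`` (self included with affinity 1), with
    ``sigma_i`` the distance to the ka-th nearest neighbor.  ``A`` is then
    symmetrized as ``(A + A^T) / 2`` and row-normalized to a Markov matrix.
    Duplicate points that make ``sigma_i = 0`` fall back to the global median
    of positive neighbor distances.
    """
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if k_neighbors >= n:
        raise ConfigurationError("k_neighbors must be smaller than the number of cells")
    if ka_adaptive > k_neighbors:
        raise ConfigurationError("ka_adaptive must be <= k_neighbors")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    dist, idx = nn.kneighbors(X)  # includes self at distance 0
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self column
    sigma = dist[:, ka_adaptive - 1].copy()
    if np.any(sigma == 0):
        positive = dist[dist > 0]
        fallback = float(np.median(positive)) if len(positive) else 1.0
        sigma[sigma == 0] = fallback
    aff = np.exp(-((dist / sigma[:, None]) ** 2))
    rows = np.repeat(np.arange(n), k_neighbors)
    A = scipy.sparse.coo_matrix((aff.ravel(), (rows, idx.ravel())), shape=(n, n)).tocsr()
    A = A + scipy.sparse.identity(n, format="csr")  # self-affinity exp(0) = 1
    A = (A + A.T) / 2.0
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    M = scipy.sparse.diags(1.0 / rowsum) @ A
    return DiffusionOperator(M.tocsr(), k_neighbors, ka_adaptive)


def impute(expr: np.ndarray, op: DiffusionOperator, t: int) -> np.ndarray:
    """t-step diffusion averaging over cells: ``expr @ (M^T)^t``; t = 0 is the
    identity."""
    if t < 0:
        raise ConfigurationError("diffusion time t must be non-negative")
    Y = np.asarray(expr, dtype=float)
    if Y.shape[1] != op.n_cells:
        raise ConfigurationError("expression matrix and operator cover different cells")
    MT = op.matrix.T.tocsr()
    for _ in range(t):
        Y = Y @ MT
    return np.asarray(Y)


# ---------------------------------------------------------------------------
# approximate spectral clustering


@dataclass
class StageAssignment:
    """Per-cell stage labels in 1..K plus the nearest-representative index."""

    labels: np.ndarray  # (n_cells,) ints in 1..K
    K: int
    representative_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if np.any((self.labels < 1) | (self.labels > self.K)):
            raise ConfigurationError("stage labels must lie in 1..K")

    def cells_in(self, stages) -> np.ndarray:
        stages = {stages} if np.isscalar(stages) else set(stages)
        return np.isin(self.labels, sorted(stages))


def _first_principal_axis(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ vt[0]


def _spectral_embed(affinity: np.ndarray, K: int) -> np.ndarray:
    """Rows of the top-K eigenvectors of D^-1/2 A D^-1/2, unit-normalized."""
    d = affinity.sum(axis=1)
    d_inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
    M = affinity * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    n = M.shape[0]
    _, vecs = eigh(M, subset_by_index=(max(0, n - K), n - 1))
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    return vecs / norms[:, None]


def approx_spectral_cluster(
    embedding: np.ndarray,
    m_representatives: int,
    K: int,
    seed: int = 0,
) -> StageAssignment:
    """k-means-based approximate spectral clustering into K stages.

    Steps: k-means with m centers; Gaussian affinity among centers with
    bandwidth = median pairwise center distance (zero diagonal); symmetric
    normalized Laplacian; row-normalized top-K eigenvector embedding; k-means
    into K clusters; each cell inherits its nearest center's cluster.  With
    ``m_representatives == n_cells`` the representative step is skipped and
    the result is plain normalized spectral clustering on all cells.  Labels
    are relabelled 1..K by increasing cluster mean along the first principal
    axis of the embedding.  A disconnected center affinity graph is clustered
    per connected component with a warning.
    """
    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if not (K <= m_representatives <= n):
        raise ConfigurationError("need K <= m_representatives <= n_cells")
    if m_representatives < n:
        km = KMeans(n_clusters=m_representatives, random_state=seed, n_init=10).fit(X)
        centers = km.cluster_centers_
        cell_to_center = km.labels_
    else:
        centers = X
        cell_to_center = np.arange(n)

    diff = centers[:, None, :] - centers[None, :, :]
    D = np.sqrt((diff**2).sum(axis=-1))
    off = D[~np.eye(len(centers), dtype=bool)]
    sigma = float(np.median(off)) if len(off) and np.median(off) > 0 else 1.0
    A = np.exp(-((D / sigma) ** 2))
    np.fill_diagonal(A, 0.0)

    n_comp, comp = connected_components(scipy.sparse.csr_matrix(A > 0), directed=False)
    center_labels = np.zeros(len(centers), dtype=int)
    if n_comp > 1:
        warnings.warn(
            f"center affinity graph has {n_comp} components; clustering each separately",
            stacklevel=2,
        )
        sizes = np.bincount(comp, minlength=n_comp)
        k_alloc = np.maximum(1, np.round(K * sizes / sizes.sum()).astype(int))
        while k_alloc.sum() > K:
            k_alloc[np.argmax(k_alloc)] -= 1
        while k_alloc.sum() < K:
            k_alloc[np.argmax(sizes - k_alloc)] += 1
        next_label = 0
        for ci in range(n_comp):
            mask = comp == ci
            k_i = min(int(k_alloc[ci]), int(mask.sum()))
            emb = _spectral_embed(A[np.ix_(mask, mask)], k_i)
            lab = KMeans(n_clusters=k_i, random_state=seed, n_init=10).fit_predict(emb)
            center_labels[mask] = lab + next_label
            next_label += k_i
    else:
        emb = _spectral_embed(A, K)
        center_labels = KMeans(n_clusters=K, random_state=seed, n_init=10).fit_predict(emb)

    labels0 = center_labels[cell_to_center]
    axis = _first_principal_axis(X)
    order = np.argsort(
        [axis[labels0 == k].mean() if np.any(labels0 == k) else np.inf for k in range(K)]
    )
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(1, K + 1)
    return StageAssignment(relabel[labels0], K, representative_index=cell_to_center)


# ---------------------------------------------------------------------------
# outlier removal and stage profiles


def remove_outliers(
    embedding: np.ndarray, stages: StageAssignment, c_mad: float = 3.0
) -> np.ndarray:
    """Boolean mask of retained cells.

    Within each stage, a cell is flagged when its distance to the stage
    centroid strictly exceeds ``median + c_mad * MAD`` of the stage's
    distances (raw MAD, no consistency constant).  Stages of size < 5 are
    skipped with a warning; removing more than half of a stage is an error.
    """
    X = np.asarray(embedding, dtype=float)
    if len(X) != len(stages.labels):
        raise ConfigurationError("embedding and stage assignment cover different cells")
    keep = np.ones(len(X), dtype=bool)
    for k in range(1, stages.K + 1):
        members = np.nonzero(stages.labels == k)[0]
        if len(members) == 0:
            continue
        if len(members) < 5:
            warnings.warn(f"stage {k} has fewer than 5 cells; outlier step skipped", stacklevel=2)
            continue
        d = np.linalg.norm(X[members] - X[members].mean(axis=0), axis=1)
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        cutoff = med + c_mad * mad
        out = d > cutoff
        if out.sum() > 0.5 * len(members):
            raise ConfigurationError(f"outlier rule would remove >50% of stage {k}")
        keep[members[out]] = False
    return keep


@dataclass
class StageProfile:
    """Per-gene stage-wise mean imputed expression and its normalized form."""

    mean_expr: pd.DataFrame  # genes x stages, log2(mean cpm + 1)
    normalized: pd.DataFrame  # per-gene normalization across stages
    constant_genes: set[str] = field(default_factory=set)
    normalization: str = "zscore"

    @property
    def stages(self) -> list[int]:
        return [int(c) for c in self.mean_expr.columns]


def stage_profile(
    imputed_cpm: np.ndarray,
    gene_ids: list[str],
    stages: StageAssignment,
    stage_subset: list[int] | None = None,
    normalization: str = "zscore",
) -> StageProfile:
    """Stage-wise mean of imputed cpm, log-transformed and row-normalized.

    ``mean_expr[g, s] = log2(mean over cells in stage s of imputed cpm + 1)``;
    ``normalized`` z-scores each gene across the included stages (population
    SD), or min-max scales with ``normalization='minmax'``.  Genes constant
    across stages map to all-zero rows and are flagged in
    ``constant_genes``.
    """
    vals = np.asarray(imputed_cpm, dtype=float)
    subset = sorted(stage_subset) if stage_subset is not None else list(range(1, stages.K + 1))
    cols = {}
    for s in subset:
        members = stages.labels == s
        if not members.any():
            raise ConfigurationError(f"stage {s} is empty in the requested subset")
        cols[s] = np.log2(vals[:, members].mean(axis=1) + 1.0)
    mean_expr = pd.DataFrame(cols, index=gene_ids)
    M = mean_expr.to_numpy()
    tol = 1e-10  # numerically-constant rows count as constant
    if normalization == "zscore":
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        flat = sd.ravel() <= tol * np.maximum(1.0, np.abs(mu.ravel()))
        sd[sd == 0] = 1.0
        norm = (M - mu) / sd
        norm[flat] = 0.0
    elif normalization == "minmax":
        lo = M.min(axis=1, keepdims=True)
        hi = M.max(axis=1, keepdims=True)
        rng = hi - lo
        flat = rng.ravel() <= tol * np.maximum(1.0, np.abs(hi.ravel()))
        rng[rng == 0] = 1.0
        norm = (M - lo) / rng
        norm[flat] = 0.0
    else:
        raise ConfigurationError(f"unknown normalization: {normalization}")
    constant = {g for g, f in zip(gene_ids, flat) if f}
    return StageProfile(
        mean_expr,
        pd.DataFrame(norm, index=gene_ids, columns=mean_expr.columns),
        constant,
        normalization,
    )


def orient_stages(
    labels: np.ndarray, K: int, peak_stage_of: dict[str, int], basal_weight: dict[str, float]
) -> tuple[np.ndarray, bool]:
    """Orient stage labels so that basal-anchored genes peak early.

    The first-principal-axis ordering fixes the stage sequence only up to
    direction.  ``basal_weight`` carries prior evidence that a gene belongs
    to the undifferentiated end (e.g. log expression in proliferating
    keratinocyte culture); if the weighted mean peak stage of those genes
    falls in the upper half of the stage range, all labels are flipped
    ``s -> K + 1 - s``.  Returns ``(labels, flipped)``.
    """
    genes = [g for g in basal_weight if g in peak_stage_of]
    if not genes:
        return labels, False
    w = np.array([max(basal_weight[g], 0.0) for g in genes])
    if w.sum() == 0:
        return labels, False
    peaks = np.array([peak_stage_of[g] for g in genes], dtype=float)
    flipped = float(np.average(peaks, weights=w)) > (K + 1) / 2.0
    if flipped:
        labels = K + 1 - np.asarray(labels, dtype=int)
    return labels, bool(flipped)


# ---------------------------------------------------------------------------
# full staging sub-pipeline


@dataclass
class StagingResult:
    """Everything downstream stages need from the staging workflow."""

    retained_cells: list[str]
    stages: StageAssignment  # over retained cells
    imputed_cpm: pd.DataFrame  # genes x retained cells, reimputed
    log_imputed: pd.DataFrame  # log2(imputed cpm + 1)
    profile: StageProfile
    embedding: np.ndarray  # retained cells x d
    mask: np.ndarray  # over all_cells (lexicographic cell order)
    first_pass_stages: StageAssignment
    all_cells: list[str] = field(default_factory=list)


def stage_cells(
    counts: CountMatrix,
    n_stages: int = 8,
    n_pcs: int = 30,
    k_neighbors: int = 30,
    ka_adaptive: int = 10,
    t_impute: int = 6,
    t_reimpute: int = 1,
    k_reimpute: int = 10,
    ka_reimpute: int = 4,
    m_representatives: int = 1000,
    c_mad: float = 3.0,
    seed: int = 0,
) -> StagingResult:
    """Run the full staging workflow on a raw count matrix.

    Normalize; embed (PCA of log cpm); build the diffusion operator; impute
    cpm at diffusion time ``t_impute``; cluster the PCA embedding of the
    log-imputed values into ``n_stages``; drop per-stage outliers; rebuild a
    deliberately lighter operator over retained cells (``k_reimpute``
    neighbors) and re-impute with the reduced time ``t_reimpute``; compute
    stage profiles from the re-imputed cpm.

    The reduced second imputation matters: heavy smoothing drives every
    pair of stage-dynamic genes toward the correlation of their stage-mean
    profiles, inflating false positives in downstream correlation analysis,
    so the re-imputed values retain most cell-level variation.

    Genes and cells are processed in lexicographic identifier order, which
    makes every output invariant to the input row/column order; results are
    keyed by identifier.
    """
    order_g = np.argsort(np.asarray(counts.gene_ids, dtype=object))
    order_c = np.argsort(np.asarray(counts.cell_ids, dtype=object))
    counts = CountMatrix(
        counts.values[np.ix_(order_g, order_c)],
        [counts.gene_ids[i] for i in order_g],
        [counts.cell_ids[i] for i in order_c],
    )
    log_raw = normalize_log_cpm(counts)
    raw_cpm = cpm(counts)
    emb0 = pca_embedding(log_raw, n_pcs, seed)
    op = build_diffusion_operator(emb0, k_neighbors, ka_adaptive)
    imputed1 = impute(raw_cpm, op, t_impute)
    log_imp1 = np.log2(imputed1 + 1.0)
    emb1 = pca_embedding(log_imp1, n_pcs, seed)
    m = min(m_representatives, counts.n_cells)
    stages1 = approx_spectral_cluster(emb1, m, n_stages, seed)
    mask = remove_outliers(emb1, stages1, c_mad)

    retained = [c for c, keep in zip(counts.cell_ids, mask) if keep]
    emb_kept = emb1[mask]
    op2 = build_diffusion_operator(
        emb_kept, min(k_reimpute, len(retained) - 1), min(ka_reimpute, k_reimpute)
    )
    imputed2 = impute(raw_cpm[:, mask], op2, t_reimpute)
    stages2 = StageAssignment(
        stages1.labels[mask], n_stages, stages1.representative_index[mask]
    )
    profile = stage_profile(imputed2, counts.gene_ids, stages2)
    return StagingResult(
        retained_cells=retained,
        stages=stages2,
        imputed_cpm=pd.DataFrame(imputed2, index=counts.gene_ids, columns=retained),
        log_imputed=pd.DataFrame(
            np.log2(imputed2 + 1.0), index=counts.gene_ids, columns=retained
        ),
        profile=profile,
        embedding=emb_kept,
        mask=mask,
        first_pass_stages=stages1,
        all_cells=list(counts.cell_ids),
    )
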