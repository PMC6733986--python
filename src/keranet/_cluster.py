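"""Shared agglomerative clustering on Pearson correlation distance.

Items are sorted lexicographically by identifier before distances are
computed, which makes the linkage (and therefore every downstream cut)
invariant to input order and gives deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ConfigurationError


def correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; errors on zero-variance rows."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ConfigurationError(
            f"zero-variance rows at indices {list(np.nonzero(sd == 0)[0][:5])}"
        )
    d = 1.0 - np.corrcoef(X)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class CorrClustering:
    """Ordered item ids, their labels (1..n_clusters) and the linkage tree."""

    item_ids: list[str]
    labels: dict[str, int]
    linkage_matrix: np.ndarray
    n_clusters: int
    linkage_method: str
    distance_kind: str = "pearson-correlation-distance"

    def members(self, cluster_id: int) -> list[str]:
        return [g for g, c in self.labels.items() if c == cluster_id]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out


def corr_cluster(
    frame: pd.DataFrame, n_clusters: int, linkage_method: str = "average"
) -> CorrClustering:
    """Agglomerative clustering of the rows of ``frame`` on 1 - Pearson r."""
    if len(frame) < n_clusters:
        raise ConfigurationError("fewer items than requested clusters")
    ordered = frame.loc[sorted(str(i) for i in frame.index)]
    D = correlation_distance(ordered.to_numpy())
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    lab = fcluster(Z, t=n_clusters, criterion="maxclust")
    # renumber clusters 1..n in order of first appearance for determinism
    remap: dict[int, int] = {}
    for c in lab:
        if c not in remap:
            remap[c] = len(remap) + 1
    labels = {g: remap[c] for g, c in zip(ordered.index, lab)}
    return CorrClustering(list(ordered.index), labels, Z, n_clusters, linkage_method)


def linkage_to_bracket(cl: CorrClustering) -> str:
    """Newick-like bracket text for the linkage tree (heights as lengths)."""
    n = len(cl.item_ids)
    Z = cl.linkage_matrix

    def node(i: int, parent_h: float) -> str:
        if i < n:
            return f"{cl.item_ids[i]}:{parent_h:.6g}"
        a, b, h, _ = Z[i - n]
        return f"({node(int(a), h)},{node(int(b), h)}):{max(parent_h - h, 0.0):.6g}"

    if n == 1:
        return f"{cl.item_ids[0]};"
    root_h = Z[-1, 2]
    a, b = int(Z[-1, 0]), int(Z[-1, 1])
    return f"({node(a, root_h)},{node(b, root_h)});"
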