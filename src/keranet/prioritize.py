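"""Differentiation-promoting scores and knockdown-candidate ranking.

A candidate TF's score is the sum, over its correlated keratinocyte-specific
targets, of ``sign(r) * logfc`` with logfc the moderated DK - BK log2 fold
change: strongly negative scores nominate basal-state (progenitor) promoters.
Candidates lowly expressed in undifferentiated keratinocyte cultures
(< 5 FPKM by default; exactly 5 is retained) are filtered before ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigurationError


@dataclass
class TargetCall:
    gene: str
    r: float
    sign: int
    logfc: float | None = None


@dataclass
class DPScore:
    """Per-TF differentiation-promoting score with its audit trail.

    The score is exactly reproducible from ``targets``:
    ``score = sum(sign(r_t) * logfc_t)``.
    """

    tf: str
    score: float
    targets: list[TargetCall] = field(default_factory=list)
    passed_culture_filter: bool | None = None
    fpkm: float | None = None

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def recompute(self) -> float:
        return float(sum(t.sign * t.logfc for t in self.targets))


def identify_targets(
    expr: pd.DataFrame,
    cell_mask: np.ndarray,
    tf: str,
    candidate_genes: list[str] | set[str],
    min_abs_r: float = 0.3,
) -> list[TargetCall]:
    """Genes whose |Pearson r| with the TF over the selected cells reaches
    ``min_abs_r``, each with the correlation's sign.  The TF itself is never
    its own target; a zero-variance TF is an error.
    """
    cells = np.asarray(cell_mask, dtype=bool)
    if tf not in expr.index:
        raise ConfigurationError(f"TF {tf} absent from expression matrix")
    x = expr.loc[tf, expr.columns[cells]].to_numpy(dtype=float)
    if x.std() == 0:
        raise ConfigurationError(f"TF {tf} has zero variance over the selected cells")
    out = []
    genes = sorted(g for g in set(candidate_genes) if g != tf and g in expr.index)
    sub = expr.loc[genes, expr.columns[cells]].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    xc = x - x.mean()
    denom = np.sqrt((xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (sub - sub.mean(axis=1, keepdims=True)) @ xc / (
            np.sqrt(((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)) * denom
        )
    for g, ri, s in zip(genes, r, sd):
        if s == 0 or not np.isfinite(ri):
            continue
        if abs(ri) >= min_abs_r:
            out.append(TargetCall(gene=g, r=float(ri), sign=1 if ri > 0 else -1))
    return out


def differentiation_score(tf: str, targets: list[TargetCall], de: pd.DataFrame) -> DPScore:
    """Sum of signed DK - BK log fold changes over the TF's targets.

    Every target must have a moderated-DE fold change; missing genes are an
    error listing them.  An empty target list scores 0.
    """
    missing = [t.gene for t in targets if t.gene not in de.index]
    if missing:
        raise ConfigurationError(f"targets without DE fold change: {missing[:10]}")
    audited = []
    score = 0.0
    for t in targets:
        lfc = float(de.loc[t.gene, "logfc"])
        audited.append(TargetCall(t.gene, t.r, t.sign, lfc))
        score += t.sign * lfc
    return DPScore(tf=tf, score=float(score), targets=audited)


def rank_candidates(
    scores: list[DPScore],
    culture_fpkm: pd.DataFrame | dict[str, float],
    min_fpkm: float = 5.0,
) -> pd.DataFrame:
    """Filter by culture expression and rank ascending by score.

    TFs with culture FPKM strictly below ``min_fpkm`` are excluded (a TF at
    exactly the threshold is retained); TFs absent from the table fail the
    filter with a warning.  The remainder is sorted ascending by score (most
    basal-promoting first), ties by descending target count then TF id.
    """
    if isinstance(culture_fpkm, pd.DataFrame):
        table = {str(t): float(v) for t, v in culture_fpkm["fpkm"].items()}
    else:
        table = {str(t): float(v) for t, v in culture_fpkm.items()}
    rows = []
    for s in scores:
        fpkm = table.get(s.tf)
        if fpkm is None:
            warnings.warn(f"TF {s.tf} absent from culture table; treated as failing", stacklevel=2)
            passed = False
        else:
            passed = fpkm >= min_fpkm
        s.fpkm = fpkm
        s.passed_culture_filter = passed
        rows.append(
            {
                "tf": s.tf,
                "score": s.score,
                "n_targets": s.n_targets,
                "fpkm": fpkm if fpkm is not None else np.nan,
                "passed_culture_filter": passed,
            }
        )
    df = pd.DataFrame(rows, columns=["tf", "score", "n_targets", "fpkm", "passed_culture_filter"])
    kept = df[df["passed_culture_filter"]].copy()
    if kept.empty:
        warnings.warn("all TFs failed the culture expression filter", stacklevel=2)
    kept = kept.sort_values(
        by=["score", "n_targets", "tf"], ascending=[True, False, True]
    ).reset_index(drop=True)
    kept.index = kept.index + 1
    kept.index.name = "rank"
    return kept


def target_audit_frame(scores: list[DPScore]) -> pd.DataFrame:
    rows = [
        {"tf": s.tf, "gene": t.gene, "r": t.r, "sign": t.sign, "logfc": t.logfc}
        for s in scores
        for t in s.targets
    ]
    return pd.DataFrame(rows, columns=["tf", "gene", "r", "sign", "logfc"])
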