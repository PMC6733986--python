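"""TF binding-motif models and super-enhancer differential motif enrichment.

The scanning model is the classic log-odds position weight matrix: at every
position of a sequence (both strands) the PWM log2-odds score against a
background base composition is computed, and a position is a *hit* when its
score reaches the threshold whose exact per-position null p-value — computed
by dynamic programming over the integer-rounded score distribution under the
background — is at or below the requested scan p-value.  Overlapping hits all
count.  ``N`` bases contribute a log-odds of 0 (background).

Per-enhancer occurrence counts are scaled to occurrences per kilobase, the
two enhancer states (basal BK vs differentiated DK) are compared per TF with
a two-sided Mann-Whitney U test, and the signed magnitude of differential
enrichment is the rank-biserial effect size ``2*AUC(BK over DK) - 1``
(positive = BK-enriched).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .io import ConfigurationError, SERegionSet
from .screen import bh_fdr, mann_whitney_u

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=int)  # A<->T, C<->G


@dataclass
class PWM:
    """Position weight matrix over A, C, G, T.

    ``counts`` may hold occurrence counts or column-normalized probabilities;
    probabilities are derived with a background-weighted pseudocount either
    way, so columns of the probability form always sum to 1.
    """

    name: str
    counts: np.ndarray  # (4, L)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ConfigurationError(f"PWM {self.name}: counts must be 4 x L")
        if self.length < 4:
            raise ConfigurationError(f"PWM {self.name}: motif length must be >= 4")
        if self.pseudocount <= 0:
            raise ConfigurationError(f"PWM {self.name}: pseudocount must be positive")
        if abs(self.background.sum() - 1.0) > 1e-9 or np.any(self.background <= 0):
            raise ConfigurationError(f"PWM {self.name}: background must be a positive 4-simplex point")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        col_tot = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount * self.background[:, None]) / (
            col_tot + self.pseudocount
        )

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in np.argmax(self.probabilities, axis=0))

    @property
    def information_content(self) -> float:
        """Total information content in bits relative to the background."""
        p = self.probabilities
        return float(np.sum(p * np.log2(p / self.background[:, None])))

    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds matrix against the background."""
        return np.log2(self.probabilities / self.background[:, None])

    # -- exact null score distribution -------------------------------------

    def _int_log_odds(self, scale: int) -> np.ndarray:
        return np.round(self.log_odds() * scale).astype(np.int64)

    def score_distribution(self, scale: int = 1000) -> tuple[np.ndarray, int]:
        """Exact pmf of the integer-rounded per-position score under the background.

        Returns ``(pmf, offset)`` where ``pmf[i]`` is the probability of integer
        score ``offset + i`` for a background-generated window.
        """
        ilo = self._int_log_odds(scale)
        pmf = np.array([1.0])
        offset = 0
        for j in range(self.length):
            col = ilo[:, j]
            lo, hi = int(col.min()), int(col.max())
            new = np.zeros(len(pmf) + (hi - lo))
            for a in range(4):
                shift = int(col[a]) - lo
                new[shift : shift + len(pmf)] += self.background[a] * pmf
            pmf = new
            offset += lo
        return pmf, offset

    def threshold_score(self, score_threshold_pvalue: float, scale: int = 1000) -> int:
        """Smallest integer score whose exact null tail p-value is <= the target.

        Tail p-values P(score >= T) come from :meth:`score_distribution`.  If
        even the maximal score is more probable than the target p-value the
        returned threshold is unattainable and scanning yields zero hits.
        """
        if not (0.0 < score_threshold_pvalue <= 0.01):
            raise ConfigurationError("scan p-value threshold must lie in (0, 0.01]")
        pmf, offset = self.score_distribution(scale=scale)
        tail = np.cumsum(pmf[::-1])[::-1]
        ok = np.nonzero(tail <= score_threshold_pvalue + 1e-15)[0]
        if len(ok) == 0:
            return offset + len(pmf)  # unattainable
        return offset + int(ok[0])


# ---------------------------------------------------------------------------
# motif file formats (JASPAR PFM, MEME minimal) via Biopython


def read_jaspar(path: str | Path) -> list[PWM]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in _ALPHABET], dtype=float)
        name = m.name or m.matrix_id
        out.append(PWM(name=str(name), counts=counts))
    return out


def write_jaspar(pwms: list[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name} {p.name}\n")
            for i, base in enumerate(_ALPHABET):
                row = " ".join(f"{v:7.2f}" for v in p.counts[i])
                fh.write(f"{base} [ {row} ]\n")


def read_meme_minimal(path: str | Path) -> list[PWM]:
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in _ALPHABET], dtype=float)
        out.append(PWM(name=str(m.name), counts=counts))
    return out


# ---------------------------------------------------------------------------
# scanning


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    idx = np.full(len(seq), -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")] = 4
    if np.any(idx < 0):
        bad = sorted({c for c in seq if c not in "ACGTN"})
        raise ConfigurationError(f"invalid sequence characters: {bad}")
    return idx


def _window_scores(idx: np.ndarray, ext_ilo: np.ndarray) -> np.ndarray:
    """Integer score of every window; ``ext_ilo`` is 5 x L with an all-zero N row."""
    L = ext_ilo.shape[1]
    n_win = len(idx) - L + 1
    scores = np.zeros(n_win, dtype=np.int64)
    for j in range(L):
        scores += ext_ilo[idx[j : j + n_win], j]
    return scores


def scan_pwm(
    sequence: str,
    pwm: PWM,
    score_threshold_pvalue: float = 1e-4,
    scale: int = 1000,
) -> int:
    """Count motif hits on both strands; overlapping hits all count.

    Sequences shorter than the motif yield 0 hits.
    """
    idx = _encode(sequence)
    if len(idx) < pwm.length:
        return 0
    threshold = pwm.threshold_score(score_threshold_pvalue, scale=scale)
    ilo = pwm._int_log_odds(scale)
    ext = np.vstack([ilo, np.zeros((1, pwm.length), dtype=np.int64)])
    # reverse strand == scanning the forward sequence with the reverse
    # complement of the matrix; the N row stays zero on both strands
    rc = ilo[_COMPLEMENT, ::-1]
    ext_rc = np.vstack([rc, np.zeros((1, pwm.length), dtype=np.int64)])
    n_fwd = int(np.sum(_window_scores(idx, ext) >= threshold))
    n_rev = int(np.sum(_window_scores(idx, ext_rc) >= threshold))
    return n_fwd + n_rev


def scaled_counts(
    se: SERegionSet,
    pwm: PWM,
    score_threshold_pvalue: float = 1e-4,
    scale: int = 1000,
) -> pd.Series:
    """Occurrences per kilobase for every region (index = region id)."""
    out = {}
    for r in se.regions:
        seq = se.sequences.get(r.region_id)
        if seq is None:
            raise ConfigurationError(f"region {r.region_id} has no sequence")
        n = scan_pwm(seq, pwm, score_threshold_pvalue, scale=scale)
        out[r.region_id] = n * 1000.0 / r.length
    return pd.Series(out, name=pwm.name)


# ---------------------------------------------------------------------------
# differential enrichment


def differential_enrichment(
    counts_bk: np.ndarray, counts_dk: np.ndarray, min_regions: int = 5
) -> tuple[float, float, float]:
    """Two-sided MWU of BK vs DK scaled counts plus rank-biserial magnitude.

    Returns ``(U, p, signed_magnitude)`` with ``signed_magnitude`` in [-1, 1]
    and positive values meaning BK-enriched.  BH correction across TFs is the
    caller's job (see :func:`enrichment_table`).
    """
    x = np.asarray(counts_bk, dtype=float)
    y = np.asarray(counts_dk, dtype=float)
    if min(len(x), len(y)) < min_regions:
        warnings.warn(
            f"fewer than {min_regions} regions in a state; enrichment test is weak",
            stacklevel=2,
        )
    u, p = mann_whitney_u(x, y, alternative="two-sided")
    auc = u / (len(x) * len(y))
    return float(u), float(p), float(2.0 * auc - 1.0)


def enrichment_table(
    se: SERegionSet,
    pwms: list[PWM],
    score_threshold_pvalue: float = 1e-4,
    alpha: float = 0.05,
    min_regions: int = 5,
    scale: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-TF differential enrichment between the BK and DK region states.

    Returns ``(table, per_region_counts)``.  ``table`` has one row per PWM with
    columns tf, u_statistic, p_value, q_value, direction, signed_magnitude;
    direction is "none" unless q < alpha, otherwise the state with the larger
    scaled counts.  ``per_region_counts`` is regions x TFs scaled counts.
    """
    bk_ids = [r.region_id for r in se.by_state("BK")]
    dk_ids = [r.region_id for r in se.by_state("DK")]
    if not bk_ids or not dk_ids:
        raise ConfigurationError("need regions in both BK and DK states")
    counts = pd.DataFrame(
        {p.name: scaled_counts(se, p, score_threshold_pvalue, scale=scale) for p in pwms}
    )
    rows = []
    for p in pwms:
        u, pval, mag = differential_enrichment(
            counts.loc[bk_ids, p.name].to_numpy(),
            counts.loc[dk_ids, p.name].to_numpy(),
            min_regions=min_regions,
        )
        rows.append({"tf": p.name, "u_statistic": u, "p_value": pval, "signed_magnitude": mag})
    table = pd.DataFrame(rows).set_index("tf", drop=False)
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    direction = np.where(
        table["q_value"] < alpha,
        np.where(table["signed_magnitude"] > 0, "BK", "DK"),
        "none",
    )
    table["direction"] = direction
    return table, counts


def concordance_test(
    branch_of: dict[str, str],
    signed_magnitude: dict[str, float],
    restrict_to_significant: bool = False,
    significant: set[str] | None = None,
) -> float:
    """One-sided MWU p-value that BK-branch TFs have larger signed magnitudes.

    ``branch_of`` maps TF -> "BK_branch"/"DK_branch" (peak-expression branch
    from trajectory clustering); ``signed_magnitude`` maps TF -> rank-biserial
    differential motif enrichment.  With ``restrict_to_significant`` only TFs
    in ``significant`` enter the test.
    """
    tfs = [t for t in branch_of if t in signed_magnitude]
    if restrict_to_significant:
        if significant is None:
            raise ConfigurationError("restrict_to_significant requires a significant set")
        tfs = [t for t in tfs if t in significant]
    bk = [signed_magnitude[t] for t in tfs if branch_of[t] == "BK_branch"]
    dk = [signed_magnitude[t] for t in tfs if branch_of[t] == "DK_branch"]
    for name, vals in (("BK_branch", bk), ("DK_branch", dk)):
        if len(vals) < 2:
            raise ConfigurationError(f"branch {name} has fewer than 2 TFs after restriction")
    _, p = mann_whitney_u(np.array(bk), np.array(dk), alternative="greater")
    return float(p)
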