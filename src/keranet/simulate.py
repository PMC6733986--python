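"""Synthetic keratinocyte differentiation data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, with known labels for every planted feature:

* a genes x cells UMI count matrix with K discrete differentiation stages,
  smooth unimodal stage-mean trajectories, TF->target correlation induced by
  shared per-cell latent TF activities, negative-binomial counts with an
  independent dropout layer;
* a bulk cell-type expression matrix (CAGE-style TSS features summing to
  genes) with a small keratinocyte sample group carrying planted upregulated
  genes;
* two super-enhancer region sets (BK and DK states) of i.i.d. background
  sequence with motif consensus sites planted as Poisson processes whose
  per-kilobase rates differ between states for directional TFs.

All randomness flows from one root seed through named substreams, so a fixed
``(config, seed)`` pair reproduces every output byte-identically and partial
reruns of a single generator are stable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ConfigurationError, CountMatrix, BulkExpressionMatrix, SERegion, SERegionSet
from .motifs import PWM

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the scale the pipeline is exercised at: ~3,000 cells x
    1,500 genes in 8 stages, 10 keratinocyte TFs (half peaking basally, half
    in differentiation) each driving ``targets_per_tf`` signed targets, a
    495-sample bulk atlas with a 3-sample keratinocyte group, and 50
    super-enhancers per state with a 3-fold planted motif density contrast.
    """

    n_cells: int = 3000
    n_genes: int = 1500
    n_stages: int = 8
    n_tfs: int = 10
    targets_per_tf: int = 20
    n_specific_genes: int = 200
    antioxidant_cluster_sizes: tuple[int, int, int] = (20, 6, 6)  # basal, mid, late
    library_size_mean: float = 5000.0
    nb_dispersion: float = 0.1
    dropout_rate: float = 0.3
    latent_noise_sd: float = 0.5
    tf_activity_noise_sd: float = 1.5  # cell-level (bursting) noise of TF expression
    stage_fingerprint_sd: float = 0.6  # per-stage level jitter of background genes
    tf_target_coupling: float = 2.0  # log2 units per SD of TF activity
    n_bulk_samples: int = 495
    n_target_samples: int = 3
    bulk_effect_lfc: float = 4.0
    features_per_gene_max: int = 3
    n_se_per_state: int = 50
    se_length_range: tuple[int, int] = (1000, 3000)
    se_gc: float = 0.41
    motif_length: int = 8
    se_motif_density_per_kb: float = 1.0
    n_null_motifs: int = 5
    planted_density_ratio: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_cells": self.n_cells,
            "n_genes": self.n_genes,
            "n_stages": self.n_stages,
            "n_tfs": self.n_tfs,
            "targets_per_tf": self.targets_per_tf,
            "library_size_mean": self.library_size_mean,
            "n_bulk_samples": self.n_bulk_samples,
            "n_target_samples": self.n_target_samples,
            "n_se_per_state": self.n_se_per_state,
            "planted_density_ratio": self.planted_density_ratio,
            "motif_length": self.motif_length,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive (got {value})")
        if self.nb_dispersion < 0 or self.latent_noise_sd < 0:
            raise ConfigurationError("dispersion and noise SD must be non-negative")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        if self.n_target_samples >= self.n_bulk_samples:
            raise ConfigurationError("n_target_samples must be < n_bulk_samples")
        if self.se_length_range[0] < self.motif_length:
            raise ConfigurationError("minimum SE length must be >= motif length")
        if self.se_length_range[0] > self.se_length_range[1]:
            raise ConfigurationError("se_length_range must be (min, max)")
        if self.n_planted_genes > self.n_genes:
            raise ConfigurationError(
                "n_genes too small for the requested TFs/targets/specific/antioxidant genes"
            )
        if not (0.0 < self.se_gc < 1.0):
            raise ConfigurationError("se_gc must lie in (0, 1)")

    # -- derived layout ----------------------------------------------------

    @property
    def n_bk_tfs(self) -> int:
        return (self.n_tfs + 1) // 2

    @property
    def bk_tfs(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_bk_tfs)]

    @property
    def dk_tfs(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_bk_tfs, self.n_tfs)]

    @property
    def tfs(self) -> list[str]:
        return self.bk_tfs + self.dk_tfs

    @property
    def null_motif_names(self) -> list[str]:
        return [f"NULL{i + 1:02d}" for i in range(self.n_null_motifs)]

    @property
    def n_planted_genes(self) -> int:
        return (
            self.n_tfs
            + self.n_tfs * self.targets_per_tf
            + self.n_specific_genes
            + sum(self.antioxidant_cluster_sizes)
        )

    @property
    def bk_stage_range(self) -> tuple[int, int]:
        """Stages counting as the basal (BK) state; 1-3 at K = 8."""
        hi = max(1, round(3 * self.n_stages / 8))
        return (1, hi)

    @property
    def dk_stage_range(self) -> tuple[int, int]:
        """Stages counting as the differentiated (DK) state; 5-7 at K = 8."""
        lo = min(self.n_stages, max(2, round(5 * self.n_stages / 8)))
        hi = max(lo, self.n_stages - 1)
        return (lo, hi)

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the root seed (stable across partial reruns)."""
        key = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedTruth:
    """Ground-truth labels for everything the generator plants."""

    cell_stage: dict[str, int] = field(default_factory=dict)
    gene_role: dict[str, str] = field(default_factory=dict)
    tf_target_sign: dict[str, dict[str, int]] = field(default_factory=dict)
    tf_enrichment_direction: dict[str, str] = field(default_factory=dict)
    target_lfc: dict[str, float] = field(default_factory=dict)
    planted_sites: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        owners: dict[str, str] = {}
        for tf, targets in self.tf_target_sign.items():
            for g in targets:
                if g in owners:
                    raise ConfigurationError(f"target {g} mapped to two TFs")
                owners[g] = tf

    def target_pairs(self) -> list[tuple[str, str, int]]:
        return [
            (tf, g, sign)
            for tf, targets in sorted(self.tf_target_sign.items())
            for g, sign in sorted(targets.items())
        ]

    def to_dict(self) -> dict:
        return {
            "cell_stage": self.cell_stage,
            "gene_role": self.gene_role,
            "tf_target_sign": self.tf_target_sign,
            "tf_enrichment_direction": self.tf_enrichment_direction,
            "target_lfc": self.target_lfc,
            "planted_sites": self.planted_sites,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        return cls(
            cell_stage={k: int(v) for k, v in d.get("cell_stage", {}).items()},
            gene_role=dict(d.get("gene_role", {})),
            tf_target_sign={
                tf: {g: int(s) for g, s in t.items()}
                for tf, t in d.get("tf_target_sign", {}).items()
            },
            tf_enrichment_direction=dict(d.get("tf_enrichment_direction", {})),
            target_lfc={k: float(v) for k, v in d.get("target_lfc", {}).items()},
            planted_sites=list(d.get("planted_sites", [])),
        )


# ---------------------------------------------------------------------------
# gene layout and stage-mean profiles


def _bump(stages: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-((stages - peak) ** 2) / (2.0 * width**2))


def _gene_layout(config: SimulationConfig) -> tuple[list[str], dict[str, str], dict[str, dict[str, int]]]:
    """Deterministic gene id list, roles, and TF->target sign map."""
    rng = config.rng("gene_layout")
    gene_ids: list[str] = []
    role: dict[str, str] = {}
    sign_map: dict[str, dict[str, int]] = {}
    for tf in config.bk_tfs:
        gene_ids.append(tf)
        role[tf] = "bk_tf"
    for tf in config.dk_tfs:
        gene_ids.append(tf)
        role[tf] = "dk_tf"
    for tf in config.tfs:
        sign_map[tf] = {}
        for k in range(config.targets_per_tf):
            g = f"{tf}_tgt{k + 1:03d}"
            gene_ids.append(g)
            role[g] = f"target_of_{tf}"
            sign_map[tf][g] = 1 if rng.random() < 0.5 else -1
    for k in range(config.n_specific_genes):
        g = f"SPEC{k + 1:04d}"
        gene_ids.append(g)
        role[g] = "specific_gene"
    for cls, n in zip(("basal", "mid", "late"), config.antioxidant_cluster_sizes):
        for k in range(n):
            g = f"AOX_{cls}{k + 1:02d}"
            gene_ids.append(g)
            role[g] = f"antioxidant_{cls}"
    for k in range(config.n_genes - config.n_planted_genes):
        g = f"BG{k + 1:04d}"
        gene_ids.append(g)
        role[g] = "background"
    return gene_ids, role, sign_map


def _stage_profiles(
    config: SimulationConfig, gene_ids: list[str], role: dict[str, str]
) -> pd.DataFrame:
    """Per-gene log2 stage-mean profiles for the non-target genes.

    Targets get their profiles through the TF latent activity instead and are
    set to their baselines here (overridden per cell during sampling).
    """
    rng = config.rng("profiles")
    stages = np.arange(1, config.n_stages + 1, dtype=float)
    bk_lo, bk_hi = config.bk_stage_range
    dk_lo, dk_hi = config.dk_stage_range
    prof = np.zeros((len(gene_ids), config.n_stages))
    for i, g in enumerate(gene_ids):
        r = role[g]
        if r == "bk_tf":
            # continuous peak positions and varied widths keep TF activity
            # profiles mutually distinguishable within the state window
            base = rng.uniform(4.0, 6.0)
            peak = rng.uniform(bk_lo, bk_hi)
            prof[i] = base + 3.0 * _bump(stages, peak, rng.uniform(0.9, 1.5))
        elif r == "dk_tf":
            base = rng.uniform(4.0, 6.0)
            peak = rng.uniform(dk_lo, dk_hi)
            prof[i] = base + 3.0 * _bump(stages, peak, rng.uniform(0.9, 1.5))
        elif r.startswith("target_of_"):
            prof[i] = rng.uniform(4.0, 6.0)
        elif r == "specific_gene":
            # cell-type specific in bulk but essentially stage-flat in the
            # single-cell cohort (specificity != differentiation dynamics)
            base = rng.uniform(2.0, 5.0)
            amp = rng.uniform(0.0, 0.3)
            peak = rng.uniform(1.0, config.n_stages)
            prof[i] = base + amp * _bump(stages, peak, rng.uniform(1.0, 2.0))
        elif r.startswith("antioxidant_"):
            # each planted class shares a coherent trajectory shape (peaks
            # jitter within a narrow window) so the classes are recoverable
            # as distinct trajectory clusters
            base = rng.uniform(3.0, 5.0)
            cls = r.removeprefix("antioxidant_")
            mid_stage = (bk_hi + dk_lo) / 2.0
            if cls == "basal":
                peak = rng.uniform(bk_lo + 0.8, bk_lo + 1.6)
            elif cls == "mid":
                peak = rng.uniform(mid_stage - 0.3, mid_stage + 0.3)
            else:
                peak = rng.uniform(dk_hi - 1.2, dk_hi - 0.4)
            prof[i] = base + 2.5 * _bump(stages, peak, 1.4)
        else:  # background
            # smooth low-amplitude trend plus independent per-stage levels:
            # most of the transcriptome shifts between differentiation stages,
            # which is what makes the K stages discrete expression states
            base = rng.uniform(1.0, 4.0)
            amp = rng.uniform(0.0, 0.4)
            peak = rng.uniform(1.0, config.n_stages)
            prof[i] = (
                base
                + amp * _bump(stages, peak, rng.uniform(1.0, 2.0))
                + rng.normal(0.0, config.stage_fingerprint_sd, config.n_stages)
            )
    return pd.DataFrame(prof, index=gene_ids, columns=[f"stage_{int(s)}" for s in stages])


# ---------------------------------------------------------------------------
# single-cell counts


def simulate_stage_counts(config: SimulationConfig) -> tuple[CountMatrix, PlantedTruth]:
    """Simulate the stage-structured UMI count matrix and its ground truth.

    Cells are spread near-uniformly over the K stages.  Every TF's per-cell
    latent activity is its stage-mean log2 level plus Gaussian noise; each
    target's log2 level is its baseline plus ``tf_target_coupling`` times the
    signed, standardized activity of its TF, which induces per-cell Pearson
    correlation of the planted sign.  Counts are negative binomial around
    ``library_size * relative expression`` (Poisson when ``nb_dispersion`` is
    0) and then zeroed independently with probability ``dropout_rate``.
    """
    gene_ids, role, sign_map = _gene_layout(config)
    profiles = _stage_profiles(config, gene_ids, role)
    K = config.n_stages

    rng_cells = config.rng("cell_stages")
    stage_of_cell = np.tile(np.arange(1, K + 1), config.n_cells // K + 1)[: config.n_cells]
    rng_cells.shuffle(stage_of_cell)
    cell_ids = [f"cell_{i + 1:05d}" for i in range(config.n_cells)]

    rng_lat = config.rng("latent")
    prof = profiles.to_numpy()
    log2x = prof[:, stage_of_cell - 1].astype(float)  # genes x cells
    noise_sd = config.latent_noise_sd
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # TF activities: stage mean + cell-level noise, then standardized over
    # cells.  The activity noise is deliberately large relative to the
    # stage-trend amplitude: single-cell TF expression is dominated by
    # cell-to-cell variability, and the shared activity (not the stage trend)
    # is what couples a TF to its targets.
    for tf in config.tfs:
        ti = gene_index[tf]
        act = log2x[ti] + rng_lat.normal(0.0, config.tf_activity_noise_sd, config.n_cells)
        log2x[ti] = act
        sd = act.std()
        z = (act - act.mean()) / sd if sd > 0 else np.zeros_like(act)
        for g, sign in sign_map[tf].items():
            gi = gene_index[g]
            log2x[gi] = (
                prof[gi, 0]  # constant baseline
                + config.tf_target_coupling * sign * z
                + rng_lat.normal(0.0, noise_sd, config.n_cells)
            )
    non_tf_target = [
        i
        for g, i in gene_index.items()
        if role[g] not in ("bk_tf", "dk_tf") and not role[g].startswith("target_of_")
    ]
    for i in non_tf_target:
        log2x[i] = log2x[i] + rng_lat.normal(0.0, noise_sd, config.n_cells)

    x = np.exp2(log2x)
    rates = config.library_size_mean * x / x.sum(axis=0, keepdims=True)

    rng_counts = config.rng("counts")
    if config.nb_dispersion == 0:
        counts = rng_counts.poisson(rates)
    else:
        n = 1.0 / config.nb_dispersion
        p = n / (n + rates)
        counts = rng_counts.negative_binomial(n, p)
    if config.dropout_rate > 0:
        keep = rng_counts.random(counts.shape) >= config.dropout_rate
        counts = counts * keep

    truth = PlantedTruth(
        cell_stage={c: int(s) for c, s in zip(cell_ids, stage_of_cell)},
        gene_role=role,
        tf_target_sign=sign_map,
        tf_enrichment_direction=_enrichment_directions(config),
        target_lfc=_model_target_lfc(config, gene_ids, role, sign_map, profiles),
    )
    return CountMatrix(counts.astype(np.int64), gene_ids, cell_ids), truth


def _model_target_lfc(
    config: SimulationConfig,
    gene_ids: list[str],
    role: dict[str, str],
    sign_map: dict[str, dict[str, int]],
    profiles: pd.DataFrame,
) -> dict[str, float]:
    """Model-implied expected DK - BK difference of log2(cpm + 1).

    Computed from the noise-free stage-mean expression (targets inherit the
    standardized stage profile of their TF scaled by the coupling), converted
    to log2 cpm with equal stage weights, and multiplied by
    ``1 - dropout_rate``: independent zeroing scales the expected log-scale
    signal of every gene by the kept fraction.
    """
    K = config.n_stages
    prof = profiles.to_numpy().astype(float).copy()
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    stage_sd_floor = 1e-12
    for tf, targets in sign_map.items():
        tf_prof = prof[gene_index[tf]]
        mu = tf_prof.mean()
        sd = np.sqrt(tf_prof.var() + config.tf_activity_noise_sd**2)
        z = (tf_prof - mu) / max(sd, stage_sd_floor)
        for g, sign in targets.items():
            gi = gene_index[g]
            prof[gi] = prof[gi] + config.tf_target_coupling * sign * z
    x = np.exp2(prof)
    cpm = 1e6 * x / x.sum(axis=0, keepdims=True)
    log_cpm = np.log2(cpm + 1.0)
    bk_lo, bk_hi = config.bk_stage_range
    dk_lo, dk_hi = config.dk_stage_range
    bk_cols = np.arange(bk_lo - 1, bk_hi)
    dk_cols = np.arange(dk_lo - 1, dk_hi)
    diff = log_cpm[:, dk_cols].mean(axis=1) - log_cpm[:, bk_cols].mean(axis=1)
    diff = (1.0 - config.dropout_rate) * diff
    return {
        g: float(diff[gene_index[g]])
        for g in gene_ids
        if role[g].startswith("target_of_")
    }


def _enrichment_directions(config: SimulationConfig) -> dict[str, str]:
    out = {tf: "BK" for tf in config.bk_tfs}
    out.update({tf: "DK" for tf in config.dk_tfs})
    out.update({m: "none" for m in config.null_motif_names})
    return out


# ---------------------------------------------------------------------------
# bulk cell-type matrix


def simulate_bulk_celltype_matrix(
    config: SimulationConfig,
) -> tuple[BulkExpressionMatrix, PlantedTruth]:
    """Simulate the CAGE-style bulk atlas at TSS-feature level.

    Every planted keratinocyte gene (TFs, targets, specific genes,
    antioxidants) has its log2 expression elevated by ``bulk_effect_lfc`` in
    the ``n_target_samples``-sample keratinocyte group; each gene's value is
    split over 1..``features_per_gene_max`` TSS features so the gene-level
    aggregation step is exercised.  With ``bulk_effect_lfc == 0`` nothing is
    planted (the null case for screen calibration).
    """
    gene_ids, role, _ = _gene_layout(config)
    rng = config.rng("bulk")
    n_s = config.n_bulk_samples
    n_t = config.n_target_samples
    # keratinocyte-specific bulk expression is planted for TFs, their targets
    # and the SPEC genes; antioxidant genes are a separately curated list and
    # stay out of the screen's planted truth
    keratinocyte_roles = (
        lambda r: r in ("bk_tf", "dk_tf", "specific_gene") or r.startswith("target_of_")
    )
    planted = (
        [g for g in gene_ids if keratinocyte_roles(role[g])]
        if config.bulk_effect_lfc != 0
        else []
    )

    base = rng.normal(5.0, 1.0, len(gene_ids))
    log2v = base[:, None] + rng.normal(0.0, 0.5, (len(gene_ids), n_s))
    planted_idx = [i for i, g in enumerate(gene_ids) if g in set(planted)]
    log2v[np.ix_(planted_idx, np.arange(n_t))] += config.bulk_effect_lfc
    values = np.exp2(log2v)

    sample_ids = [f"kerat_{i + 1}" for i in range(n_t)] + [
        f"other_{i + 1:03d}" for i in range(n_s - n_t)
    ]
    group = {s: ("keratinocyte" if s.startswith("kerat_") else "other") for s in sample_ids}

    feature_ids: list[str] = []
    feature_to_gene: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for i, g in enumerate(gene_ids):
        n_peaks = int(rng.integers(1, config.features_per_gene_max + 1))
        w = rng.dirichlet(np.ones(n_peaks))
        for k in range(n_peaks):
            fid = f"peak{k + 1}@{g}"
            feature_ids.append(fid)
            feature_to_gene[fid] = g
            rows.append(values[i] * w[k])
    bulk = BulkExpressionMatrix(
        np.vstack(rows), feature_ids, sample_ids, group, feature_to_gene
    )
    truth = PlantedTruth(
        gene_role=role,
        tf_target_sign={},
        tf_enrichment_direction=_enrichment_directions(config),
    )
    return bulk, truth


# ---------------------------------------------------------------------------
# motifs and super-enhancer regions


def simulate_motifs(config: SimulationConfig) -> list[PWM]:
    """One high-information consensus PWM per TF plus null motifs.

    Columns put probability 0.88 on the consensus base (~1.28 bits/column,
    >10 bits for the default 8-mer), comfortably detectable at the default
    scan p-value once planted.
    """
    rng = config.rng("motifs")
    out = []
    for name in config.tfs + config.null_motif_names:
        consensus = rng.integers(0, 4, config.motif_length)
        counts = np.full((4, config.motif_length), 4.0)
        counts[consensus, np.arange(config.motif_length)] = 88.0
        out.append(PWM(name=name, counts=counts))
    return out


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def simulate_se_regions(
    config: SimulationConfig, pwms: list[PWM] | None = None
) -> tuple[SERegionSet, PlantedTruth]:
    """Simulate BK and DK super-enhancer sets with planted motif densities.

    Background sequence is i.i.d. with the configured GC content; for each
    PWM, consensus occurrences are planted as a Poisson process whose rate is
    ``se_motif_density_per_kb`` (per kb), multiplied by
    ``planted_density_ratio`` in the TF's enriched state.  BED coordinates
    are 0-based half-open and consistent with the sequence lengths.
    """
    if pwms is None:
        pwms = simulate_motifs(config)
    for p in pwms:
        if p.length > config.se_length_range[0]:
            raise ConfigurationError(f"motif {p.name} longer than the shortest region")
    directions = _enrichment_directions(config)
    rng = config.rng("se_regions")
    regions: list[SERegion] = []
    sequences: dict[str, str] = {}
    sites: list[dict] = []
    offset = 0
    for state in ("BK", "DK"):
        for i in range(config.n_se_per_state):
            length = int(rng.integers(config.se_length_range[0], config.se_length_range[1] + 1))
            rid = f"SE_{state}_{i + 1:03d}"
            seq = _random_sequence(rng, length, config.se_gc)
            for pwm in pwms:
                direction = directions.get(pwm.name, "none")
                rate = config.se_motif_density_per_kb
                if direction == state:
                    rate *= config.planted_density_ratio
                n_occ = rng.poisson(rate * length / 1000.0)
                consensus = pwm.consensus
                for _ in range(n_occ):
                    pos = int(rng.integers(0, length - pwm.length + 1))
                    strand = "+" if rng.random() < 0.5 else "-"
                    planted = consensus if strand == "+" else _revcomp(consensus)
                    seq[pos : pos + pwm.length] = [_BASE_INDEX_SIM[b] for b in planted]
                    sites.append(
                        {
                            "region_id": rid,
                            "position": pos,
                            "strand": strand,
                            "motif": pwm.name,
                        }
                    )
            regions.append(SERegion("chrS", offset, offset + length, rid, state))
            offset += length + 100
            sequences[rid] = "".join(_BASES[seq])
    truth = PlantedTruth(
        gene_role={},
        tf_target_sign={},
        tf_enrichment_direction=directions,
        planted_sites=sites,
    )
    return SERegionSet(regions, sequences), truth


_BASE_INDEX_SIM = {b: i for i, b in enumerate("ACGT")}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# culture expression and curated lists


def simulate_culture_fpkm(config: SimulationConfig) -> pd.DataFrame:
    """Bulk FPKM of each TF in undifferentiated keratinocyte culture.

    Cultured keratinocytes are proliferating/basal, so basal-peaking TFs are
    robustly expressed (well above the 5-FPKM culture filter) while
    differentiation-peaking TFs scatter around it and can fail it.
    """
    rng = config.rng("culture_fpkm")
    rows = []
    for tf in config.bk_tfs:
        rows.append({"tf": tf, "fpkm": float(np.exp2(rng.normal(5.0, 0.8)))})
    for tf in config.dk_tfs:
        rows.append({"tf": tf, "fpkm": float(np.exp2(rng.normal(2.5, 1.5)))})
    return pd.DataFrame(rows).set_index("tf", drop=False)


def curated_tf_list(config: SimulationConfig) -> list[str]:
    """Deterministic stand-in for the literature-curated TF list.

    Every second TF of each planted group is 'curated', so the candidate set
    (screen TFs minus curated) retains both basal- and differentiation-
    peaking members and TF prioritization is non-trivial.
    """
    return [tf for i, tf in enumerate(config.tfs) if i % 2 == 1]


def tf_annotation_list(config: SimulationConfig) -> list[str]:
    """Stand-in for the genome-wide TF catalogue used to split TFs from genes."""
    return list(config.tfs)
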