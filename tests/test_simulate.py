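"""Generator contracts: determinism, closed-form count moments, planted
structure (bulk effects, motif sites, correlation signs)."""

import numpy as np
import pytest

from keranet.io import ConfigurationError
from keranet.simulate import (
    SimulationConfig,
    curated_tf_list,
    simulate_bulk_celltype_matrix,
    simulate_motifs,
    simulate_se_regions,
    simulate_stage_counts,
)

_COMP = str.maketrans("ACGT", "TGCA")


class TestConfig:
    def test_rejects_bad_dimensions(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_cells=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_target_samples=10, n_bulk_samples=10)
        with pytest.raises(ConfigurationError):
            SimulationConfig(se_length_range=(4, 100), motif_length=8)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=10)  # too small for planted roles

    def test_stage_windows_match_study_layout(self):
        cfg = SimulationConfig()
        assert cfg.bk_stage_range == (1, 3)
        assert cfg.dk_stage_range == (5, 7)


class TestDeterminism:
    def test_identical_seed_reproduces_everything(self, small_config):
        c1, t1 = simulate_stage_counts(small_config)
        c2, t2 = simulate_stage_counts(small_config)
        np.testing.assert_array_equal(c1.values, c2.values)
        assert t1.cell_stage == t2.cell_stage
        b1, _ = simulate_bulk_celltype_matrix(small_config)
        b2, _ = simulate_bulk_celltype_matrix(small_config)
        np.testing.assert_array_equal(b1.values, b2.values)
        s1, tt1 = simulate_se_regions(small_config)
        s2, tt2 = simulate_se_regions(small_config)
        assert s1.sequences == s2.sequences
        assert tt1.planted_sites == tt2.planted_sites

    def test_different_seed_changes_counts(self, small_config):
        c1, _ = simulate_stage_counts(small_config)
        cfg2 = SimulationConfig(**{**small_config.to_dict(), "seed": 43})
        c2, _ = simulate_stage_counts(cfg2)
        assert (c1.values != c2.values).any()


def _expected_stage_rates(cfg):
    """Noise-free expected per-stage NB means, including the target coupling.

    With balanced stages and zero noise the generator's per-cell standardized
    TF activity equals the stage-wise z-score of the TF profile.
    """
    from keranet.simulate import _gene_layout, _stage_profiles

    gene_ids, role, sign_map = _gene_layout(cfg)
    prof = _stage_profiles(cfg, gene_ids, role).to_numpy().copy()
    idx = {g: i for i, g in enumerate(gene_ids)}
    for tf, targets in sign_map.items():
        a = prof[idx[tf]]
        z = (a - a.mean()) / a.std() if a.std() > 0 else np.zeros_like(a)
        for g, sign in targets.items():
            prof[idx[g]] = prof[idx[g], 0] + cfg.tf_target_coupling * sign * z
    x = np.exp2(prof)
    return gene_ids, cfg.library_size_mean * x / x.sum(axis=0, keepdims=True)


class TestCountMoments:
    def test_degenerate_noise_mean_matches_closed_form(self):
        """Poisson limit, no dropout/noise: E[count] = libsize * mu / sum(mu)."""
        cfg = SimulationConfig(
            n_cells=6000,
            n_genes=60,
            n_tfs=2,
            targets_per_tf=2,
            n_specific_genes=5,
            antioxidant_cluster_sizes=(2, 1, 1),
            nb_dispersion=0.0,
            dropout_rate=0.0,
            latent_noise_sd=0.0,
            tf_activity_noise_sd=0.0,
            stage_fingerprint_sd=0.0,
            n_bulk_samples=10,
            n_target_samples=2,
            seed=5,
        )
        counts, truth = simulate_stage_counts(cfg)
        _, rates = _expected_stage_rates(cfg)
        stage_of = np.array([truth.cell_stage[c] for c in counts.cell_ids])
        for s in (1, 4, 8):
            cells = stage_of == s
            expected = rates[:, s - 1]
            observed = counts.values[:, cells].mean(axis=1)
            se = np.sqrt(np.maximum(expected, 1e-9) / cells.sum())  # Poisson SE
            assert np.all(np.abs(observed - expected) < 4 * se + 0.05)

    def test_nb_dropout_mean_within_monte_carlo_error(self):
        """With NB dispersion and dropout: E[count] = rate * (1 - dropout)."""
        cfg = SimulationConfig(
            n_cells=10000,
            n_genes=60,
            n_tfs=2,
            targets_per_tf=2,
            n_specific_genes=5,
            antioxidant_cluster_sizes=(2, 1, 1),
            latent_noise_sd=0.0,
            tf_activity_noise_sd=0.0,
            stage_fingerprint_sd=0.0,
            n_bulk_samples=10,
            n_target_samples=2,
            seed=6,
        )
        counts, truth = simulate_stage_counts(cfg)
        _, rates = _expected_stage_rates(cfg)
        stage_of = np.array([truth.cell_stage[c] for c in counts.cell_ids])
        cells = stage_of == 2
        rate = rates[:, 1]
        expected = rate * (1.0 - cfg.dropout_rate)
        observed = counts.values[:, cells].mean(axis=1)
        # NB-with-dropout variance: (1-d)*(m + phi m^2) + d(1-d) m^2
        var = (1 - cfg.dropout_rate) * (rate + cfg.nb_dispersion * rate**2) + cfg.dropout_rate * (
            1 - cfg.dropout_rate
        ) * rate**2
        se = np.sqrt(var / cells.sum())
        assert np.all(np.abs(observed - expected) < 4 * se + 0.05)


class TestPlantedStructure:
    def test_roles_are_disjoint_and_targets_unique(self, small_config):
        _, truth = simulate_stage_counts(small_config)
        owners = {}
        for tf, targets in truth.tf_target_sign.items():
            for g in targets:
                assert g not in owners
                owners[g] = tf
                assert truth.gene_role[g] == f"target_of_{tf}"

    def test_target_correlation_sign_at_low_noise(self):
        """Planted per-cell TF-target correlations carry the planted sign."""
        cfg = SimulationConfig(
            n_cells=2000,
            n_genes=300,
            n_tfs=4,
            targets_per_tf=8,
            n_specific_genes=30,
            antioxidant_cluster_sizes=(4, 2, 2),
            latent_noise_sd=0.05,
            n_bulk_samples=10,
            n_target_samples=2,
            seed=11,
        )
        counts, truth = simulate_stage_counts(cfg)
        log_cpm = np.log2(1e6 * counts.values / counts.values.sum(0) + 1)
        idx = {g: i for i, g in enumerate(counts.gene_ids)}
        ok = total = 0
        for tf, targets in truth.tf_target_sign.items():
            for g, sign in targets.items():
                r = np.corrcoef(log_cpm[idx[tf]], log_cpm[idx[g]])[0, 1]
                ok += int(np.sign(r) == sign)
                total += 1
        assert ok / total >= 0.95

    def test_bulk_null_plants_nothing(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(), "bulk_effect_lfc": 0.0})
        bulk, truth = simulate_bulk_celltype_matrix(cfg)
        target = [s for s in bulk.sample_ids if bulk.sample_group[s] == "keratinocyte"]
        assert len(target) == cfg.n_target_samples
        # no systematic elevation: group-mean log ratio centred near zero
        tcols = [bulk.sample_ids.index(s) for s in target]
        ocols = [i for i in range(len(bulk.sample_ids)) if i not in tcols]
        lfc = np.log2(bulk.values[:, tcols].mean(1) + 1) - np.log2(
            bulk.values[:, ocols].mean(1) + 1
        )
        assert abs(np.mean(lfc)) < 0.2

    def test_bulk_large_effect_elevates_planted_genes(self, small_config):
        bulk, truth = simulate_bulk_celltype_matrix(small_config)
        agg = {}
        for f, g in bulk.feature_to_gene.items():
            agg.setdefault(g, np.zeros(len(bulk.sample_ids)))
            agg[g] += bulk.values[bulk.feature_ids.index(f)]
        t = [i for i, s in enumerate(bulk.sample_ids) if bulk.sample_group[s] == "keratinocyte"]
        o = [i for i in range(len(bulk.sample_ids)) if i not in t]
        planted = [
            g
            for g, r in truth.gene_role.items()
            if r in ("bk_tf", "dk_tf", "specific_gene") or r.startswith("target_of_")
        ]
        for g in planted:
            assert agg[g][t].mean() > agg[g][o].mean()

    def test_planted_motif_sites_match_consensus(self, small_config):
        # low density so overlapping plantings (which may overwrite earlier
        # sites) are rare; every surviving site must spell the consensus
        cfg = SimulationConfig(
            **{
                **small_config.to_dict(),
                "se_motif_density_per_kb": 0.2,
                "planted_density_ratio": 1.0,
            }
        )
        pwms = simulate_motifs(cfg)
        by_name = {p.name: p for p in pwms}
        se, truth = simulate_se_regions(cfg, pwms)
        assert truth.planted_sites, "generator must record planted sites"
        ok = 0
        for site in truth.planted_sites:
            pwm = by_name[site["motif"]]
            seq = se.sequences[site["region_id"]][site["position"] : site["position"] + pwm.length]
            want = pwm.consensus if site["strand"] == "+" else pwm.consensus.translate(_COMP)[::-1]
            ok += int(seq == want)
        assert ok / len(truth.planted_sites) > 0.98

    def test_poisson_site_counts_match_rate(self):
        cfg = SimulationConfig(
            n_se_per_state=150,
            se_length_range=(2000, 2000),
            se_motif_density_per_kb=5.0,
            planted_density_ratio=1.0,
            n_tfs=2,
            targets_per_tf=2,
            n_genes=100,
            n_specific_genes=5,
            antioxidant_cluster_sizes=(2, 1, 1),
            n_null_motifs=0,
            n_bulk_samples=10,
            n_target_samples=2,
            seed=3,
        )
        se, truth = simulate_se_regions(cfg)
        per_region = {}
        for s in truth.planted_sites:
            if s["motif"] == "TF01":
                per_region[s["region_id"]] = per_region.get(s["region_id"], 0) + 1
        counts = [per_region.get(r.region_id, 0) for r in se.regions]
        mean = np.mean(counts)
        se_mc = np.sqrt(10.0 / len(counts))
        assert abs(mean - 10.0) < 4 * se_mc

    def test_curated_list_keeps_candidates_mixed(self, small_config):
        curated = set(curated_tf_list(small_config))
        candidates = set(small_config.tfs) - curated
        assert candidates & set(small_config.bk_tfs)
        assert candidates & set(small_config.dk_tfs)
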