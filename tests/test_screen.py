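"""Specificity screen, rank statistics and moderated differential expression.

The Mann-Whitney implementation is checked against exhaustive permutation
enumeration; BH against the textbook step-up rule; moderated DE against the
d0 -> 0 limit, the shrinkage sandwich property, a null simulation, the
planted-truth generator, and an independent R/limma run when available.
"""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from keranet.io import BulkExpressionMatrix, ConfigurationError, CountMatrix
from keranet.screen import (
    aggregate_features_to_genes,
    assemble_gene_sets,
    bh_fdr,
    celltype_specific_screen,
    de_expressed_filter,
    fit_variance_prior,
    mann_whitney_u,
    moderated_de,
    normalize_log_cpm_frame,
    scrna_expression_filter,
    squeeze_variances,
)
from keranet.simulate import SimulationConfig, simulate_bulk_celltype_matrix, simulate_stage_counts


def _mwu_enumeration(x, y, alternative="two-sided"):
    """Exact p by enumerating all assignments of pooled values to groups."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for xi in xs:
            for yi in ys:
                u += (xi > yi) + 0.5 * (xi == yi)
        return u

    u_obs = u_stat(x, y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    eps = 1e-9
    if alternative == "greater":
        p = np.mean(us >= u_obs - eps)
    elif alternative == "less":
        p = np.mean(us <= u_obs + eps)
    else:
        mu = n1 * (len(pooled) - n1) / 2
        p = min(1.0, 2 * min(np.mean(us >= u_obs - eps), np.mean(us <= u_obs + eps)))
    return u_obs, p


class TestMannWhitney:
    def test_small_sample_closed_form(self):
        u, p = mann_whitney_u(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets_give_p_one(self):
        with pytest.warns(UserWarning):
            u, p = mann_whitney_u(np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert p == 1.0

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_agrees_with_exhaustive_enumeration(self, rng, alternative):
        for _ in range(25):
            n1, n2 = rng.integers(2, 6, 2)
            x = rng.normal(size=n1).round(2)
            y = rng.normal(size=n2).round(2)
            if len(np.unique(np.concatenate([x, y]))) < n1 + n2:
                continue  # tie-free branch is the exact one
            u, p = mann_whitney_u(x, y, alternative)
            u_ref, p_ref = _mwu_enumeration(x, y, alternative)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_large_sample_uses_tie_corrected_normal(self, rng):
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 4, 30).astype(float)
        u, p = mann_whitney_u(x, y)
        assert 0 <= p <= 1


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_fdr(np.ones(5)), 1.0)

    def test_matches_textbook_step_up(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            m = len(p)
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_rejects_nan(self):
        with pytest.raises(ConfigurationError):
            bh_fdr(np.array([0.1, np.nan]))


class TestAggregation:
    def test_two_peaks_sum(self):
        bulk = BulkExpressionMatrix(
            np.array([[3.0], [5.0]]), ["p1", "p2"], ["s1"], {"s1": "a"},
            {"p1": "G", "p2": "G"},
        )
        agg = aggregate_features_to_genes(bulk)
        assert agg.values[0, 0] == 8.0

    def test_identity_map_preserves_matrix(self, rng):
        vals = rng.random((4, 3))
        bulk = BulkExpressionMatrix(
            vals, list("abcd"), ["s1", "s2", "s3"], {s: "g" for s in ["s1", "s2", "s3"]},
            {f: f for f in "abcd"},
        )
        agg = aggregate_features_to_genes(bulk)
        np.testing.assert_allclose(agg.to_frame().loc[list("abcd")].to_numpy(), vals)

    def test_matches_groupby_oracle(self, rng):
        genes = [f"G{i}" for i in rng.integers(0, 20, 100)]
        vals = rng.random((100, 5))
        fmap = {f"f{i}": genes[i] for i in range(100)}
        bulk = BulkExpressionMatrix(
            vals, [f"f{i}" for i in range(100)], [f"s{j}" for j in range(5)],
            {f"s{j}": "x" for j in range(5)}, fmap,
        )
        agg = aggregate_features_to_genes(bulk)
        df = pd.DataFrame(vals, index=genes).groupby(level=0).sum()
        np.testing.assert_allclose(agg.to_frame().to_numpy(), df.to_numpy())

    def test_empty_map_errors(self):
        bulk = BulkExpressionMatrix(np.ones((1, 1)), ["f"], ["s"], {"s": "x"}, {})
        with pytest.raises(ConfigurationError):
            aggregate_features_to_genes(bulk)


class TestScreen:
    def test_down_in_target_never_selected(self, rng):
        vals = rng.random((5, 20)) + 1
        vals[0, :3] = 0.01  # clearly lower in target
        group = {f"s{j}": ("kera" if j < 3 else "other") for j in range(20)}
        bulk = BulkExpressionMatrix(vals, [f"g{i}" for i in range(5)],
                                    [f"s{j}" for j in range(20)], group)
        res = celltype_specific_screen(bulk, "kera", alpha=0.99)
        assert not res.loc["g0", "selected"]
        assert res.loc["g0", "direction"] == "down_in_target"

    def test_null_false_positive_control(self, small_config):
        cfg = SimulationConfig(**{**small_config.to_dict(), "bulk_effect_lfc": 0.0})
        bulk, _ = simulate_bulk_celltype_matrix(cfg)
        res = celltype_specific_screen(aggregate_features_to_genes(bulk), "keratinocyte")
        frac = res["selected"].mean()
        assert frac <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / len(res))

    def test_planted_genes_recovered(self, small_config):
        bulk, truth = simulate_bulk_celltype_matrix(small_config)
        res = celltype_specific_screen(aggregate_features_to_genes(bulk), "keratinocyte")
        planted = [
            g for g, r in truth.gene_role.items()
            if r in ("bk_tf", "dk_tf", "specific_gene") or r.startswith("target_of_")
        ]
        recovered = res.loc[planted, "selected"].mean()
        assert recovered >= 0.95

    def test_excluded_samples_are_ignored(self, rng):
        vals = rng.random((3, 10)) + 1
        group = {f"s{j}": ("kera" if j < 3 else "other") for j in range(10)}
        bulk = BulkExpressionMatrix(vals, list("abc"), [f"s{j}" for j in range(10)], group)
        full = celltype_specific_screen(bulk, "kera")
        drop = celltype_specific_screen(bulk, "kera", exclude_samples=["s9"])
        assert not full.equals(drop)


class TestExpressionFilters:
    def test_boundaries(self):
        values = np.zeros((3, 1000), dtype=int)
        values[0, :10] = 1  # exactly 1% of cells
        values[1, :9] = 1
        counts = CountMatrix(values, ["keep", "drop", "zero"],
                             [f"c{i}" for i in range(1000)])
        kept = scrna_expression_filter(counts)
        assert kept == {"keep"}

    def test_de_filter_boundary(self):
        values = np.zeros((2, 30), dtype=int)
        values[0, :20] = 3
        values[1, :19] = 3
        counts = CountMatrix(values, ["in", "out"], [f"c{i}" for i in range(30)])
        assert de_expressed_filter(counts) == {"in"}

    def test_matches_brute_force(self, rng, tiny_counts):
        kept = scrna_expression_filter(tiny_counts, min_umis=2, min_cell_fraction=0.3)
        need = math.ceil(0.3 * tiny_counts.n_cells)
        for i, g in enumerate(tiny_counts.gene_ids):
            assert (g in kept) == ((tiny_counts.values[i] >= 2).sum() >= need)


class TestGeneSets:
    def test_union_size(self):
        tfs = {f"T{i}" for i in range(51)}
        curated = {f"T{i}" for i in range(41, 90)}  # overlap 10
        gs = assemble_gene_sets(tfs, set(), curated)
        assert len(gs.keratinocyte_tfs) == 90
        assert gs.candidate_tfs == tfs - curated
        assert not (gs.candidate_tfs & gs.curated_tfs)

    def test_empty_curated_makes_all_candidates(self):
        gs = assemble_gene_sets({"A", "B"}, {"G"}, set())
        assert gs.candidate_tfs == {"A", "B"}
        assert gs.keratinocyte_genes == {"A", "B", "G"}

    def test_manual_additions_flagged_and_warned(self):
        with pytest.warns(UserWarning, match="manual additions"):
            gs = assemble_gene_sets({"A"}, set(), set(), {"HES1"}, expressed_genes={"A"})
        assert "HES1" in gs.fantom_tfs
        assert gs.manual_additions == {"HES1"}

    def test_set_algebra_oracle(self, rng):
        universe = [f"g{i}" for i in range(100)]
        tfs = set(rng.choice(universe, 30, replace=False))
        genes = set(rng.choice(universe, 40, replace=False)) - tfs
        curated = set(rng.choice(universe, 20, replace=False))
        gs = assemble_gene_sets(tfs, genes, curated)
        assert gs.keratinocyte_tfs == tfs | curated
        assert gs.candidate_tfs == tfs - curated
        assert gs.keratinocyte_genes == tfs | curated | genes


class TestModeratedDE:
    def _null_matrix(self, rng, n_genes=300, n_per=40):
        x = rng.normal(5, 1, (n_genes, 2 * n_per))
        cells = [f"c{i}" for i in range(2 * n_per)]
        state = {c: ("BK" if i < n_per else "DK") for i, c in enumerate(cells)}
        return pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)], columns=cells), state

    def test_d0_zero_limit_is_unmoderated(self, rng):
        s2 = rng.random(50) + 0.5
        np.testing.assert_allclose(squeeze_variances(s2, 10, 0.0, np.ones(50)), s2)

    def test_shrinkage_sandwich(self, rng):
        log_cpm, state = self._null_matrix(rng)
        res = moderated_de(log_cpm, state, trend=False)
        s2 = res["s2"].to_numpy()
        post = res["s2_post"].to_numpy()
        d0, s0 = fit_variance_prior(s2, len(state) - 2)
        lo = np.minimum(s2, s0)
        hi = np.maximum(s2, s0)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_null_calls_controlled(self, rng):
        log_cpm, state = self._null_matrix(rng, n_genes=2000)
        res = moderated_de(log_cpm, state)
        assert (res["q_value"] < 0.05).mean() <= 0.05

    def test_matches_plain_t_when_variance_shared(self, rng):
        n = 500
        x = np.vstack([rng.normal(0, 1.0, (200, 2 * n))])
        cells = [f"c{i}" for i in range(2 * n)]
        state = {c: ("BK" if i < n else "DK") for i, c in enumerate(cells)}
        log_cpm = pd.DataFrame(x, index=[f"g{i}" for i in range(200)], columns=cells)
        res = moderated_de(log_cpm, state, trend=False)
        from scipy import stats as st

        t_plain = st.ttest_ind(x[:, n:], x[:, :n], axis=1).statistic
        # under a shared variance the EB fit pools fully; the residual
        # deviation is the plain t's own variance-estimation noise
        # (~ |t| * sd(s)/sigma ~ 0.1 at the tail over 200 genes)
        d = np.abs(res["t_mod"].to_numpy() - t_plain)
        assert np.max(d) < 0.2
        assert np.median(d) < 0.02

    def test_recovers_planted_fold_changes(self):
        cfg = SimulationConfig(
            n_cells=1000,
            n_genes=500,
            n_tfs=4,
            targets_per_tf=10,
            n_specific_genes=60,
            antioxidant_cluster_sizes=(6, 3, 3),
            library_size_mean=30000.0,
            n_bulk_samples=10,
            n_target_samples=2,
            seed=8,
        )
        counts, truth = simulate_stage_counts(cfg)
        log_cpm = normalize_log_cpm_frame(counts)
        bk_lo, bk_hi = cfg.bk_stage_range
        dk_lo, dk_hi = cfg.dk_stage_range
        state = {}
        for c, s in truth.cell_stage.items():
            state[c] = "BK" if bk_lo <= s <= bk_hi else "DK" if dk_lo <= s <= dk_hi else "x"
        res = moderated_de(log_cpm, state)
        targets = list(truth.target_lfc)
        est = res.loc[targets, "logfc"].to_numpy()
        want = np.array([truth.target_lfc[g] for g in targets])
        assert abs(np.mean(est - want)) < 0.05

    def test_small_state_errors(self, rng):
        log_cpm, _ = self._null_matrix(rng, n_genes=10, n_per=5)
        state = {c: "BK" for c in log_cpm.columns}
        state[log_cpm.columns[0]] = "DK"
        with pytest.raises(ConfigurationError):
            moderated_de(log_cpm, state)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_cross_checks_against_limma(self, rng, tmp_path):
        """Independent oracle: limma-trend on the same two-group matrix."""
        log_cpm, state = self._null_matrix(rng, n_genes=120, n_per=15)
        log_cpm.iloc[:20] += np.where(
            np.array([state[c] == "DK" for c in log_cpm.columns]), 1.0, 0.0
        )
        log_cpm.to_csv(tmp_path / "x.tsv", sep="\t")
        groups = ",".join("1" if state[c] == "DK" else "0" for c in log_cpm.columns)
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1, check.names=FALSE))
        g <- c({groups})
        design <- cbind(Intercept=1, DK=g)
        fit <- eBayes(lmFit(x, design), trend=TRUE)
        out <- topTable(fit, coef="DK", number=Inf, sort.by="none")
        write.csv(out[, c("logFC", "t")], "{tmp_path}/limma.csv")
        """
        r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        if r.returncode != 0:
            pytest.skip(f"limma unavailable: {r.stderr[-200:]}")
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        res = moderated_de(log_cpm, state, trend=True)
        np.testing.assert_allclose(res["logfc"].to_numpy(), ref["logFC"].to_numpy(), atol=1e-8)
        # different trend smoothers (lowess vs limma's) leave small t differences
        assert np.median(np.abs(res["t_mod"].to_numpy() - ref["t"].to_numpy())) < 0.15
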