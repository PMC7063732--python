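"""Analysis-method tests: every statistic against an independent oracle
(exhaustive enumeration, textbook formula, or scipy), plus screen-level
behaviour on simulated data."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import screensim as ss
from screensim.analyze import (
    AnalysisError,
    _hypergeom_sf,
    analyze_screen,
    bh_adjust,
    guide_log_fold_changes,
    pooled_t_test,
    rsa_rank_pvalue,
    size_factors,
    stouffer_combine,
)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile(np.arange(1, 51)[:, None], (1, 2))
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample(self):
        a = np.arange(1, 51)
        counts = np.c_[a, 2 * a]
        np.testing.assert_allclose(
            size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_matches_brute_force_median_of_ratios(self, rng):
        counts = rng.integers(1, 500, size=(50, 4))
        # oracle: per-guide geometric mean reference, per-sample median ratio
        ref = np.array([math.prod(row) ** (1 / 4) for row in counts.astype(float)])
        raw = np.array(
            [np.median(counts[:, j] / ref) for j in range(4)]
        )
        oracle = raw / math.prod(raw) ** (1 / 4)
        np.testing.assert_allclose(size_factors(counts), oracle, rtol=1e-10)

    def test_all_zero_sample_rejected(self):
        counts = np.c_[np.arange(10), np.zeros(10, dtype=int)]
        with pytest.raises(AnalysisError):
            size_factors(counts)


class TestLogFoldChanges:
    samples = ["initial_rep1", "treated_rep1"]

    def test_identical_arms_give_zero_lfc(self):
        counts = np.tile(np.arange(1, 21)[:, None], (1, 2))
        out = guide_log_fold_changes(counts, self.samples, centering="all")
        np.testing.assert_allclose(out["lfc"], 0.0, atol=1e-12)

    def test_doubled_guide_is_one_lfc_up(self):
        base = np.full(200, 100)
        treated = base.copy()
        treated[0] = 200
        out = guide_log_fold_changes(
            np.c_[base, treated], self.samples, pseudocount=0.5, centering="all"
        )
        # median-centered; the bulk sits at 0 so the doubled guide shows ~ +1
        assert out["lfc"].iloc[0] == pytest.approx(1.0, abs=0.02)
        assert np.median(out["lfc"]) == pytest.approx(0.0, abs=1e-12)

    def test_control_median_is_zero_after_centering(self, small_screen):
        out = guide_log_fold_changes(
            small_screen.counts,
            small_screen.sample_names,
            guide_ids=small_screen.library.guides["guide"].to_numpy(),
            control_mask=small_screen.library.control_mask,
            centering="controls",
        )
        ctrl_lfc = out.loc[small_screen.library.control_mask, "lfc"]
        assert np.median(ctrl_lfc) == pytest.approx(0.0, abs=1e-12)

    def test_missing_controls_falls_back_with_warning(self, caplog):
        counts = np.tile(np.arange(1, 21)[:, None], (1, 2))
        with caplog.at_level("WARNING"):
            guide_log_fold_changes(counts, self.samples, centering="controls")
        assert any("falling back" in r.message for r in caplog.records)


class TestPooledT:
    def test_equal_samples_give_t_zero(self):
        t, p = pooled_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_guide_against_textbook_oracle(self):
        gene = np.array([-1.0])
        ctrl = np.array([0.1, -0.1, 0.0, 0.05, -0.05])
        t, p = pooled_t_test(gene, ctrl)
        # textbook pooled two-sample t computed from first principles
        n1, n2 = 1, 5
        sp2 = (0.0 + ((ctrl - ctrl.mean()) ** 2).sum()) / (n1 + n2 - 2)
        t_oracle = (gene.mean() - ctrl.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), n1 + n2 - 2)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_matches_scipy_equal_variance_t(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 8))
            c = rng.normal(size=rng.integers(2, 30))
            t, p = pooled_t_test(x, c)
            ref = stats.ttest_ind(x, c, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_requires_two_controls(self):
        with pytest.raises(AnalysisError):
            pooled_t_test([1.0], [0.0])


def _bh_brute_force(p):
    """Step-up BH by direct definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj


class TestBH:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_exhaustive_small_instances_match_brute_force(self):
        grid = [0.005, 0.04, 0.25, 1.0]
        for n in range(1, 7):
            for combo in itertools.product(grid, repeat=n):
                np.testing.assert_allclose(
                    bh_adjust(list(combo)), _bh_brute_force(combo), atol=1e-12
                )

    def test_nan_rejected(self):
        with pytest.raises(AnalysisError):
            bh_adjust([0.1, float("nan")])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_contract(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


def _rsa_enumeration_oracle(ranks, n_total):
    """min over prefixes of exhaustively enumerated hypergeometric tails."""
    ranks = sorted(ranks)
    k = len(ranks)
    best = 1.0
    for i, r in enumerate(ranks, start=1):
        hits = 0
        total = 0
        for subset in itertools.combinations(range(1, n_total + 1), k):
            total += 1
            if sum(1 for s in subset if s <= r) >= i:
                hits += 1
        best = min(best, hits / total)
    return best


class TestRSA:
    def test_single_top_ranked_guide(self):
        assert rsa_rank_pvalue([1], 10) == pytest.approx(0.1)

    def test_two_top_guides(self):
        assert rsa_rank_pvalue([1, 2], 10) == pytest.approx(1 / 45)

    def test_exhaustive_configurations_match_enumeration(self):
        for n_total in range(1, 9):
            for k in range(1, n_total + 1):
                for ranks in itertools.combinations(range(1, n_total + 1), k):
                    assert rsa_rank_pvalue(list(ranks), n_total) == pytest.approx(
                        _rsa_enumeration_oracle(ranks, n_total), abs=1e-12
                    )

    def test_duplicate_ranks_rejected(self):
        with pytest.raises(AnalysisError):
            rsa_rank_pvalue([3, 3], 10)

    def test_fast_tail_matches_scipy(self, rng):
        M = 5000
        K = rng.integers(1, 21, 300)
        N = rng.integers(1, M + 1, 300)
        i = np.array([rng.integers(1, k + 1) for k in K])
        np.testing.assert_allclose(
            _hypergeom_sf(i, M, K, N),
            stats.hypergeom.sf(i - 1, M, K, N),
            atol=1e-10,
        )

    def test_null_calibration_bounded_by_prefix_union(self, rng):
        """Under uniform random ranks the min-over-prefixes p-value is
        anti-conservative (it takes an uncorrected minimum over
        guides_per_gene cutoffs) but bounded: each prefix tail is
        marginally super-uniform, so t <= P(p <= t) <= guides_per_gene * t."""
        n_genes, gpg = 4000, 4
        n_total = n_genes * gpg
        perm = rng.permutation(n_total) + 1
        pvals = np.array(
            [
                rsa_rank_pvalue(perm[g * gpg : (g + 1) * gpg], n_total)
                for g in range(n_genes)
            ]
        )
        grid = np.linspace(0.01, 0.5, 20)
        ecdf = (pvals[:, None] <= grid[None, :]).mean(axis=0)
        mc_tol = 3 * np.sqrt(0.25 / n_genes)
        assert np.all(ecdf <= gpg * grid + mc_tol)
        assert np.all(ecdf >= grid - mc_tol)


class TestStouffer:
    def test_single_guide_identity(self):
        assert stouffer_combine([0.05], [1]) == pytest.approx(0.05, abs=1e-12)

    def test_two_consistent_guides_match_normal_quantile_oracle(self):
        # two guides each with one-sided p = 0.05 (two-sided 0.1), same direction
        combined = stouffer_combine([0.1, 0.1], [1, 1])
        z = 2 * stats.norm.isf(0.05) / np.sqrt(2)
        assert z == pytest.approx(2.3262, abs=1e-4)
        assert combined == pytest.approx(2 * stats.norm.sf(z), abs=1e-12)

    def test_opposite_directions_cancel(self):
        assert stouffer_combine([0.03, 0.03], [1, -1]) == pytest.approx(1.0)

    def test_degenerate_p_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            p = stouffer_combine([0.0, 0.5], [1, 1])
        assert 0.0 < p < 1.0


class TestAnalyzeScreen:
    def test_gene_table_shape_and_contract(self, small_screen):
        res = analyze_screen(
            small_screen.counts, small_screen.sample_names, small_screen.library, "t_test"
        )
        assert len(res) == small_screen.library.n_genes
        assert not res["gene"].str.startswith("ctrl").any()
        assert res["p_value"].between(0, 1).all()
        assert res["fdr"].between(0, 1).all()
        assert sorted(res["rank"]) == list(range(1, len(res) + 1))
        # BH FDR is monotone along the p-value ordering
        ordered = res.sort_values("rank")
        assert (ordered["fdr"].diff().dropna() >= -1e-12).all()

    @pytest.mark.parametrize("method", ["t_test", "rsa", "stouffer"])
    def test_row_order_invariance(self, small_screen, method):
        lib = small_screen.library
        res_a = analyze_screen(small_screen.counts, small_screen.sample_names, lib, method)
        perm = np.random.default_rng(0).permutation(lib.n_guides)
        lib_perm = ss.GuideLibrary(
            guides=lib.guides.iloc[perm].reset_index(drop=True), genes=lib.genes
        )
        res_b = analyze_screen(
            small_screen.counts[perm], small_screen.sample_names, lib_perm, method
        )
        pd.testing.assert_frame_equal(res_a, res_b)

    def test_t_test_requires_controls(self, small_params):
        p = small_params.replace(n_controls=0)
        s = ss.simulate_screen(p)
        with pytest.raises(AnalysisError, match="control"):
            analyze_screen(s.counts, s.sample_names, s.library, "t_test")

    def test_unknown_method_rejected(self, small_screen):
        with pytest.raises(AnalysisError, match="unknown method"):
            analyze_screen(
                small_screen.counts, small_screen.sample_names, small_screen.library, "magic"
            )

    @pytest.mark.parametrize("method", ["t_test", "rsa", "stouffer"])
    def test_essential_pvalues_stochastically_smaller(self, small_screen, method):
        res = analyze_screen(
            small_screen.counts, small_screen.sample_names, small_screen.library, method
        )
        truth = small_screen.library.truth_labels().reindex(res["gene"])
        ess = res.loc[truth.to_numpy(), "p_value"]
        null = res.loc[~truth.to_numpy(), "p_value"]
        assert stats.mannwhitneyu(ess, null, alternative="less").pvalue < 1e-10

    def test_rsa_and_t_test_agree_on_strong_signal(self, small_screen):
        lib = small_screen.library
        n_ess = int(lib.genes["is_essential"].sum())
        tops = {}
        for method in ("t_test", "rsa"):
            res = analyze_screen(small_screen.counts, small_screen.sample_names, lib, method)
            tops[method] = set(res.nsmallest(n_ess, "rank")["gene"])
        overlap = len(tops["t_test"] & tops["rsa"]) / n_ess
        assert overlap > 0.5

    def test_stouffer_matches_scalar_combination(self, small_screen):
        """The vectorized per-gene path equals explicit stouffer_combine calls."""
        lib = small_screen.library
        lfc = guide_log_fold_changes(
            small_screen.counts,
            small_screen.sample_names,
            guide_ids=lib.guides["guide"].to_numpy(),
            control_mask=lib.control_mask,
        )
        ctrl = lfc.loc[lib.control_mask, "lfc"]
        mu, sd = ctrl.mean(), ctrl.std(ddof=1)
        res = analyze_screen(small_screen.counts, small_screen.sample_names, lib, "stouffer")
        merged = lfc.merge(lib.guides, on="guide")
        for gene in res["gene"].sample(10, random_state=0):
            z = (merged.loc[merged["gene"] == gene, "lfc"] - mu) / sd
            p2 = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1 - 1e-16)
            expected = stouffer_combine(p2, np.sign(z.to_numpy()))
            got = float(res.loc[res["gene"] == gene, "p_value"].iloc[0])
            assert got == pytest.approx(expected, rel=1e-9)
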