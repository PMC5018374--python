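"""Per-set logistic regression, FDR adjustment and classification."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import mirgsa as mg
from oracles import grid_mle, random_logistic_instance


def gene_index(t_values, targeted=None):
    genes = [f"g{i}" for i in range(len(t_values))]
    targeted = [True] * len(t_values) if targeted is None else targeted
    return pd.DataFrame(
        {"t": list(t_values), "targeted": targeted},
        index=pd.Index(genes, name="gene_id"),
    )


class TestNormalizeIndex:
    def test_symmetric_and_order_preserving(self):
        out = mg.normalize_index(gene_index([-5.0, 0.0, 5.0]))
        t = out["t"].to_numpy()
        assert t[1] == pytest.approx(0.0)
        assert t[0] == pytest.approx(-t[2])
        assert t[0] < t[1] < t[2]

    def test_all_ties_map_to_zero(self):
        out = mg.normalize_index(gene_index([2.0, 2.0, 2.0, 2.0]))
        assert np.allclose(out["t"], 0.0)

    def test_quantiles_at_rank_over_n_plus_one(self):
        out = mg.normalize_index(gene_index([1.0, 2.0, 3.0, 4.0]))
        expected = scipy.stats.norm.ppf([0.2, 0.4, 0.6, 0.8])
        assert np.allclose(out["t"], expected, atol=5e-5)
        assert out["t"].to_numpy() == pytest.approx(
            [-0.8416, -0.2533, 0.2533, 0.8416], abs=5e-5
        )

    def test_untargeted_rows_untouched(self):
        gi = gene_index([1.0, 2.0, 3.0, 9.9], targeted=[True, True, True, False])
        out = mg.normalize_index(gi)
        assert out.loc["g3", "t"] == 9.9

    def test_too_few_targeted_genes(self):
        with pytest.raises(ValueError, match=">= 3"):
            mg.normalize_index(gene_index([1.0, 2.0]))


class TestFitSetLogistic:
    def test_null_pvalues_uniform(self):
        """Membership independent of the score gives ~U(0,1) Wald p-values."""
        rng = np.random.default_rng(101)
        pvals = []
        genes = [f"g{i}" for i in range(2000)]
        for _ in range(500):
            t = pd.Series(rng.normal(size=2000), index=genes)
            members = set(rng.choice(genes, size=200, replace=False))
            fit = mg.fit_set_logistic(t, members)
            assert fit.converged
            assert abs(fit.alpha) < 1.0
            pvals.append(fit.pvalue)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_shifted_members_detected(self):
        """A one-sd shift of 100/1000 members is detected nearly always."""
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(1000)]
        members = set(genes[:100])
        hits = 0
        for _ in range(200):
            t = rng.normal(size=1000)
            t[:100] += 1.0
            fit = mg.fit_set_logistic(pd.Series(t, index=genes), members)
            hits += fit.converged and fit.alpha > 0 and fit.pvalue < 0.05
        assert hits >= 190  # >= 95% of 200 replicates

    def test_perfect_separation_flagged(self):
        t = pd.Series([10.0] * 5 + [-10.0] * 5, index=[f"g{i}" for i in range(10)])
        fit = mg.fit_set_logistic(t, {f"g{i}" for i in range(5)})
        assert not fit.converged and np.isnan(fit.pvalue)

    def test_degenerate_universe_is_an_error_not_nonconvergence(self):
        t = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="members and non-members"):
            mg.fit_set_logistic(t, set())
        with pytest.raises(ValueError, match="members and non-members"):
            mg.fit_set_logistic(t, {"a", "b", "c"})

    def test_mle_matches_grid_search_oracle(self):
        """On 50 small instances the MLE matches a brute-force grid search."""
        rng = np.random.default_rng(42)
        n_done = 0
        while n_done < 50:
            inst = random_logistic_instance(rng)
            if inst is None:
                continue
            t, y = inst
            series = pd.Series(t, index=[f"g{i}" for i in range(len(t))])
            members = {f"g{i}" for i in range(len(t)) if y[i] == 1}
            fit = mg.fit_set_logistic(series, members)
            if not fit.converged:
                continue
            gk, ga = grid_mle(t, y)
            assert fit.kappa == pytest.approx(gk, abs=1e-4)
            assert fit.alpha == pytest.approx(ga, abs=1e-4)
            n_done += 1

    def test_slope_nondecreasing_in_member_shift(self):
        """Shifting members upward by delta never decreases the fitted slope."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(400)]
        base = rng.normal(size=400)
        members = set(genes[:50])
        alphas = []
        for delta in [0.0, 0.25, 0.5, 1.0, 2.0]:
            t = base.copy()
            t[:50] += delta
            fit = mg.fit_set_logistic(pd.Series(t, index=genes), members)
            assert fit.converged
            alphas.append(fit.alpha)
        assert all(b >= a - 1e-12 for a, b in zip(alphas, alphas[1:]))


class TestAdjustPvalues:
    def test_bh_step_up_hand_computed(self):
        assert mg.adjust_pvalues([0.01, 0.02, 0.03], "BH") == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_pvalue_unchanged_under_bh(self):
        assert mg.adjust_pvalues([0.2], "BH")[0] == pytest.approx(0.2)

    def test_nan_passthrough(self):
        out = mg.adjust_pvalues([0.01, np.nan, 0.04], "BH")
        assert np.isnan(out[1]) and np.isfinite(out[0]) and np.isfinite(out[2])
        # the two finite values are adjusted as a family of two
        assert out[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mg.adjust_pvalues([0.5, 1.2], "BH")

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
        st.sampled_from(["BH", "BY"]),
    )
    def test_adjusted_values_dominate_raw_and_cap_at_one(self, pvals, method):
        adj = mg.adjust_pvalues(pvals, method)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_by_dominates_bh(self, pvals):
        assert np.all(
            mg.adjust_pvalues(pvals, "BY") >= mg.adjust_pvalues(pvals, "BH") - 1e-15
        )


class TestClassifyTerm:
    @pytest.mark.parametrize(
        "alpha,padj,expected",
        [
            (2.1, 0.001, mg.INHIBITED_IN_CASES),
            (-1.3, 0.01, mg.DEREGULATED_IN_CASES),
            (5.0, 0.2, mg.NOT_SIGNIFICANT),
            (np.nan, np.nan, mg.NOT_SIGNIFICANT),
        ],
    )
    def test_labels(self, alpha, padj, expected):
        assert mg.classify_term(alpha, padj, 0.05) == expected

    @given(
        alpha=st.floats(-10, 10, allow_nan=False),
        padj=st.floats(0, 1, allow_nan=False),
    )
    def test_totality(self, alpha, padj):
        assert mg.classify_term(alpha, padj, 0.05) in mg.CLASSIFICATIONS


class TestRunGsa:
    def test_planted_top_decile_set_detected(self):
        """A set whose members occupy the top scores comes out positive."""
        rng = np.random.default_rng(11)
        t = np.sort(rng.normal(size=2000))
        gi = gene_index(t)
        members = frozenset(
            f"g{i}" for i in rng.choice(np.arange(1800, 2000), 50, replace=False)
        )
        decoys = [
            mg.GeneSet(
                f"null{i:02d}",
                f"null {i}",
                frozenset(f"g{j}" for j in rng.choice(2000, 50, replace=False)),
            )
            for i in range(20)
        ]
        sets = mg.GeneSetCollection([mg.GeneSet("top", "top decile", members), *decoys])
        records = mg.run_gsa(gi, sets, mg.GsaParams())
        rec = {r.set_id: r for r in records}["top"]
        assert rec.alpha > 0 and rec.padj < 0.05
        assert rec.classification == mg.INHIBITED_IN_CASES

    def test_size_filter_applied_in_universe(self):
        gi = gene_index(np.linspace(-2, 2, 100))
        sets = mg.GeneSetCollection(
            [
                mg.GeneSet("small", "s", frozenset(["g1", "g2"])),
                mg.GeneSet("ok", "o", frozenset(f"g{i}" for i in range(30))),
            ]
        )
        records = mg.run_gsa(gi, sets, mg.GsaParams(min_set_size=10))
        assert [r.set_id for r in records] == ["ok"]

    def test_deterministic_output(self, small_scenario):
        _, stats, tm, sets, _ = small_scenario
        gi = mg.transfer_index(mg.compute_ranking_index(stats), tm)
        first = mg.records_to_frame(mg.run_gsa(gi, sets, mg.GsaParams()))
        second = mg.records_to_frame(mg.run_gsa(gi, sets, mg.GsaParams()))
        pd.testing.assert_frame_equal(first, second)

    def test_no_surviving_set_warns_not_raises(self, caplog):
        gi = gene_index(np.linspace(-2, 2, 20))
        sets = mg.GeneSetCollection([mg.GeneSet("s", "s", frozenset(["g1"]))])
        with caplog.at_level("WARNING"):
            assert mg.run_gsa(gi, sets, mg.GsaParams()) == []
        assert any("survived" in rec.message for rec in caplog.records)

    def test_every_record_carries_exactly_one_label(self, small_scenario):
        _, stats, tm, sets, _ = small_scenario
        gi = mg.transfer_index(mg.compute_ranking_index(stats), tm)
        records = mg.run_gsa(gi, sets, mg.GsaParams(min_set_size=5))
        assert records
        assert all(r.classification in mg.CLASSIFICATIONS for r in records)
        assert all(r.padj >= r.pvalue - 1e-15 for r in records if r.converged)
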