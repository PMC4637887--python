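import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from grnmap.association import (
    SingleLocusModel,
    bh_adjust,
    genotype_deviations,
    scan_single,
    significance_transform,
)
from grnmap.datatypes import Cohort, PhenotypeTable, StructureCovariates
from grnmap.io import align_cohort


def class_data(means, n_per_class=10):
    """y exactly equal to its genotype-class mean (zero residual noise)."""
    g = np.repeat([0, 1, 2][: len(means)], n_per_class).astype(float)
    y = np.repeat(means, n_per_class).astype(float)
    return y, g


class TestAdditiveDominanceClosedForm:
    def test_means_8_11_10(self):
        # a = (m2 - m0)/2 = 1; d = m1 - (m0 + m2)/2 = 2
        y, g = class_data([8.0, 11.0, 10.0])
        res = SingleLocusModel(y, g).fit()
        assert res.a_hat == pytest.approx(1.0, abs=1e-10)
        assert res.d_hat == pytest.approx(2.0, abs=1e-10)

    def test_flat_means(self):
        y, g = class_data([10.0, 10.0, 10.0])
        res = SingleLocusModel(y, g).fit()
        assert res.a_hat == pytest.approx(0.0, abs=1e-12)
        assert res.d_hat == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_unbalanced(self, rng):
        # saturated coding: closed form holds for any class sizes
        g = np.array([0] * 5 + [1] * 17 + [2] * 8, dtype=float)
        y = rng.normal(size=g.size) + 2 * g
        res = SingleLocusModel(y, g).fit()
        m = [y[g == c].mean() for c in (0, 1, 2)]
        assert res.a_hat == pytest.approx((m[2] - m[0]) / 2, abs=1e-10)
        assert res.d_hat == pytest.approx(m[1] - (m[0] + m[2]) / 2, abs=1e-10)


class TestGenotypicTest:
    def test_perfect_fit(self):
        y, g = class_data([0.0, 1.0, 2.0])
        res = SingleLocusModel(y, g).fit()
        assert res.r2_explained == pytest.approx(1.0)
        assert res.m_p == pytest.approx(0.0, abs=1e-300)

    def test_equals_one_way_anova_without_covariates(self, rng):
        from scipy.stats import f_oneway

        g = np.repeat([0, 1, 2], 30).astype(float)
        y = rng.normal(size=90) + 0.3 * g
        res = SingleLocusModel(y, g).fit()
        f, p = f_oneway(y[g == 0], y[g == 1], y[g == 2])
        assert res.m_f == pytest.approx(f, rel=1e-10)
        assert res.m_p == pytest.approx(p, rel=1e-10)

    def test_structure_confounding_controlled(self, rng):
        # trait depends only on Q; SNP correlated with Q
        n = 400
        q = rng.normal(size=(n, 1))
        p_minor = 1 / (1 + np.exp(-q[:, 0]))  # genotype tracks structure
        g = rng.binomial(2, np.clip(p_minor / 2 + 0.2, 0.05, 0.95)).astype(float)
        pvals_adj, pvals_raw = [], []
        for _ in range(200):
            y = 2.0 * q[:, 0] + rng.normal(size=n)
            pvals_adj.append(SingleLocusModel(y, g, q).fit().m_p)
            pvals_raw.append(SingleLocusModel(y, g).fit().m_p)
        # adjusted: near-uniform null; unadjusted: inflated
        assert np.mean(np.array(pvals_adj) < 0.05) < 0.12
        assert np.mean(np.array(pvals_raw) < 0.05) > 0.3

    def test_skip_single_class(self):
        y = np.arange(10.0)
        g = np.ones(10)
        res = SingleLocusModel(y, g).fit()
        assert res.skipped
        assert "fewer than 2" in res.reason

    def test_two_class_additive_only(self):
        y, g = class_data([1.0, 2.0])
        res = SingleLocusModel(y, g).fit()
        assert not res.skipped
        assert np.isfinite(res.a_hat)
        assert np.isnan(res.d_hat)
        assert "not estimable" in res.reason

    def test_min_class_n_excludes_small_class(self):
        y = np.array([1.0, 2, 3, 4, 5, 6, 7, 100.0])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 2], dtype=float)
        res = SingleLocusModel(y, g, min_class_n=3).fit()
        assert res.n_used == 7  # single minor homozygote excluded


class TestOracleEquivalence:
    """p-values match an independently coded full-vs-reduced OLS comparison."""

    def statsmodels_pvalues(self, y, g, Q):
        cov = [np.ones(y.size)]
        if Q is not None:
            cov.append(Q)
        base = np.column_stack(cov)
        classes = np.unique(g)
        dummies = np.column_stack([(g == c).astype(float) for c in classes[1:]])
        full_fac = sm.OLS(y, np.column_stack([base, dummies])).fit()
        red = sm.OLS(y, base).fit()
        m_p = float(full_fac.compare_f_test(red)[1])
        x = g - 1.0
        z = np.where(g == 1.0, 0.5, -0.5)
        full = sm.OLS(y, np.column_stack([base, x, z])).fit()
        a_p = float(full.compare_f_test(sm.OLS(y, np.column_stack([base, z])).fit())[1])
        d_p = float(full.compare_f_test(sm.OLS(y, np.column_stack([base, x])).fit())[1])
        return m_p, a_p, d_p

    @pytest.mark.parametrize("with_q", [False, True])
    def test_matches_statsmodels(self, rng, with_q):
        for _ in range(25):
            n = int(rng.integers(30, 150))
            g = rng.binomial(2, rng.uniform(0.2, 0.5), size=n).astype(float)
            if len(np.unique(g)) < 3 or min(np.bincount(g.astype(int))) < 3:
                continue
            Q = rng.normal(size=(n, 2)) if with_q else None
            y = rng.normal(size=n) + 0.4 * g
            res = SingleLocusModel(y, g, Q).fit()
            m_p, a_p, d_p = self.statsmodels_pvalues(y, g, Q)
            assert res.m_p == pytest.approx(m_p, abs=1e-10)
            assert res.a_p == pytest.approx(a_p, abs=1e-10)
            assert res.d_p == pytest.approx(d_p, abs=1e-10)


class TestSignificanceTransform:
    def test_values(self):
        assert significance_transform(0.001) == pytest.approx(3.0)
        assert significance_transform(1.0) == pytest.approx(0.0)
        assert significance_transform(9.83e-07) == pytest.approx(6.0074, abs=1e-3)

    def test_invalid(self):
        with pytest.raises(ValueError):
            significance_transform(0.0)
        with pytest.raises(ValueError):
            significance_transform(-0.5)


class TestBHAdjust:
    def test_hand_computed(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_ties(self):
        assert bh_adjust(np.array([0.3]))[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust(np.full(5, 0.2)), np.full(5, 0.2))

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 50)))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-15)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=100)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([]))


class TestGenotypeDeviations:
    def test_balanced_two_classes(self):
        y = np.array([1.0, 1.0, 3.0, 3.0])
        g = np.array([0.0, 0.0, 2.0, 2.0])
        rows = genotype_deviations(y, g)
        assert [r.deviation for r in rows] == [pytest.approx(-1.0), pytest.approx(1.0)]

    def test_single_class(self):
        rows = genotype_deviations(np.array([2.0, 4.0]), np.array([1.0, 1.0]))
        assert rows[0].deviation == pytest.approx(0.0)

    def test_weighted_deviations_sum_to_zero(self, rng):
        y = rng.normal(size=200)
        g = rng.integers(0, 3, size=200).astype(float)
        rows = genotype_deviations(y, g)
        assert sum(r.n * r.deviation for r in rows) == pytest.approx(0.0, abs=1e-9)

    def test_deviation_matches_reported_style(self):
        # class mean 38.55 against grand mean 40.14 -> deviation -1.59
        y = np.concatenate([np.full(50, 38.55), np.full(50, 41.73)])
        g = np.concatenate([np.ones(50), np.full(50, 2.0)])
        rows = genotype_deviations(y, g, labels={1: "AG", 2: "GG"})
        ag = next(r for r in rows if r.genotype == "AG")
        assert ag.deviation == pytest.approx(38.55 - 40.14, abs=1e-9)


class TestScanSingle:
    def make_cohort(self, rng, n=200, m=10, trait_fn=None):
        from grnmap.simulate import SimulationSpec, simulate_genotypes
        import pandas as pd

        gm = simulate_genotypes(SimulationSpec(n, m, maf=(0.2, 0.5), seed=4))
        y = trait_fn(gm) if trait_fn else rng.normal(size=n)
        phen = PhenotypeTable(
            list(gm.individual_ids),
            pd.DataFrame({"t": y}, index=gm.individual_ids),
        )
        return align_cohort(gm, phen)

    def test_null_scan_bh_controls(self):
        # under a global null, BH at 0.1 rejects in at most ~10% of families
        total_sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cohort = self.make_cohort(rng)
            df = scan_single(cohort, alpha=0.01, fdr_max=0.1)
            assert len(df) == 10
            total_sig += int((df["significant_a"] | df["significant_d"]).sum())
        assert total_sig <= 10  # expected ~4 family-wise false rejections

    def test_planted_snp_detected(self, rng):
        def trait(gm):
            return gm.calls[:, 3] * 1.0 + rng.normal(size=gm.n_individuals) * 0.5

        cohort = self.make_cohort(rng, n=435, trait_fn=trait)
        df = scan_single(cohort)
        hit = df[df["snp"] == "snp4"].iloc[0]
        assert hit["significant_a"]

    def test_empty_snp_set(self, rng):
        cohort = self.make_cohort(rng)
        df = scan_single(cohort, snp_ids=[])
        assert df.empty

    def test_monomorphic_flagged(self, rng, genotypes_factory):
        import pandas as pd

        gm = genotypes_factory(np.zeros((20, 1)))
        phen = PhenotypeTable(
            list(gm.individual_ids),
            pd.DataFrame({"t": rng.normal(size=20)}, index=gm.individual_ids),
        )
        df = scan_single(align_cohort(gm, phen))
        assert df.iloc[0]["flags"] == "monomorphic"


class TestBHProperties:
    """Property-based checks of the step-up adjustment."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    pvec = st.lists(
        st.floats(min_value=1e-12, max_value=1.0, allow_nan=False),
        min_size=1, max_size=60,
    ).map(np.array)

    @given(pvec)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_q_bounds_and_ordering(self, p):
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-15)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    @given(pvec)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_statsmodels_reference(self, p):
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-10
        )
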