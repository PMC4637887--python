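import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from grnmap.coding import additive_code, dominance_code
from grnmap.datatypes import PhenotypeTable
from grnmap.epistasis import (
    EFFECT_TYPES,
    OccupancyRule,
    TwoLocusModel,
    combination_deviations,
    combination_effects,
    hub_target_pairs,
    scan_epistasis,
    two_locus_design,
)
from grnmap.io import align_cohort
from grnmap.simulate import (
    EffectModel,
    EpistaticTerm,
    SimulationSpec,
    simulate_genotypes,
    simulate_phenotype,
)


class TestTwoLocusDesign:
    def test_coding_table(self):
        design, counts = two_locus_design(np.array([2.0, 1.0]), np.array([0.0, 1.0]))
        row = design.iloc[0]
        assert (row.x1, row.x2, row.x1x2) == (1.0, -1.0, -1.0)
        assert (row.z1, row.z2, row.z1z2) == (-0.5, -0.5, 0.25)
        het = design.iloc[1]
        assert (het.x1, het.x2) == (0.0, 0.0)
        assert (het.z1, het.z2, het.z1z2) == (0.5, 0.5, 0.25)
        assert het.x1x2 == het.x1z2 == het.z1x2 == 0.0

    def test_single_cell_counts(self):
        _, counts = two_locus_design(np.zeros(7), np.zeros(7))
        assert counts[0, 0] == 7
        assert counts.sum() == 7

    def test_balanced_design_orthogonal(self):
        # with 1:2:1 x 1:2:1 cell counts (allele frequencies 1/2 at both
        # loci, exact HWE proportions) the 8 genetic columns are mutually
        # orthogonal -- the classical orthogonal partition
        w = [0.0] + [1.0] * 2 + [2.0]  # genotype pattern in 1:2:1 ratio
        g1 = np.repeat(w, 4)
        g2 = np.tile(w, 4)
        design, _ = two_locus_design(g1, g2)
        X = design.to_numpy()
        Xc = X - X.mean(axis=0)
        gram = Xc.T @ Xc
        off_diag = gram - np.diag(np.diag(gram))
        assert np.abs(off_diag).max() < 1e-12


def two_locus_panel(seed=3, n=435, maf=(0.3, 0.4)):
    gm = simulate_genotypes(SimulationSpec(n, 2, maf=list(maf), seed=seed))
    return gm


class TestTwoLocusModel:
    @pytest.mark.parametrize("effect_type", EFFECT_TYPES)
    def test_generative_recovery_noiseless(self, effect_type):
        gm = two_locus_panel()
        model = EffectModel(
            mu=2.0,
            epistasis=[EpistaticTerm("snp1", "snp2", effect_type, 1.0)],
            sigma=1e-12,
        )
        y = simulate_phenotype(gm, model, seed=1).trait("trait")
        res = TwoLocusModel(y, gm.column("snp1"), gm.column("snp2")).fit()
        assert res.estimate(effect_type) == pytest.approx(1.0, abs=1e-8)
        for other in set(EFFECT_TYPES) - {effect_type}:
            assert res.estimate(other) == pytest.approx(0.0, abs=1e-8)

    def test_duplicated_snp_non_estimable(self):
        gm = two_locus_panel()
        g = gm.column("snp1")
        y = np.random.default_rng(0).normal(size=g.size)
        rule = OccupancyRule(min_marginal_n=1, min_cells=3)
        res = TwoLocusModel(y, g, g.copy(), occupancy=rule).fit()
        assert not res.skipped
        assert any(np.isnan(res.estimate(t)) for t in EFFECT_TYPES)
        # with the default occupancy rule the pair is skipped instead
        assert TwoLocusModel(y, g, g.copy()).fit().skipped

    def test_occupancy_rule_skips(self):
        rule = OccupancyRule(min_marginal_n=3, min_cells=5)
        y = np.arange(20.0)
        g1 = np.array([0.0] * 10 + [1.0] * 8 + [2.0] * 2)  # minor hom n=2
        g2 = np.tile([0.0, 1.0, 2.0, 1.0], 5)
        res = TwoLocusModel(y, g1, g2, occupancy=rule).fit()
        assert res.skipped
        assert "marginal" in res.reason

    def test_adjusted_cell_means_no_covariates(self, rng):
        gm = two_locus_panel(seed=9, n=300)
        y = rng.normal(size=300)
        res = TwoLocusModel(y, gm.column("snp1"), gm.column("snp2")).fit()
        g1, g2 = gm.column("snp1"), gm.column("snp2")
        for i in range(3):
            for j in range(3):
                sel = (g1 == i) & (g2 == j)
                if sel.sum():
                    assert res.cell_means.loc[i, j] == pytest.approx(
                        y[sel].mean(), abs=1e-9
                    )

    def test_oracle_equivalence_statsmodels(self, rng):
        """1-df interaction p-values match independent full-vs-reduced OLS."""
        checked = 0
        for seed in range(40):
            local = np.random.default_rng(seed)
            n = int(local.integers(60, 200))
            g1 = local.binomial(2, local.uniform(0.25, 0.5), n).astype(float)
            g2 = local.binomial(2, local.uniform(0.25, 0.5), n).astype(float)
            y = local.normal(size=n) + 0.5 * (g1 - 1) * (g2 - 1)
            Q = local.normal(size=(n, 2))
            res = TwoLocusModel(y, g1, g2, Q).fit()
            if res.skipped or any(np.isnan(res.estimate(t)) for t in EFFECT_TYPES):
                continue
            x1, z1 = additive_code(g1), dominance_code(g1)
            x2, z2 = additive_code(g2), dominance_code(g2)
            cols = {
                "AxA": x1 * x2, "AxD": x1 * z2, "DxA": z1 * x2, "DxD": z1 * z2,
            }
            base = np.column_stack(
                [np.ones(n), Q, x1, z1, x2, z2] + [cols[t] for t in EFFECT_TYPES]
            )
            full = sm.OLS(y, base).fit()
            for k, t in enumerate(EFFECT_TYPES):
                reduced = sm.OLS(y, np.delete(base, 7 + k, axis=1)).fit()
                p_oracle = float(full.compare_f_test(reduced)[1])
                assert res.pvalue(t) == pytest.approx(p_oracle, abs=1e-10)
            checked += 1
        assert checked >= 20

    def test_marginal_effects_do_not_leak(self):
        # purely additive trait: epistatic estimates unbiased at zero
        for n in (200, 1000, 5000):
            ests = []
            for seed in range(30):
                gm = two_locus_panel(seed=seed, n=n)
                model = EffectModel(
                    mu=0.0, additive={"snp1": 0.5, "snp2": 0.3},
                    dominance={"snp1": 0.2}, sigma=1.0,
                )
                y = simulate_phenotype(gm, model, seed=seed + 100).trait("trait")
                res = TwoLocusModel(y, gm.column("snp1"), gm.column("snp2")).fit()
                if not res.skipped:
                    ests.append([res.estimate(t) for t in EFFECT_TYPES])
            mean_abs = np.abs(np.nanmean(ests, axis=0))
            assert mean_abs.max() < 4.0 / np.sqrt(n * 0.05)


TABLE_AXA_FIXTURE = [
    # printed allele-allele rows: (combination, effect, frequency)
    ("A-T", 2.07, 0.107),
    ("T-C", 0.514, 0.426),
    ("A-C", -0.637, 0.343),
    ("T-T", -1.8, 0.124),
]


class TestCombinationEffects:
    def test_printed_fixture_invariants(self):
        freqs = np.array([r[2] for r in TABLE_AXA_FIXTURE])
        effects = np.array([r[1] for r in TABLE_AXA_FIXTURE])
        assert freqs.sum() == pytest.approx(1.0, abs=2e-3)
        assert float(freqs @ effects) == pytest.approx(0.0, abs=5e-3)

    def test_own_outputs_satisfy_invariants(self, rng):
        g1 = rng.integers(0, 3, 100).astype(float)
        g2 = rng.integers(0, 3, 100).astype(float)
        y = rng.normal(size=100)
        for effect_type in EFFECT_TYPES:
            rows = combination_effects(y, g1, g2, effect_type)
            freq = sum(r.frequency for r in rows)
            weighted = sum(r.frequency * r.effect for r in rows)
            assert freq == pytest.approx(1.0, abs=1e-12)
            assert weighted == pytest.approx(0.0, abs=1e-9)

    def test_enumeration_oracle(self):
        # brute-force per-individual contribution enumeration, 20 individuals
        rng = np.random.default_rng(7)
        g1 = rng.integers(0, 3, 20).astype(float)
        g2 = rng.integers(0, 3, 20).astype(float)
        y = rng.normal(size=20)
        rows = combination_effects(y, g1, g2, "AxA",
                                   alleles1=("A", "T"), alleles2=("C", "G"))
        # oracle: expand every individual into 4 weighted (allele, allele) draws
        records = []
        for yi, a, b in zip(y, g1, g2):
            al1 = ["A", "A"] if a == 0 else (["A", "T"] if a == 1 else ["T", "T"])
            al2 = ["C", "C"] if b == 0 else (["C", "G"] if b == 1 else ["G", "G"])
            for u in al1:
                for v in al2:
                    records.append((f"{u}-{v}", yi))
        df = pd.DataFrame(records, columns=["combo", "y"])
        grand = y.mean()
        for row in rows:
            sub = df[df["combo"] == row.combination]
            assert row.effect == pytest.approx(sub["y"].mean() - grand, abs=1e-12)
            assert row.frequency == pytest.approx(len(sub) / len(df), abs=1e-12)

    def test_dxd_single_combination(self):
        y = np.array([3.0, 3.0, 3.0])
        g1 = np.ones(3)
        g2 = np.ones(3)
        rows = combination_effects(y, g1, g2, "DxD")
        assert len(rows) == 1
        assert rows[0].effect == pytest.approx(0.0)
        assert rows[0].frequency == pytest.approx(1.0)

    def test_rows_sorted_by_effect(self, rng):
        g1 = rng.integers(0, 3, 60).astype(float)
        g2 = rng.integers(0, 3, 60).astype(float)
        y = rng.normal(size=60)
        rows = combination_effects(y, g1, g2, "AxD")
        effects = [r.effect for r in rows]
        assert effects == sorted(effects, reverse=True)


class TestCombinationDeviations:
    def test_constant_trait(self):
        dev = combination_deviations(np.full(30, 2.0),
                                     np.tile([0.0, 1, 2], 10),
                                     np.repeat([0.0, 1, 2], 10))
        filled = dev.to_numpy()[~np.isnan(dev.to_numpy())]
        np.testing.assert_allclose(filled, 0.0, atol=1e-12)

    def test_single_occupied_cell(self):
        dev = combination_deviations(np.array([1.0, 2.0]), np.zeros(2), np.zeros(2))
        assert dev.loc[0, 0] == pytest.approx(0.0)
        assert np.isnan(dev.loc[1, 2])

    def test_hand_built_panel(self):
        y = np.array([1.0, 3.0, 10.0, 20.0])
        g1 = np.array([0.0, 0.0, 2.0, 2.0])
        g2 = np.array([0.0, 0.0, 1.0, 1.0])
        dev = combination_deviations(y, g1, g2)
        grand = 8.5
        assert dev.loc[0, 0] == pytest.approx(2.0 - grand)
        assert dev.loc[2, 1] == pytest.approx(15.0 - grand)


class TestScanEpistasis:
    def test_pair_combinatorics(self):
        pairs = hub_target_pairs([f"h{i}" for i in range(19)],
                                 [f"t{i}" for i in range(100)])
        assert len(pairs) == 1900

    def test_planted_pair_detected_and_null_controlled(self, rng):
        gm = simulate_genotypes(SimulationSpec(435, 12, maf=(0.25, 0.5), seed=21))
        model = EffectModel(
            mu=0.0,
            epistasis=[EpistaticTerm("snp1", "snp2", "AxA", 1.0)],
            sigma=1.0,
        )
        phen = simulate_phenotype(gm, model, seed=2)
        cohort = align_cohort(gm, phen)
        df = scan_epistasis(cohort, "all-pairs", alpha=0.01, fdr_max=0.1)
        sig = df[df["significant"].astype(bool)]
        assert (("snp1", "snp2", "AxA") in
                set(zip(sig.snp1, sig.snp2, sig.effect_type)))
        false_pos = sig[~((sig.snp1 == "snp1") & (sig.snp2 == "snp2"))]
        assert len(false_pos) <= 2
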